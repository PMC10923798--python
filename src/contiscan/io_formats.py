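"""Readers and writers for every external format the pipeline touches.

All interval types are 1-based inclusive (GFF convention); VCF positions are
1-based. Coordinate conversions are localized here. Parsers never silently
drop data: every excluded record is counted in a :class:`FilterReport`.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  #: genotype code for a missing call
REF, ALT = 0, 1

_NUC = frozenset("ACGT")


class ParseError(ValueError):
    """Raised for malformed input records (carries file context)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of records excluded by a reader, keyed by reason."""

    dropped: dict[str, int] = field(default_factory=dict)

    def bump(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    def total(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SnpAlignment:
    """Samples x biallelic-SNP matrix anchored to 1-based reference positions.

    ``genotypes[i, j]`` is 0 (reference allele), 1 (alternate allele) or -1
    (missing) for sample ``sample_ids[i]`` at reference position
    ``positions[j]``.
    """

    sample_ids: list[str]
    positions: np.ndarray          # int64, 1-based, strictly increasing
    ref_alleles: np.ndarray        # '<U1'
    alt_alleles: np.ndarray        # '<U1'
    genotypes: np.ndarray          # int8, shape (n_samples, n_sites)
    genome_length: int
    contig_id: str = "chr1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype="<U1")
        self.alt_alleles = np.asarray(self.alt_alleles, dtype="<U1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.n_sites:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be unique and strictly increasing")
            if int(self.positions[-1]) > self.genome_length:
                raise ValueError("genome_length < max(position)")
            if np.any(self.ref_alleles == self.alt_alleles):
                raise ValueError("ref and alt allele identical at some site")
        if self.genotypes.shape != (self.n_samples, self.n_sites):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({self.n_samples}, {self.n_sites})"
            )
        bad = ~np.isin(self.genotypes, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError("genotypes must be in {0, 1, -1}")

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def site_slice(self, start: int, end: int) -> slice:
        """Index slice of sites with ``start <= position <= end`` (1-based)."""
        lo = int(np.searchsorted(self.positions, start, side="left"))
        hi = int(np.searchsorted(self.positions, end, side="right"))
        return slice(lo, hi)

    def sequences(self, reference: str) -> dict[str, str]:
        """Reconstruct full-length sequences by substituting alt alleles."""
        if len(reference) != self.genome_length:
            raise ValueError("reference length != genome_length")
        out: dict[str, str] = {}
        ref_arr = np.frombuffer(reference.encode(), dtype="S1").astype("<U1")
        idx = self.positions - 1
        for i, sid in enumerate(self.sample_ids):
            seq = ref_arr.copy()
            g = self.genotypes[i]
            seq[idx[g == ALT]] = self.alt_alleles[g == ALT]
            seq[idx[g == MISSING]] = "N"
            out[sid] = "".join(seq)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene interval (1-based inclusive)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def codon_complete(self) -> bool:
        return self.length % 3 == 0


@dataclass(frozen=True)
class RecombEvent:
    """A homologous-recombination tract and the strains that carry it."""

    start: int
    end: int
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("recombination event with end < start")
        if not self.carriers:
            raise ValueError("recombination event with no carriers")
        object.__setattr__(self, "carriers", frozenset(self.carriers))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AniMatrix:
    """Symmetric percent-identity matrix; NaN marks missing pairs."""

    sample_ids: list[str]
    values: np.ndarray  # float64, (n, n), diagonal 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("ANI matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values - self.values.T)) > 1e-9:
                raise ValueError("ANI matrix not symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("ANI diagonal must be 100")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("ANI values outside [0, 100]")


@dataclass
class SampleMetadata:
    """Per-sample table: lineage, coordinates, habitat, environment, HGT."""

    table: pd.DataFrame  # index = sample_id

    REQUIRED = ("lineage", "latitude", "longitude")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if (t["lineage"].astype(str).str.len() == 0).any():
            raise ValueError("empty lineage label")
        if (t["latitude"].abs() > 90).any() or (t["longitude"].abs() > 180).any():
            raise ValueError("coordinates out of range")
        if "hgt_count" in t.columns and (t["hgt_count"].dropna() < 0).any():
            raise ValueError("negative hgt_count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def lineage_map(self) -> dict[str, str]:
        return dict(self.table["lineage"].astype(str))

    def env_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("env_")]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_snp_vcf(
    path: str | Path,
    filter_biallelic: bool = True,
    contig: str | None = None,
    genome_length: int | None = None,
) -> tuple[SnpAlignment, FilterReport]:
    """Read a VCF into a :class:`SnpAlignment`, keeping biallelic SNPs only.

    Indels, MNPs and multiallelic records are dropped and counted in the
    returned :class:`FilterReport` when ``filter_biallelic`` is set.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    report = FilterReport()
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    contig_seen: str | None = None
    glen = genome_length
    try:
        seqnames, seqlens = list(vcf.seqnames), list(vcf.seqlens)
    except AttributeError:  # header without contig lengths
        seqnames, seqlens = [], []
    if seqnames:
        if contig is None and len(seqnames) > 1:
            raise ParseError("multi-contig VCF: name a contig explicitly")
        if contig is None:
            contig_seen = seqnames[0]
        if glen is None:
            want = contig or seqnames[0]
            if want in seqnames:
                glen = int(seqlens[seqnames.index(want)])
    for rec in vcf:
        if contig is not None and rec.CHROM != contig:
            continue
        if contig is None:
            if contig_seen is None:
                contig_seen = rec.CHROM
            elif rec.CHROM != contig_seen:
                raise ParseError("multi-contig VCF: name a contig explicitly")
        alt_list = rec.ALT
        if filter_biallelic:
            if len(alt_list) != 1:
                report.bump("dropped_multiallelic")
                continue
            if len(rec.REF) != 1 or len(alt_list[0]) != 1:
                report.bump("dropped_indel")
                continue
            if rec.REF not in _NUC or alt_list[0] not in _NUC:
                report.bump("dropped_non_acgt")
                continue
        if positions and rec.POS == positions[-1]:
            raise ParseError(f"duplicate position {rec.POS}")
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(alt_list[0])
        gt = np.asarray(rec.gt_types)  # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt == 0] = REF
        row[gt == 2] = ALT
        row[gt == 1] = ALT  # haploid callers may emit het-coded mixed calls
        rows.append(row)
    vcf.close()
    pos_arr = np.array(positions, dtype=np.int64)
    if pos_arr.size and np.any(np.diff(pos_arr) <= 0):
        raise ParseError("VCF positions not sorted / duplicated")
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    if glen is None:
        glen = int(pos_arr[-1]) if pos_arr.size else 0
    aln = SnpAlignment(
        sample_ids=samples,
        positions=pos_arr,
        ref_alleles=np.array(refs, dtype="<U1"),
        alt_alleles=np.array(alts, dtype="<U1"),
        genotypes=geno,
        genome_length=max(glen, int(pos_arr[-1]) if pos_arr.size else 0),
        contig_id=contig or contig_seen or "chr1",
    )
    return aln, report


def write_snp_vcf(aln: SnpAlignment, path: str | Path) -> None:
    """Write a haploid VCF v4.2 with GT fields (deterministic formatting)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={aln.contig_id},length={aln.genome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(aln.sample_ids)
            + "\n"
        )
        code = {REF: "0", ALT: "1", MISSING: "."}
        for j in range(aln.n_sites):
            gts = "\t".join(code[int(g)] for g in aln.genotypes[:, j])
            fh.write(
                f"{aln.contig_id}\t{aln.positions[j]}\t.\t{aln.ref_alleles[j]}\t"
                f"{aln.alt_alleles[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# FASTA alignment
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    path: str | Path, reference_id: str | None = None
) -> tuple[SnpAlignment, FilterReport, str]:
    """Extract biallelic SNP columns from a whole-genome FASTA alignment.

    Columns with gaps or more than two nucleotide states are excluded and
    counted. Returns ``(alignment, report, reference_sequence)``; the
    reference is the record named ``reference_id`` (default: first record),
    which is *not* included as a sample.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged sequence lengths {sorted(lengths)}")
    glen = lengths.pop()
    ref_idx = 0
    if reference_id is not None:
        ids = [r.id for r in records]
        if reference_id not in ids:
            raise ParseError(f"reference {reference_id!r} not in alignment")
        ref_idx = ids.index(reference_id)
    ref_seq = str(records[ref_idx].seq).upper()
    samples = [r for i, r in enumerate(records) if i != ref_idx]
    sample_ids = [r.id for r in samples]
    mat = np.array(
        [np.frombuffer(str(r.seq).upper().encode(), dtype="S1") for r in samples]
    ).astype("<U1")
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1").astype("<U1")

    report = FilterReport()
    positions, refs, alts, cols = [], [], [], []
    for j in range(glen):
        col = mat[:, j]
        states = set(col.tolist()) | {ref_arr[j]}
        if not states <= _NUC:
            if not (set(col.tolist()) | {ref_arr[j]}) <= (_NUC | {"-", "N"}):
                report.bump("dropped_non_acgt")
            else:
                report.bump("dropped_gap_or_missing")
            continue
        if len(states) == 1:
            continue
        if len(states) > 2:
            report.bump("dropped_multiallelic")
            continue
        ref_base = ref_arr[j]
        alt_base = (states - {ref_base}).pop()
        positions.append(j + 1)
        refs.append(ref_base)
        alts.append(alt_base)
        cols.append((col == alt_base).astype(np.int8))
    geno = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    aln = SnpAlignment(
        sample_ids=sample_ids,
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=np.array(refs, dtype="<U1"),
        alt_alleles=np.array(alts, dtype="<U1"),
        genotypes=geno,
        genome_length=glen,
    )
    return aln, report, ref_seq


def write_fasta_alignment(
    sequences: Mapping[str, str], path: str | Path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF (genes + Gubbins-style recombination dialect)
# ---------------------------------------------------------------------------

_GFF_COLS = (
    "seqid source type start end score strand phase attributes".split()
)


def _parse_gff_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            yield lineno, fields


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in re.split(r";\s*", attr.strip()):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:  # GFF2 style: key "value"
            k, v = part.split(" ", 1)
        else:
            k, v = part, ""
        out[k.strip()] = v.strip().strip('"')
    return out


def read_gene_gff(path: str | Path) -> tuple[list[GeneModel], FilterReport]:
    """Read CDS/gene features from GFF3, sorted by start.

    CDS whose length is not a multiple of 3 are retained but counted in the
    report under ``flagged_not_codon_multiple``.
    """
    genes: list[GeneModel] = []
    report = FilterReport()
    for lineno, f in _parse_gff_rows(path):
        if f[2].lower() not in ("cds", "gene"):
            continue
        start, end = int(f[3]), int(f[4])
        if end < start:
            raise ParseError(f"{path}:{lineno}: end < start")
        attrs = _parse_attributes(f[8])
        gid = attrs.get("ID") or attrs.get("gene_id") or f"gene_{lineno}"
        phase = int(f[7]) if f[7] in "012" else 0
        g = GeneModel(gene_id=gid, start=start, end=end, strand=f[6], phase=phase)
        if not g.codon_complete:
            report.bump("flagged_not_codon_multiple")
        genes.append(g)
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes, report


def write_gene_gff(genes: Sequence[GeneModel], path: str | Path,
                   contig_id: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{contig_id}\tcontiscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t"
                f"{g.phase}\tID={g.gene_id}\n"
            )


def read_recomb_gff(
    path: str | Path,
    known_samples: Sequence[str] | None = None,
    strict: bool = True,
) -> list[RecombEvent]:
    """Read a Gubbins-style recombination GFF (``taxa="s1 s2"`` attribute).

    Coordinates are kept 1-based inclusive. Records are never deduplicated:
    identical intervals with different carriers are distinct events. A carrier
    not among ``known_samples`` raises in strict mode, warns otherwise.
    """
    known = set(known_samples) if known_samples is not None else None
    events: list[RecombEvent] = []
    for lineno, f in _parse_gff_rows(path):
        attrs = _parse_attributes(f[8])
        if "taxa" not in attrs:
            raise ParseError(f"{path}:{lineno}: record without taxa attribute")
        carriers = frozenset(attrs["taxa"].split())
        if not carriers:
            raise ParseError(f"{path}:{lineno}: empty taxa attribute")
        if known is not None:
            unknown = carriers - known
            if unknown:
                msg = f"{path}:{lineno}: unknown carriers {sorted(unknown)}"
                if strict:
                    raise ParseError(msg)
                warnings.warn(msg)
        events.append(RecombEvent(start=int(f[3]), end=int(f[4]), carriers=carriers))
    return events


def write_recomb_gff(events: Sequence[RecombEvent], path: str | Path,
                     contig_id: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            taxa = " ".join(sorted(ev.carriers))
            fh.write(
                f'{contig_id}\tgubbins\tCDS\t{ev.start}\t{ev.end}\t.\t.\t.\t'
                f'taxa="{taxa}"\n'
            )


# ---------------------------------------------------------------------------
# ANI / metadata TSV
# ---------------------------------------------------------------------------

def read_ani_matrix(path: str | Path) -> AniMatrix:
    """Read an ANI table: long format (query, target, identity) or square.

    Reciprocal values are symmetrized by arithmetic mean; self-identity is
    forced to 100. Missing pairs are NaN.
    """
    df = pd.read_csv(path, sep="\t")
    is_long = (
        df.shape[1] in (3, 4)
        and df.iloc[:, 0].dtype == object
        and df.iloc[:, 1].dtype == object
        and df.iloc[:, 2].dtype.kind in "fi"
        and not set(df.columns[1:]) & set(df.iloc[:, 0])
    )
    if is_long:
        q, t, v = df.columns[:3]
        ids = sorted(set(df[q]) | set(df[t]))
        idx = {s: i for i, s in enumerate(ids)}
        n = len(ids)
        acc = np.full((n, n), np.nan)
        cnt = np.zeros((n, n))
        for _, row in df.iterrows():
            val = float(row[v])
            if not 0 <= val <= 100:
                raise ParseError(f"identity {val} outside [0, 100]")
            i, j = idx[row[q]], idx[row[t]]
            if np.isnan(acc[i, j]):
                acc[i, j] = 0.0
            acc[i, j] += val
            cnt[i, j] += 1
        with np.errstate(invalid="ignore"):
            mean = acc / np.where(cnt > 0, cnt, np.nan)
        vals = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                pair = [x for x in (mean[i, j], mean[j, i]) if np.isfinite(x)]
                if pair:
                    vals[i, j] = vals[j, i] = float(np.mean(pair))
        np.fill_diagonal(vals, 100.0)
        return AniMatrix(sample_ids=ids, values=vals)
    # square matrix with header row + index column
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = list(df.index.astype(str))
    if list(df.columns.astype(str)) != ids:
        raise ParseError("square ANI matrix rows and columns disagree")
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 100.0)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ParseError("identity outside [0, 100]")
    return AniMatrix(sample_ids=ids, values=vals)


def write_ani_matrix(ani: AniMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ani.values, index=ani.sample_ids, columns=ani.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(table=df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_tree(path: str | Path):
    """Read a rooted newick tree (dendropy Tree with tip labels preserved)."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError("negative branch length")
    return tree


def write_tree(tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
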
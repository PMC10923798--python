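"""Per-gene McDonald-Kreitman tests with neutrality index and classification.

Divergence is polarized against the reference genome sequence: a site is a
fixed difference when every non-missing ingroup allele agrees and differs
from the reference base, and polymorphic when two alleles segregate in the
ingroup. Synonymous vs nonsynonymous status is decided by translating the
codon (bacterial table 11) with the variant substituted into the
ingroup-consensus codon background; minus-strand genes are
reverse-complemented. NI = (Pn/Ps)/(Dn/Ds); the Fisher exact test is
two-sided on [[Dn, Ds], [Pn, Ps]].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import ALT, MISSING, REF, GeneModel, SnpAlignment
from .popgen_scan import OutlierRegion

_COMP = str.maketrans("ACGT", "TGCA")
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        t = unambiguous_dna_by_id[11]
        _CODON_TABLE.update(t.forward_table)
        for stop in t.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _translate_codon(codon: str, strand: str) -> str:
    if strand == "-":
        codon = codon.translate(_COMP)[::-1]
    return _codon_table().get(codon, "X")


@dataclass
class SiteChangeCounts:
    gene_id: str
    Dn: int = 0
    Ds: int = 0
    Pn: int = 0
    Ps: int = 0
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class MkResult:
    gene_id: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    NI: float
    p: float
    selection_class: str  # positive | negative | none | undefined
    in_outlier_region: bool = False


def classify_site_changes(
    gene: GeneModel,
    aln: SnpAlignment,
    ingroup: Sequence[str],
    reference: str,
    max_missing_frac: float = 0.5,
) -> SiteChangeCounts:
    """Count fixed/polymorphic x synonymous/nonsynonymous changes in a gene.

    Multiple SNPs in one codon are resolved one at a time against the
    ingroup-consensus codon background. Codons missing in more than
    ``max_missing_frac`` of ingroup samples are excluded. Genes whose
    reference frame contains an internal stop are flagged and skipped.
    """
    out = SiteChangeCounts(gene_id=gene.gene_id)
    if not gene.codon_complete:
        out.skipped = True
        out.skip_reason = "length_not_multiple_of_3"
        return out
    if gene.end > len(reference):
        raise ValueError(f"gene {gene.gene_id} beyond reference end")
    ref_cds = reference[gene.start - 1 : gene.end].upper()
    coding = ref_cds.translate(_COMP)[::-1] if gene.strand == "-" else ref_cds
    table = _codon_table()
    aa = [table.get(coding[i : i + 3], "X") for i in range(0, len(coding), 3)]
    if "*" in aa[:-1]:
        out.skipped = True
        out.skip_reason = "internal_stop_in_reference_frame"
        return out

    rows = aln.sample_index(ingroup)
    sl = aln.site_slice(gene.start, gene.end)
    positions = aln.positions[sl]
    geno = aln.genotypes[rows, sl]
    refs = aln.ref_alleles[sl]
    alts = aln.alt_alleles[sl]
    n_in = len(rows)

    # group variant sites by codon (plus-strand codon index)
    by_codon: dict[int, list[int]] = {}
    for j, p in enumerate(positions):
        ci = (int(p) - gene.start) // 3
        by_codon.setdefault(ci, []).append(j)

    for ci, site_js in sorted(by_codon.items()):
        cstart = gene.start + 3 * ci  # 1-based codon start on the genome
        # ingroup consensus codon background (reference base where monomorphic)
        background = list(reference[cstart - 1 : cstart + 2].upper())
        codon_missing = 0
        site_info = []
        for j in site_js:
            col = geno[:, j]
            called = col[col != MISSING]
            codon_missing = max(codon_missing, int((col == MISSING).sum()))
            if called.size == 0:
                continue
            n_alt = int((called == ALT).sum())
            n_ref = called.size - n_alt
            consensus = alts[j] if n_alt >= n_ref else refs[j]
            background[int(positions[j]) - cstart] = consensus
            site_info.append((j, n_ref, n_alt))
        if n_in and codon_missing / n_in > max_missing_frac:
            continue
        for j, n_ref, n_alt in site_info:
            off = int(positions[j]) - cstart
            codon_a = list(background)
            codon_b = list(background)
            codon_a[off] = refs[j]
            codon_b[off] = alts[j]
            syn = _translate_codon("".join(codon_a), gene.strand) == \
                _translate_codon("".join(codon_b), gene.strand)
            if n_ref > 0 and n_alt > 0:  # segregating in the ingroup
                if syn:
                    out.Ps += 1
                else:
                    out.Pn += 1
            elif n_ref == 0 and n_alt > 0:  # fixed for alt vs reference
                if syn:
                    out.Ds += 1
                else:
                    out.Dn += 1
            # n_alt == 0: ingroup fixed for the reference base; no change
    return out


def mk_test(counts: SiteChangeCounts, alpha: float = 0.05) -> MkResult:
    """Neutrality index and two-sided Fisher exact test for one gene."""
    Dn, Ds, Pn, Ps = counts.Dn, counts.Ds, counts.Pn, counts.Ps
    if min(Dn, Ds, Pn, Ps) < 0:
        raise ValueError("negative MK counts")
    _, p = sps.fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
    if Ps == 0 or Ds == 0 or Dn == 0:
        ni = math.nan
        cls = "undefined"
    else:
        ni = (Pn / Ps) / (Dn / Ds)
        if p < alpha:
            cls = "positive" if ni < 1 else ("negative" if ni > 1 else "none")
        else:
            cls = "none"
    if counts.skipped:
        cls = "undefined"
        p = math.nan
    return MkResult(gene_id=counts.gene_id, Dn=Dn, Ds=Ds, Pn=Pn, Ps=Ps,
                    NI=ni, p=float(p), selection_class=cls)


def genomewide_mk(
    genes: Sequence[GeneModel],
    aln: SnpAlignment,
    lineage_map: Mapping[str, str],
    reference: str,
    alpha: float = 0.05,
    outlier_regions: Sequence[OutlierRegion] = (),
    bh_correct: bool = False,
) -> dict[str, list[MkResult]]:
    """MK test for every gene, per lineage ingroup.

    Returns {lineage: [MkResult, ...]}; genes overlapping an outlier region
    are flagged ``in_outlier_region`` (divergence-candidate logic). Optional
    Benjamini-Hochberg correction replaces p with adjusted values before
    classification.
    """
    groups: dict[str, list[str]] = {}
    for s in aln.sample_ids:
        if s in lineage_map:
            groups.setdefault(lineage_map[s], []).append(s)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    region_ivs = [(r.start, r.end) for r in outlier_regions]

    out: dict[str, list[MkResult]] = {}
    for lin in sorted(groups):
        results = []
        for g in genes:
            counts = classify_site_changes(g, aln, groups[lin], reference)
            results.append((g, counts))
        pvals = []
        mk = [mk_test(c, alpha=alpha) for _, c in results]
        if bh_correct:
            finite = [r for r in mk if np.isfinite(r.p)]
            if finite:
                order = np.argsort([r.p for r in finite])
                m = len(finite)
                adj = np.empty(m)
                prev = 1.0
                for rank, oi in list(enumerate(order))[::-1]:
                    val = finite[oi].p * m / (rank + 1)
                    prev = min(prev, val)
                    adj[oi] = prev
                for r, a in zip(finite, adj):
                    r.p = float(a)
                    if np.isfinite(r.NI):
                        if r.p < alpha:
                            r.selection_class = (
                                "positive" if r.NI < 1
                                else ("negative" if r.NI > 1 else "none")
                            )
                        else:
                            r.selection_class = "none"
        for (g, _), r in zip(results, mk):
            r.in_outlier_region = any(
                g.start <= e and g.end >= s for s, e in region_ivs
            )
        out[lin] = mk
    return out
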
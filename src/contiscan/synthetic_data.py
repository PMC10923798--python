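"""Synthetic speciation-continuum datasets with a machine-readable truth set.

The generator emulates the statistical structure of a multi-lineage
bacterial SNP dataset: K lineages diverge from a star of founder sequences
(per-site founder divergence ``d``); within each lineage haplotypes descend
from a Kingman coalescent with per-site mutation parameter ``theta``, drawn
independently per genealogy block (emulating the quasi-independent local
trees that pervasive homologous recombination produces); an optional
high-divergence island multiplies founder divergence over an interval;
homologous-recombination tracts are copied donor -> recipient and recorded
as :class:`RecombEvent` truth; codon-partitioned genes are tiled across the
genome, a designated subset receiving implanted nonsynonymous fixed
differences; sampling locations scatter around lineage centroids and
environmental traits evolve by Brownian motion on the true tree.

Under this model (documented closed forms):

* ``E[pi]`` within a lineage is ``theta``;
* founder pairwise divergence is ``d*(1 - d/2)`` (independent Bernoulli(d/2)
  flips per lineage to a shared alternate allele);
* ``E[D_XY] = d*(1 - d/2) + theta_A*(1 - 1/n_A) + theta_B*(1 - 1/n_B)``
  (tip-to-founder distance adds ``theta*(1 - 1/n)`` per side);
* ``E[Tajima's D] ~ 0`` under neutral configs.

A single seed drives the run; per-component child streams are derived with
fixed labels so individual components are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    ALT,
    REF,
    AniMatrix,
    GeneModel,
    RecombEvent,
    SampleMetadata,
    SnpAlignment,
    write_ani_matrix,
    write_fasta_alignment,
    write_gene_gff,
    write_metadata,
    write_recomb_gff,
    write_snp_vcf,
)

_BASES = np.array(["A", "C", "G", "T"])

# translation table 11 (bacterial); start-codon exceptions are irrelevant here
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        t = unambiguous_dna_by_id[11]
        _CODON_TABLE.update(t.forward_table)
        for stop in t.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class IslandConfig:
    start: int
    end: int
    divergence_multiplier: float = 5.0


@dataclass
class GeneConfig:
    n_genes: int = 40
    codons_per_gene: int = 300
    n_selected: int = 4
    omega_pos: int = 20  #: implanted nonsynonymous fixed differences per selected gene
    minus_strand_fraction: float = 0.25
    #: probability a nonsynonymous change inside a gene survives purifying
    #: selection (applied to neutral mutations and founder divergence alike;
    #: implanted omega_pos sites bypass it). 1.0 disables purifying selection.
    #: The default 0.1 mirrors typical bacterial core-gene dN/dS.
    nonsyn_retention: float = 0.1


@dataclass
class GeographyConfig:
    lineage_centroids: list[tuple[float, float]] | None = None  # (lat, lon)
    scatter_km: float = 50.0


@dataclass
class EnvConfig:
    n_vars: int = 3
    brownian_sigma: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_lineages: int = 4
    samples_per_lineage: list[int] = field(default_factory=lambda: [10, 10, 10, 10])
    genome_length: int = 100_000
    theta: float = 0.005          # within-lineage per-site diversity
    divergence: float = 0.015     # per-site founder divergence between lineages
    #: shared divergence of every lineage from the reference genome (emulating
    #: polarization against an outgroup reference); adds fixed differences
    #: common to all lineages without affecting between-lineage statistics
    outgroup_divergence: float = 0.01
    tract_rate: float = 2.0       # expected HR tracts per strain
    tract_mean_len: int = 2_000   # geometric mean tract length, bp
    between_tract_prob: float = 0.3
    migration_weights: dict[tuple[str, str], float] | None = None
    island: IslandConfig | None = None
    genes: GeneConfig = field(default_factory=GeneConfig)
    geography: GeographyConfig = field(default_factory=GeographyConfig)
    env: EnvConfig = field(default_factory=EnvConfig)
    genealogy_block_len: int = 10_000
    hgt_rate_per_mb: float = 50.0

    def __post_init__(self) -> None:
        if len(self.samples_per_lineage) != self.n_lineages:
            raise ValueError("samples_per_lineage length != n_lineages")
        if any(n < 1 for n in self.samples_per_lineage):
            raise ValueError("each lineage needs >=1 sample")
        if not (0 <= self.theta <= 0.2 and 0 <= self.divergence <= 0.2):
            raise ValueError("theta and divergence must be in [0, 0.2]")
        if self.island is not None:
            if not (1 <= self.island.start <= self.island.end <= self.genome_length):
                raise ValueError("island interval outside genome")
        if self.genome_length < 3:
            raise ValueError("genome too short")

    @property
    def lineage_names(self) -> list[str]:
        return [f"L{k + 1}" for k in range(self.n_lineages)]


# ---------------------------------------------------------------------------
# Truth set and bundle
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    lineage_map: dict[str, str]
    events: list[RecombEvent]
    island: tuple[int, int] | None
    selected_genes: list[str]
    tree_newick: str
    expected_pi: float
    expected_dxy: dict[str, float]        # "A|B" -> closed-form E[D_XY]
    expected_fst: dict[str, float]
    between_union_fraction: dict[str, float]  # realized, from implanted tracts
    per_strain_tract_count: dict[str, int]
    config: dict

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["events"] = [
            {"start": e.start, "end": e.end, "carriers": sorted(e.carriers)}
            for e in self.events
        ]
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class Bundle:
    alignment: SnpAlignment
    reference: str
    genes: list[GeneModel]
    events: list[RecombEvent]
    metadata: SampleMetadata
    ani: AniMatrix
    tree_newick: str
    truth: TruthSet


# ---------------------------------------------------------------------------
# Kingman coalescent
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    tips: frozenset[int]
    children: list["_Node"]
    time: float            # age (0 at tips)
    branch: float = 0.0    # length to parent


def kingman_tree(n: int, rng: np.random.Generator) -> _Node:
    """Sample a Kingman coalescent genealogy for ``n`` tips (time in units of
    the pairwise coalescent mean, so E[height] = 2*(1 - 1/n))."""
    nodes = [_Node(tips=frozenset([i]), children=[], time=0.0) for i in range(n)]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.branch = t - a.time
        b.branch = t - b.time
        nodes.append(_Node(tips=a.tips | b.tips, children=[a, b], time=t))
    return nodes[0]


def _branches(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        for c in node.children:
            out.append(c)
            stack.append(c)
    return out


def _newick(node: _Node, labels: Sequence[str]) -> str:
    if not node.children:
        (tip,) = node.tips
        return f"{labels[tip]}:{node.branch:.6f}"
    inner = ",".join(_newick(c, labels) for c in node.children)
    return f"({inner}):{node.branch:.6f}"


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

_STREAMS = {
    "reference": 1, "founders": 2, "coalescent": 3, "tracts": 4,
    "geography": 5, "env": 6, "hgt": 7, "genes": 8,
}


def _stream(cfg: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[label], cfg.seed])


def _tile_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    gc = cfg.genes
    if gc.n_genes == 0:
        return []
    glen = gc.codons_per_gene * 3
    spacing = cfg.genome_length // gc.n_genes
    if glen > spacing:
        raise ValueError("genes do not fit: reduce n_genes or codons_per_gene")
    genes = []
    for i in range(gc.n_genes):
        start = i * spacing + 1
        strand = "-" if rng.random() < gc.minus_strand_fraction else "+"
        genes.append(GeneModel(gene_id=f"gene{i + 1:04d}", start=start,
                               end=start + glen - 1, strand=strand))
    return genes


def _remove_stop_codons(ref_codes: np.ndarray, genes: Sequence[GeneModel],
                        rng: np.random.Generator) -> None:
    """Redraw reference codons until no gene frame contains a stop codon.

    Works in place on the integer-coded reference. Genes are tiled without
    overlap, so sanitizing one frame cannot reintroduce a stop in another.
    """
    table = _codon_table()
    for g in genes:
        for cstart in range(g.start - 1, g.end, 3):
            while True:
                codon = "".join(_BASES[ref_codes[cstart:cstart + 3]])
                if g.strand == "-":
                    codon = _revcomp(codon)
                if table.get(codon, "X") != "*":
                    break
                ref_codes[cstart:cstart + 3] = rng.integers(0, 4, 3)


def _aa_changing(ref: np.ndarray, alt: np.ndarray, gene: GeneModel,
                 site0: int) -> bool:
    """Does substituting the alt base at 0-based genome index ``site0`` change
    the encoded amino acid of ``gene`` (table 11, strand-aware)?"""
    table = _codon_table()
    off = site0 - (gene.start - 1)
    cstart = gene.start - 1 + (off // 3) * 3
    codon_ref = "".join(ref[cstart:cstart + 3])
    codon_alt = list(codon_ref)
    codon_alt[site0 - cstart] = alt[site0]
    codon_alt = "".join(codon_alt)
    if gene.strand == "-":
        codon_ref, codon_alt = _revcomp(codon_ref), _revcomp(codon_alt)
    return table.get(codon_ref, "X") != table.get(codon_alt, "X")


def simulate_continuum(cfg: SimConfig) -> Bundle:
    """Generate a full dataset bundle plus truth set (deterministic per seed)."""
    G = cfg.genome_length
    names = cfg.lineage_names
    sample_ids = [
        f"{lin}_s{i + 1:02d}"
        for lin, n in zip(names, cfg.samples_per_lineage)
        for i in range(n)
    ]
    lineage_map = {
        sid: lin
        for lin, n in zip(names, cfg.samples_per_lineage)
        for sid in [f"{lin}_s{i + 1:02d}" for i in range(n)]
    }
    offsets: dict[str, np.ndarray] = {}
    pos = 0
    for lin, n in zip(names, cfg.samples_per_lineage):
        offsets[lin] = np.arange(pos, pos + n)
        pos += n
    n_total = pos

    # reference genome; gene reading frames sanitized to be stop-free
    rng_ref = _stream(cfg, "reference")
    ref_codes = rng_ref.integers(0, 4, size=G)
    genes = _tile_genes(cfg, _stream(cfg, "genes"))
    _remove_stop_codons(ref_codes, genes, rng_ref)
    alt_codes = (ref_codes + rng_ref.integers(1, 4, size=G)) % 4
    ref = _BASES[ref_codes]
    alt = _BASES[alt_codes]

    # purifying-selection mask: genic sites whose ref->alt change is
    # nonsynonymous are retained with probability nonsyn_retention
    nonsyn_mask = np.zeros(G, dtype=bool)
    phi = cfg.genes.nonsyn_retention
    if genes and phi < 1.0:
        for g in genes:
            for s0 in range(g.start - 1, g.end):
                if _aa_changing(ref, alt, g, s0):
                    nonsyn_mask[s0] = True

    def _thin(flips: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if phi >= 1.0:
            return flips
        purged = nonsyn_mask & (rng.random(G) >= phi)
        return flips & ~purged

    # per-site founder flip probability (island multiplies divergence)
    p_site = np.full(G, cfg.divergence / 2.0)
    island_iv = None
    if cfg.island is not None:
        island_iv = (cfg.island.start, cfg.island.end)
        p_isl = min(cfg.divergence * cfg.island.divergence_multiplier / 2.0, 0.5)
        p_site[cfg.island.start - 1 : cfg.island.end] = p_isl

    rng_f = _stream(cfg, "founders")
    # shared outgroup divergence: ancestral flips common to every founder
    ancestral = _thin(rng_f.random(G) < cfg.outgroup_divergence, rng_f)
    founder_flip = {
        lin: ancestral | (_thin(rng_f.random(G) < p_site, rng_f) & ~ancestral)
        for lin in names
    }

    # implanted nonsynonymous fixed differences in the selected gene subset
    gc = cfg.genes
    selected = [g.gene_id for g in genes[: gc.n_selected]]
    implant_sites: list[int] = []
    rng_g = _stream(cfg, "genes")
    for g in genes[: gc.n_selected]:
        cand = rng_g.permutation(np.arange(g.start - 1, g.end))
        got = 0
        for s0 in cand:
            if got >= gc.omega_pos:
                break
            if _aa_changing(ref, alt, g, int(s0)):
                implant_sites.append(int(s0))
                got += 1
        if got < gc.omega_pos:
            raise ValueError(f"gene {g.gene_id}: not enough nonsynonymous sites")

    used: set[int] = set(implant_sites)
    for lin in names:
        used.update(np.flatnonzero(founder_flip[lin]).tolist())

    # within-lineage coalescent per genealogy block
    rng_c = _stream(cfg, "coalescent")
    mutations: list[tuple[str, frozenset[int], int]] = []  # (lineage, tips, site0)
    lineage_trees: dict[str, _Node] = {}
    block_edges = list(range(0, G, cfg.genealogy_block_len))
    mu = cfg.theta / 2.0
    for lin, n in zip(names, cfg.samples_per_lineage):
        if n == 1:
            lineage_trees[lin] = _Node(tips=frozenset([0]), children=[], time=0.0)
            continue
        for bi, bs in enumerate(block_edges):
            blen = min(cfg.genealogy_block_len, G - bs)
            tree = kingman_tree(n, rng_c)
            if bi == 0:
                lineage_trees[lin] = tree
            branches = _branches(tree)
            lens = np.array([b.branch for b in branches])
            total = lens.sum()
            n_mut = rng_c.poisson(mu * total * blen)
            if n_mut == 0:
                continue
            which = rng_c.choice(len(branches), size=n_mut, p=lens / total)
            for w in which:
                # infinite-sites: retry on collision
                for _ in range(10_000):
                    s0 = int(rng_c.integers(bs, bs + blen))
                    if s0 not in used:
                        break
                else:  # pragma: no cover - saturated block
                    raise RuntimeError("could not place mutation (block saturated)")
                if nonsyn_mask[s0] and rng_c.random() >= phi:
                    continue  # purged by purifying selection; site stays free
                used.add(s0)
                mutations.append((lin, branches[w].tips, s0))

    # assemble genotype matrix over the union of variable sites
    site_set = set(implant_sites)
    for lin in names:
        site_set.update(np.flatnonzero(founder_flip[lin]).tolist())
    site_set.update(s for _, _, s in mutations)
    all_sites = np.array(sorted(site_set), dtype=np.int64)
    col_of = {s: i for i, s in enumerate(all_sites.tolist())}
    geno = np.zeros((n_total, len(all_sites)), dtype=np.int8)
    for lin in names:
        row = founder_flip[lin][all_sites].astype(np.int8)
        geno[offsets[lin]] = row
    for lin, tips, s0 in mutations:
        rows = offsets[lin][list(tips)]
        geno[rows, col_of[s0]] ^= 1
    if implant_sites:
        geno[:, [col_of[s] for s in implant_sites]] = 1

    # homologous-recombination tracts (donor -> recipient, last writer wins)
    rng_t = _stream(cfg, "tracts")
    events: list[RecombEvent] = []
    tract_count = {sid: 0 for sid in sample_ids}
    pair_names = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    for sid in sample_ids:
        lin = lineage_map[sid]
        n_tr = rng_t.poisson(cfg.tract_rate)
        for _ in range(n_tr):
            if len(names) > 1 and rng_t.random() < cfg.between_tract_prob:
                others = [x for x in names if x != lin]
                if cfg.migration_weights:
                    w = np.array([
                        cfg.migration_weights.get(tuple(sorted((lin, o))), 1.0)
                        for o in others
                    ])
                    if w.sum() == 0:
                        continue
                    donor_lin = others[int(rng_t.choice(len(others), p=w / w.sum()))]
                else:
                    donor_lin = others[int(rng_t.integers(len(others)))]
            else:
                donor_lin = lin
            pool = [s for s in sample_ids if lineage_map[s] == donor_lin and s != sid]
            if not pool:
                continue
            donor = pool[int(rng_t.integers(len(pool)))]
            start = int(rng_t.integers(1, G + 1))
            length = int(rng_t.geometric(1.0 / cfg.tract_mean_len))
            end = min(start + length - 1, G)
            lo = int(np.searchsorted(all_sites, start - 1))
            hi = int(np.searchsorted(all_sites, end, side="left"))
            ridx = sample_ids.index(sid)
            didx = sample_ids.index(donor)
            geno[ridx, lo:hi] = geno[didx, lo:hi]
            events.append(RecombEvent(start=start, end=end,
                                      carriers=frozenset({sid, donor})))
            tract_count[sid] += 1

    # drop all-reference columns (invisible to reference-based variant calling)
    keep = geno.max(axis=0) > 0
    geno = geno[:, keep]
    all_sites = all_sites[keep]
    aln = SnpAlignment(
        sample_ids=sample_ids,
        positions=all_sites + 1,
        ref_alleles=ref[all_sites],
        alt_alleles=alt[all_sites],
        genotypes=geno,
        genome_length=G,
    )

    # true tree: star of founder branches, within-lineage genealogies (block 0)
    t_div = cfg.divergence / cfg.theta if cfg.theta > 0 else 1.0
    heights = {lin: lineage_trees[lin].time for lin in names}
    root_age = t_div + max(heights.values())
    parts = []
    for lin, n in zip(names, cfg.samples_per_lineage):
        labels = [f"{lin}_s{i + 1:02d}" for i in range(n)]
        sub = lineage_trees[lin]
        sub.branch = root_age - sub.time
        parts.append(_newick(sub, labels))
    tree_newick = "(" + ",".join(parts) + "):0.0;"

    # metadata: geography, habitat, environment, HGT
    rng_geo = _stream(cfg, "geography")
    cents = cfg.geography.lineage_centroids or [
        (10.0 + 7.0 * k, 5.0 + 9.0 * k) for k in range(len(names))
    ]
    deg = cfg.geography.scatter_km / 111.0
    lat = np.empty(n_total)
    lon = np.empty(n_total)
    for lin, (clat, clon) in zip(names, cents):
        idx = offsets[lin]
        lat[idx] = np.clip(clat + rng_geo.normal(0, deg, len(idx)), -90, 90)
        lon[idx] = np.clip(clon + rng_geo.normal(0, deg, len(idx)), -180, 180)
    habitat = rng_geo.choice(["soil", "puddle"], size=n_total, p=[0.6, 0.4])

    rng_env = _stream(cfg, "env")
    env_vals = np.zeros((n_total, cfg.env.n_vars))
    for v in range(cfg.env.n_vars):
        env_vals[:, v] = _brownian_on_newick_parts(
            lineage_trees, names, cfg, offsets, rng_env, root_age
        )

    rng_h = _stream(cfg, "hgt")
    genome_mb = np.round(rng_h.normal(7.0, 0.3, n_total), 3)
    hgt = rng_h.poisson(cfg.hgt_rate_per_mb * genome_mb)

    import pandas as pd

    table = pd.DataFrame(
        {
            "lineage": [lineage_map[s] for s in sample_ids],
            "latitude": np.round(lat, 5),
            "longitude": np.round(lon, 5),
            "habitat": habitat,
            "hgt_count": hgt,
            "genome_size_mb": genome_mb,
            **{f"env_{v + 1}": np.round(env_vals[:, v], 6)
               for v in range(cfg.env.n_vars)},
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(table=table)

    # ANI from pairwise SNP identity
    diffs = (geno[:, None, :] != geno[None, :, :]).sum(axis=2) if geno.size \
        else np.zeros((n_total, n_total))
    ani_vals = 100.0 * (1.0 - diffs / G)
    np.fill_diagonal(ani_vals, 100.0)
    ani = AniMatrix(sample_ids=sample_ids, values=ani_vals)

    truth = _build_truth(cfg, lineage_map, events, island_iv, selected,
                         tree_newick, tract_count)
    return Bundle(
        alignment=aln,
        reference="".join(ref),
        genes=genes,
        events=events,
        metadata=metadata,
        ani=ani,
        tree_newick=tree_newick,
        truth=truth,
    )


def _brownian_on_newick_parts(lineage_trees, names, cfg, offsets, rng,
                              root_age) -> np.ndarray:
    """Brownian motion on the true tree: root value 0, variance sigma^2 * t."""
    sigma = cfg.env.brownian_sigma
    out = np.zeros(sum(cfg.samples_per_lineage))

    def walk(node: _Node, value: float, lin: str) -> None:
        value = value + rng.normal(0, sigma * math.sqrt(max(node.branch, 0.0)))
        if not node.children:
            (tip,) = node.tips
            out[offsets[lin][tip]] = value
            return
        for c in node.children:
            walk(c, value, lin)

    for lin in names:
        sub = lineage_trees[lin]
        sub.branch = root_age - sub.time
        walk(sub, 0.0, lin)
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cs, ce = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            total += ce - cs + 1
            cs, ce = s, e
    return total + ce - cs + 1


def _build_truth(cfg, lineage_map, events, island_iv, selected, tree_newick,
                 tract_count) -> TruthSet:
    names = cfg.lineage_names
    d_f = cfg.divergence * (1 - cfg.divergence / 2.0)
    exp_dxy, exp_fst, between_frac = {}, {}, {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na = cfg.samples_per_lineage[i]
            nb = cfg.samples_per_lineage[j]
            e_dxy = d_f + cfg.theta * (1 - 1 / na) + cfg.theta * (1 - 1 / nb)
            key = f"{a}|{b}"
            exp_dxy[key] = e_dxy
            exp_fst[key] = 1 - cfg.theta / e_dxy if e_dxy > 0 else math.nan
            ivs = [
                (e.start, e.end)
                for e in events
                if {lineage_map[c] for c in e.carriers} >= {a, b}
            ]
            between_frac[key] = _union_length(ivs) / cfg.genome_length
    cfg_dict = dataclasses.asdict(cfg)
    if cfg_dict.get("migration_weights"):
        cfg_dict["migration_weights"] = {
            "|".join(k): v for k, v in cfg_dict["migration_weights"].items()
        }
    return TruthSet(
        lineage_map=dict(lineage_map),
        events=list(events),
        island=island_iv,
        selected_genes=list(selected),
        tree_newick=tree_newick,
        expected_pi=cfg.theta,
        expected_dxy=exp_dxy,
        expected_fst=exp_fst,
        between_union_fraction=between_frac,
        per_strain_tract_count=dict(tract_count),
        config=cfg_dict,
    )


# ---------------------------------------------------------------------------
# Standalone tract implantation
# ---------------------------------------------------------------------------

def implant_recombination(
    aln: SnpAlignment,
    events: Sequence[RecombEvent],
    donors: Mapping[RecombEvent, str],
) -> SnpAlignment:
    """Copy the donor haplotype over each tract into every carrier.

    Overlapping tracts for the same carrier resolve last-writer-wins (event
    list order). Returns a new alignment; the input is not modified.
    """
    geno = aln.genotypes.copy()
    lookup = {s: i for i, s in enumerate(aln.sample_ids)}
    for ev in events:
        if ev.end > aln.genome_length:
            raise ValueError("tract outside genome")
        donor = donors[ev]
        if donor not in lookup:
            raise KeyError(f"unknown donor {donor!r}")
        sl = aln.site_slice(ev.start, ev.end)
        for c in sorted(ev.carriers):
            if c not in lookup:
                raise KeyError(f"unknown carrier {c!r}")
            geno[lookup[c], sl] = geno[lookup[donor], sl]
    return SnpAlignment(
        sample_ids=list(aln.sample_ids),
        positions=aln.positions.copy(),
        ref_alleles=aln.ref_alleles.copy(),
        alt_alleles=aln.alt_alleles.copy(),
        genotypes=geno,
        genome_length=aln.genome_length,
        contig_id=aln.contig_id,
    )


# ---------------------------------------------------------------------------
# Bundle output
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, str]:
    """Write the bundle to ``outdir``; returns {filename: sha256}.

    The manifest is written last, so a partial write leaves no manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = bundle.alignment
    # first record is the reference, as read_fasta_alignment expects
    seqs = {"reference": bundle.reference}
    seqs.update(aln.sequences(bundle.reference))
    files = {
        "alignment.fasta": lambda p: write_fasta_alignment(seqs, p),
        "variants.vcf": lambda p: write_snp_vcf(aln, p),
        "genes.gff3": lambda p: write_gene_gff(bundle.genes, p, aln.contig_id),
        "recombination.gff": lambda p: write_recomb_gff(
            bundle.events, p, aln.contig_id
        ),
        "tree.nwk": lambda p: Path(p).write_text(bundle.tree_newick + "\n"),
        "metadata.tsv": lambda p: write_metadata(bundle.metadata, p),
        "ani.tsv": lambda p: write_ani_matrix(bundle.ani, p),
        "truth.json": lambda p: Path(p).write_text(bundle.truth.to_json() + "\n"),
    }
    manifest: dict[str, str] = {}
    for name, writer in files.items():
        path = outdir / name
        writer(path)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True) + "\n")
    return manifest
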
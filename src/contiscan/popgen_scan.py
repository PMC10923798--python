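"""Windowed diversity, neutrality and differentiation statistics.

Implements per-window nucleotide diversity (pi), Watterson's theta,
Tajima's D, Fu's F_S, absolute divergence D_XY and the Hudson F_ST
estimator (1 - H_w/H_b), plus the dual-percentile outlier-region detector:
windows in the top quantile of *both* mean F_ST and mean D_XY across
lineage pairs are selected and merged into candidate divergence regions.

Missing genotypes are handled pairwise-complete per site: each site's mean
pairwise difference is computed over the samples called at that site.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import ALT, MISSING, REF, GeneModel, SnpAlignment

# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    size: int
    step: int

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")


def iter_windows(genome_length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """1-based inclusive windows: starts 1, 1+step, ...; short tail dropped.

    If the genome is shorter than the window size a single clamped window is
    returned with a warning.
    """
    if genome_length < spec.size:
        warnings.warn(
            f"genome_length {genome_length} < window size {spec.size}; "
            "returning one clamped window"
        )
        return [(1, genome_length)]
    out = []
    start = 1
    while start + spec.size - 1 <= genome_length:
        out.append((start, start + spec.size - 1))
        start += spec.step
    return out


# ---------------------------------------------------------------------------
# Per-site allele counts
# ---------------------------------------------------------------------------

def _allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) counts over non-missing calls for a sample subset."""
    n_ref = (geno == REF).sum(axis=0)
    n_alt = (geno == ALT).sum(axis=0)
    return n_ref.astype(np.int64), n_alt.astype(np.int64)


def _site_pi(geno: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference (pairwise-complete)."""
    n0, n1 = _allele_counts(geno)
    m = n0 + n1
    pairs = m * (m - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pairs > 0, n0 * n1 / pairs, 0.0)


# ---------------------------------------------------------------------------
# Tajima's D constants (Tajima 1989)
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d_from_counts(pi_total: float, s: int, n: int) -> float:
    """Tajima's D from the total mean pairwise difference count and S."""
    if n < 3 or s == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_total - s / c["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fu's F_S (Ewens sampling formula)
# ---------------------------------------------------------------------------

def _stirling_first_unsigned(n: int) -> np.ndarray:
    """|s(n, k)| for k = 0..n via the standard recurrence."""
    s = np.zeros((n + 1, n + 1), dtype=float)
    s[0, 0] = 1.0
    for i in range(1, n + 1):
        for k in range(1, i + 1):
            s[i, k] = s[i - 1, k - 1] + (i - 1) * s[i - 1, k]
    return s[n]


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n haplotypes under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    stir = _stirling_first_unsigned(n)
    rising = np.prod([theta + i for i in range(n)])
    k = np.arange(n + 1)
    return stir * theta**k / rising


def fus_fs_from_counts(k_obs: int, pi_total: float, n: int) -> float:
    """Fu's F_S = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = pi_total)."""
    if n < 3 or pi_total <= 0 or k_obs <= 1:
        return math.nan
    pmf = ewens_k_pmf(n, pi_total)
    s_prime = float(pmf[k_obs:].sum())
    if s_prime <= 0 or s_prime >= 1:
        return math.nan
    return math.log(s_prime / (1.0 - s_prime))


def fu_li_f_star(pi_total: float, s: int, eta_s: int, n: int) -> float:
    """Fu & Li's F* from pi, S and the singleton count eta_s (Fu & Li 1993,
    with the Simonsen et al. 1995 corrected v/u constants).

    Provided as the alternative reading of the ambiguous "Fu's F".
    """
    if n < 3 or s == 0:
        return math.nan
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    v = (
        2 * n**3 + 110 * n**2 - 255 * n + 153
    ) / (9 * n**2 * (n - 1)) + 2 * (n - 1) * an / n**2 - 8 * bn / n
    v /= an**2 + bn
    u = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1)
        / (3 * n * (n - 1))
    ) / an - v
    var = u * s + v * s * s
    if var <= 0:
        return math.nan
    return (pi_total - (n - 1) / n * eta_s) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Single-window statistics on genotype slices
# ---------------------------------------------------------------------------

def nucleotide_diversity(geno: np.ndarray, window_length: int) -> float:
    """Per-site pi over a window: total mean pairwise differences / length."""
    if geno.shape[0] < 2:
        warnings.warn("pi undefined with <2 samples")
        return math.nan
    return float(_site_pi(geno).sum()) / window_length


def segregating_sites(geno: np.ndarray) -> int:
    n0, n1 = _allele_counts(geno)
    return int(np.sum((n0 > 0) & (n1 > 0)))


def watterson_theta(geno: np.ndarray, window_length: int) -> float:
    n = geno.shape[0]
    if n < 2:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    return segregating_sites(geno) / (a1 * window_length)


def tajimas_d(geno: np.ndarray) -> float:
    n = geno.shape[0]
    pi_total = float(_site_pi(geno).sum())
    return tajimas_d_from_counts(pi_total, segregating_sites(geno), n)


def haplotype_count(geno: np.ndarray) -> int:
    """Distinct haplotypes over the window's sites (missing = its own state)."""
    if geno.shape[1] == 0:
        return 1
    return len({row.tobytes() for row in np.ascontiguousarray(geno)})


def fus_f(geno: np.ndarray, variant: str = "fs") -> float:
    """Fu's F for a window; ``variant`` = 'fs' (default) or 'fu_li_fstar'."""
    n = geno.shape[0]
    if n < 3:
        return math.nan
    pi_total = float(_site_pi(geno).sum())
    if variant == "fs":
        return fus_fs_from_counts(haplotype_count(geno), pi_total, n)
    if variant == "fu_li_fstar":
        n0, n1 = _allele_counts(geno)
        eta_s = int(np.sum(((n0 == 1) | (n1 == 1)) & (n0 > 0) & (n1 > 0)))
        return fu_li_f_star(pi_total, segregating_sites(geno), eta_s, n)
    raise ValueError(f"unknown Fu's F variant {variant!r}")


def dxy(geno_a: np.ndarray, geno_b: np.ndarray, window_length: int) -> float:
    """Mean per-site between-group pairwise difference (absolute divergence)."""
    if geno_a.shape[0] == 0 or geno_b.shape[0] == 0:
        raise ValueError("dxy requires >=1 sample per lineage")
    a0, a1 = _allele_counts(geno_a)
    b0, b1 = _allele_counts(geno_b)
    ma, mb = a0 + a1, b0 + b1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(
            (ma > 0) & (mb > 0), (a0 * b1 + a1 * b0) / (ma * mb * 1.0), 0.0
        )
    return float(per_site.sum()) / window_length


def fst_hudson(geno_a: np.ndarray, geno_b: np.ndarray, window_length: int) -> float:
    """Hudson-style F_ST = 1 - H_w/H_b; NaN when H_b = 0 or a group has <2."""
    if geno_a.shape[0] < 2 or geno_b.shape[0] < 2:
        return math.nan
    h_b = dxy(geno_a, geno_b, window_length)
    if h_b == 0:
        return math.nan
    h_w = 0.5 * (
        nucleotide_diversity(geno_a, window_length)
        + nucleotide_diversity(geno_b, window_length)
    )
    return 1.0 - h_w / h_b


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class WindowStatRecord:
    start: int
    end: int
    per_lineage: dict[str, dict[str, float]] = field(default_factory=dict)
    per_pair: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def mean_pair_stat(self, key: str) -> float:
        vals = [d[key] for d in self.per_pair.values() if np.isfinite(d[key])]
        return float(np.mean(vals)) if vals else math.nan


def _lineage_groups(
    lineage_map: Mapping[str, str], sample_ids: Sequence[str], min_n: int = 2
) -> tuple[dict[str, list[str]], list[str]]:
    """Group samples by lineage; lineages below ``min_n`` are excluded from
    population statistics (single-strain lineages, as in the study design)."""
    groups: dict[str, list[str]] = {}
    for s in sample_ids:
        if s in lineage_map:
            groups.setdefault(lineage_map[s], []).append(s)
    excluded = sorted(k for k, v in groups.items() if len(v) < min_n)
    return {k: v for k, v in groups.items() if len(v) >= min_n}, excluded


def scan_genome(
    aln: SnpAlignment,
    lineage_map: Mapping[str, str],
    specs: Mapping[str, WindowSpec],
    fus_f_variant: str = "fs",
) -> dict[str, list[WindowStatRecord]]:
    """Windowed per-lineage pi/S/theta_W/D/F and per-pair F_ST/D_XY.

    ``specs`` maps a scan name (e.g. ``"diversity"``, ``"neutrality"``) to a
    :class:`WindowSpec`; one record list is returned per scan. Lineages with a
    single sample are excluded from all population statistics.
    """
    groups, excluded = _lineage_groups(lineage_map, aln.sample_ids)
    if excluded:
        warnings.warn(f"singleton lineages excluded from scan: {excluded}")
    idx = {k: aln.sample_index(v) for k, v in groups.items()}
    lineages = sorted(groups)
    pairs = list(itertools.combinations(lineages, 2))
    out: dict[str, list[WindowStatRecord]] = {}
    for name, spec in specs.items():
        records: list[WindowStatRecord] = []
        for (ws, we) in iter_windows(aln.genome_length, spec):
            sl = aln.site_slice(ws, we)
            length = we - ws + 1
            rec = WindowStatRecord(start=ws, end=we)
            sub = {k: aln.genotypes[idx[k], sl] for k in lineages}
            for k in lineages:
                g = sub[k]
                pi_tot = float(_site_pi(g).sum())
                s = segregating_sites(g)
                rec.per_lineage[k] = {
                    "pi": pi_tot / length,
                    "S": float(s),
                    "theta_w": watterson_theta(g, length),
                    "tajima_d": tajimas_d_from_counts(pi_tot, s, g.shape[0]),
                    "fu_f": fus_f(g, variant=fus_f_variant),
                }
            for a, b in pairs:
                d = dxy(sub[a], sub[b], length)
                rec.per_pair[(a, b)] = {
                    "dxy": d,
                    "fst": fst_hudson(sub[a], sub[b], length),
                }
            records.append(rec)
        out[name] = records
    return out


# ---------------------------------------------------------------------------
# Departure-from-zero t test
# ---------------------------------------------------------------------------

def neutrality_departure_test(values: Sequence[float]) -> dict[str, float]:
    """One-sample two-sided t test of per-window neutrality values against 0."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size < 2:
        raise ValueError("need >=2 non-NaN window values")
    if np.ptp(v) == 0:
        t = 0.0 if v[0] == 0 else math.nan
        p = 1.0 if v[0] == 0 else math.nan
        warnings.warn("zero-variance window values; t undefined unless mean 0")
        return {"mean": float(v.mean()), "t": t, "p": p, "n": int(v.size)}
    t, p = sps.ttest_1samp(v, 0.0)
    return {"mean": float(v.mean()), "t": float(t), "p": float(p), "n": int(v.size)}


# ---------------------------------------------------------------------------
# Outlier regions
# ---------------------------------------------------------------------------

@dataclass
class OutlierRegion:
    start: int
    end: int
    windows: list[tuple[int, int]]
    mean_fst: float
    mean_dxy: float
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _quantile_threshold(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile over finite values."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return math.inf
    return float(np.quantile(finite, q))


def outlier_regions(
    records: Sequence[WindowStatRecord],
    q: float = 0.99,
    genes: Sequence[GeneModel] = (),
    pair: tuple[str, str] | None = None,
) -> list[OutlierRegion]:
    """Divergence-outlier regions: windows in the top ``q`` quantile of both
    F_ST and D_XY (aggregated as the mean across lineage pairs, or a single
    pair if given), merged when overlapping or adjacent, with overlapping
    genes attached. Ties at the threshold are included.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if len(records) < 100:
        warnings.warn(
            f"only {len(records)} windows; quantile q={q} is coarse below 100"
        )
    if pair is None:
        fst = np.array([r.mean_pair_stat("fst") for r in records])
        dxy_v = np.array([r.mean_pair_stat("dxy") for r in records])
    else:
        key = tuple(sorted(pair))
        fst = np.array([r.per_pair[key]["fst"] for r in records])
        dxy_v = np.array([r.per_pair[key]["dxy"] for r in records])
    t_fst = _quantile_threshold(fst, q)
    t_dxy = _quantile_threshold(dxy_v, q)
    selected = [
        i
        for i in range(len(records))
        if np.isfinite(fst[i]) and np.isfinite(dxy_v[i])
        and fst[i] >= t_fst and dxy_v[i] >= t_dxy
    ]
    regions: list[OutlierRegion] = []
    for i in selected:
        r = records[i]
        if regions and r.start <= regions[-1].end + 1:
            last = regions[-1]
            last.end = max(last.end, r.end)
            last.windows.append((r.start, r.end))
        else:
            regions.append(
                OutlierRegion(start=r.start, end=r.end,
                              windows=[(r.start, r.end)],
                              mean_fst=math.nan, mean_dxy=math.nan)
            )
    by_window = {(r.start, r.end): i for i, r in enumerate(records)}
    for reg in regions:
        ids = [by_window[w] for w in reg.windows]
        reg.mean_fst = float(np.nanmean(fst[ids]))
        reg.mean_dxy = float(np.nanmean(dxy_v[ids]))
        reg.gene_ids = sorted(
            g.gene_id for g in genes if g.start <= reg.end and g.end >= reg.start
        )
    return regions


def jaccard_interval(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two 1-based inclusive intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0
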
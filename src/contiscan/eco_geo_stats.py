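"""Isolation-by-distance / isolation-by-environment statistics.

Distance matrices (genetic 1-ANI, geographic great-circle km, environmental
Euclidean on z-scored variables), seed-reproducible Mantel permutation
tests, phylogenetic signal (Blomberg's K, Pagel's lambda), Kruskal-Wallis
with Dunn's Bonferroni post hoc, single-linkage ANI clustering, and
HGT-per-Mb normalization.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .io_formats import AniMatrix, SampleMetadata

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.label)

    def condensed(self) -> np.ndarray:
        """Lower-triangle vector (row-major over i > j)."""
        n = len(self.sample_ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on the mean-radius sphere, in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geo_distance_matrix(metadata: SampleMetadata) -> DistanceMatrix:
    t = metadata.table
    lat = t["latitude"].to_numpy(dtype=float)
    lon = t["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    n = len(t)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(lat[i], lon[i], lat[j], lon[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(metadata.sample_ids, vals, "geographic(km)")


def genetic_distance_matrix(ani: AniMatrix) -> DistanceMatrix:
    """1 - ANI distance, with ANI rescaled to a fraction: (100 - ANI)/100."""
    vals = (100.0 - ani.values) / 100.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(ani.sample_ids), vals, "genetic(1-ANI)")


def env_distance_matrix(
    metadata: SampleMetadata, columns: Sequence[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over (z-scored) environmental variables."""
    cols = list(columns) if columns is not None else metadata.env_columns()
    if not cols:
        raise ValueError("no environmental columns")
    x = metadata.table[cols].to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    diff = x[:, None, :] - x[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(metadata.sample_ids, vals, "environmental(euclidean)")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    alternative: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of the Pearson correlation between the lower
    triangles of two distance matrices.

    One matrix's rows/columns are label-permuted; p = (#{r_perm as or more
    extreme} + 1)/(n_perm + 1), so p >= 1/(n_perm + 1).
    """
    if d1.sample_ids != d2.sample_ids:
        if set(d1.sample_ids) != set(d2.sample_ids):
            raise ValueError("sample sets differ")
        d2 = d2.subset(d1.sample_ids)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = d1.condensed()
    y = d2.condensed()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance distance triangle")
        return MantelResult(math.nan, math.nan, n_perm, alternative)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(d1.sample_ids)
    iu = np.triu_indices(n, k=1)
    m2 = d2.values
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][iu]
        okp = np.isfinite(d1.values[iu]) & np.isfinite(yp)
        r_p = np.corrcoef(d1.values[iu][okp], yp[okp])[0, 1]
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm,
                        alternative=alternative)


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def tree_covariance(tree, tip_order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix: V[i, j] = shared root-to-MRCA path
    length of tips i and j (dendropy tree, branch lengths required)."""
    import dendropy

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in tip_order if s not in taxa]
    if missing:
        raise KeyError(f"tips not in tree: {missing[:5]}")
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    n = len(tip_order)
    v = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        v[i, i] = depth[a]
        for j in range(i + 1, n):
            b = tip_order[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            v[i, j] = v[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return v


def _phylo_mean(v_inv: np.ndarray, x: np.ndarray) -> float:
    one = np.ones(len(x))
    return float(one @ v_inv @ x / (one @ v_inv @ one))


def _k_ratio(x: np.ndarray, v_inv: np.ndarray) -> float:
    """Observed MSE0/MSE given trait values and V^-1."""
    n = len(x)
    a_hat = _phylo_mean(v_inv, x)
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ v_inv @ resid) / (n - 1)
    return mse0 / mse


def blomberg_k(
    tree, trait: Mapping[str, float], n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Blomberg's K with a tip-shuffling permutation p value.

    K is the observed MSE0/MSE ratio divided by its Brownian expectation
    (tr(V) - n/(1'V^-1 1))/(n - 1); K = 1 under Brownian motion, smaller for
    traits with less signal than Brownian motion implies.
    """
    tips = sorted(trait)
    x = np.array([trait[t] for t in tips], dtype=float)
    if x.std() == 0:
        return math.nan, math.nan
    v = tree_covariance(tree, tips)
    v_inv = np.linalg.inv(v)
    n = len(x)
    one = np.ones(n)
    expected = (np.trace(v) - n / float(one @ v_inv @ one)) / (n - 1)
    obs = _k_ratio(x, v_inv)
    k = obs / expected
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _k_ratio(rng.permutation(x), v_inv) >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(k), float(p)


def _lambda_loglik(lam: float, x: np.ndarray, v: np.ndarray) -> float:
    """Profile log-likelihood of lambda (sigma^2 and the root state profiled
    out) for the covariance with off-diagonals scaled by lambda."""
    n = len(x)
    vl = v * lam
    np.fill_diagonal(vl, np.diag(v))
    sign, logdet = np.linalg.slogdet(vl)
    if sign <= 0:
        return -math.inf
    v_inv = np.linalg.inv(vl)
    a_hat = _phylo_mean(v_inv, x)
    resid = x - a_hat
    q = float(resid @ v_inv @ resid)
    if q <= 0:
        return -math.inf
    sigma2 = q / n
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def pagel_lambda(
    tree, trait: Mapping[str, float]
) -> tuple[float, float, float]:
    """ML Pagel's lambda in [0, 1] with a boundary-corrected LRT vs lambda=0.

    Returns (lambda_hat, loglik, p). The LRT p uses the 50:50 chi2_0/chi2_1
    mixture because lambda = 0 sits on the parameter boundary.
    """
    tips = sorted(trait)
    x = np.array([trait[t] for t in tips], dtype=float)
    if x.std() == 0:
        raise ValueError("zero trait variance")
    v = tree_covariance(tree, tips)
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, x, v),
        bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the optimum can sit at a boundary the bounded optimizer never probes
    for cand in (0.0, 1.0):
        ll_c = _lambda_loglik(cand, x, v)
        if ll_c > ll_hat:
            lam_hat, ll_hat = cand, ll_c
    ll0 = _lambda_loglik(0.0, x, v)
    lr = max(0.0, 2 * (ll_hat - ll0))
    p = 0.5 * sps.chi2.sf(lr, df=1) if lr > 0 else 1.0
    return lam_hat, ll_hat, float(p)


@dataclass
class SignalResult:
    trait: str
    lam: float
    lambda_p: float
    k: float
    k_p: float
    n_perm: int


def phylogenetic_signal(
    tree, traits: pd.DataFrame, n_perm: int = 999, seed: int | None = None,
) -> list[SignalResult]:
    """Pagel's lambda and Blomberg's K for every trait column."""
    out = []
    for i, col in enumerate(traits.columns):
        trait = dict(traits[col].astype(float))
        lam, _, lam_p = pagel_lambda(tree, trait)
        k, k_p = blomberg_k(
            tree, trait, n_perm=n_perm,
            seed=None if seed is None else seed + i,
        )
        out.append(SignalResult(trait=col, lam=lam, lambda_p=lam_p, k=k,
                                k_p=k_p, n_perm=n_perm))
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p value."""
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2:
        raise ValueError("need >=2 groups")
    allv = np.concatenate(vals)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*vals)
    return float(h), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank test with Bonferroni adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with the
    tie term T = sum(t^3 - t)/(12(N - 1)); two-sided normal p multiplied by
    the number of pairs, capped at 1.
    """
    keys = [k for k, v in groups.items() if len(v) > 0]
    dropped = [k for k in groups if k not in keys]
    if dropped:
        warnings.warn(f"dropping empty groups {dropped}")
    vals = {k: np.asarray(groups[k], dtype=float) for k in keys}
    allv = np.concatenate([vals[k] for k in keys])
    n_total = len(allv)
    ranks = sps.rankdata(allv)
    mean_rank = {}
    pos = 0
    for k in keys:
        n_k = len(vals[k])
        mean_rank[k] = ranks[pos : pos + n_k].mean()
        pos += n_k
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0
    base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(keys, 2))
    rows = []
    m = len(pairs)
    for a, b in pairs:
        se = math.sqrt(base * (1.0 / len(vals[a]) + 1.0 / len(vals[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group1": a, "group2": b, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANI clustering
# ---------------------------------------------------------------------------

def ani_cluster(ani: AniMatrix, threshold: float = 95.0) -> dict[str, int]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever ANI >= threshold. Missing pairs count as below threshold."""
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    vals = ani.values
    if np.isnan(vals).any():
        warnings.warn("missing ANI pairs treated as below threshold")
    with np.errstate(invalid="ignore"):
        adj = (vals >= threshold) & np.isfinite(vals)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return {s: int(l) for s, l in zip(ani.sample_ids, labels)}


# ---------------------------------------------------------------------------
# HGT normalization
# ---------------------------------------------------------------------------

def hgt_per_mb(metadata: SampleMetadata) -> dict:
    """HGT counts normalized per Mb, with count-vs-size correlations and
    lineage/habitat group tests."""
    t = metadata.table
    if "hgt_count" not in t.columns or "genome_size_mb" not in t.columns:
        raise ValueError("metadata lacks hgt_count / genome_size_mb")
    size = t["genome_size_mb"].to_numpy(dtype=float)
    if np.any(size <= 0):
        raise ValueError("genome_size_mb must be positive")
    count = t["hgt_count"].to_numpy(dtype=float)
    rate = count / size
    rho, rho_p = sps.spearmanr(count, size)
    r, r_p = sps.pearsonr(count, size)
    out = {
        "rate_per_mb": pd.Series(rate, index=t.index, name="hgt_per_mb"),
        "spearman_rho": float(rho), "spearman_p": float(rho_p),
        "pearson_r": float(r), "pearson_p": float(r_p),
    }
    for col in ("lineage", "habitat"):
        if col in t.columns:
            groups = {
                str(k): v["__rate"].tolist()
                for k, v in t.assign(__rate=rate).groupby(col)
                if len(v) >= 2
            }
            if len(groups) >= 2:
                h, p = kruskal_wallis(groups)
                out[f"{col}_kw"] = {"H": h, "p": p}
                out[f"{col}_dunn"] = dunn_posthoc(groups)
    return out
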
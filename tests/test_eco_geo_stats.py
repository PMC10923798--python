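"""Distance matrices, Mantel, phylogenetic signal, group tests, clustering."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import contiscan as cs
from contiscan import eco_geo_stats as eco


def meta(rows: dict) -> cs.SampleMetadata:
    df = pd.DataFrame(rows)
    df.index = [f"s{i}" for i in range(len(df))]
    if "lineage" not in df:
        df["lineage"] = "A"
    if "latitude" not in df:
        df["latitude"] = 0.0
    if "longitude" not in df:
        df["longitude"] = 0.0
    return cs.SampleMetadata(table=df)


def balanced_tree(depth: int, branch: float = 1.0,
                  tip_branch: float | None = None) -> dendropy.Tree:
    n = 2**depth
    labels = [f"t{i}" for i in range(n)]
    tb = branch if tip_branch is None else tip_branch

    def build(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{tb}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch}"

    nwk = build(0, n) + ";"
    return dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)


def star_tree(n: int, branch: float = 2.0) -> dendropy.Tree:
    nwk = "(" + ",".join(f"t{i}:{branch}" for i in range(n)) + ");"
    return dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)


def simulate_bm(tree: dendropy.Tree, rng, sigma: float = 1.0) -> dict:
    vals = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = vals[id(parent)] if parent is not None else 0.0
        bl = node.edge.length or 0.0
        vals[id(node)] = base + rng.normal(0, sigma * math.sqrt(bl))
    return {leaf.taxon.label: vals[id(leaf)]
            for leaf in tree.leaf_node_iter()}


class TestGeoDistance:
    def test_identical_coordinates_zero(self):
        assert eco.haversine_km(10, 20, 10, 20) == 0.0

    def test_quarter_circle(self):
        assert eco.haversine_km(0, 0, 0, 90) == pytest.approx(
            math.pi / 2 * 6371.0088, abs=1e-6)

    def test_antipodes(self):
        assert eco.haversine_km(0, 0, 0, 180) == pytest.approx(
            math.pi * 6371.0088, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(-90, 90, 3)
        lon = rng.uniform(-180, 180, 3)
        d01 = eco.haversine_km(lat[0], lon[0], lat[1], lon[1])
        d12 = eco.haversine_km(lat[1], lon[1], lat[2], lon[2])
        d02 = eco.haversine_km(lat[0], lon[0], lat[2], lon[2])
        assert d02 <= d01 + d12 + 1e-6

    def test_matrix_from_metadata(self):
        m = meta({"latitude": [0.0, 0.0], "longitude": [0.0, 90.0]})
        d = eco.geo_distance_matrix(m)
        assert d.values[0, 1] == pytest.approx(math.pi / 2 * 6371.0088,
                                               abs=1e-6)


class TestGeneticEnvDistance:
    def test_one_minus_ani_scaling(self):
        ani = cs.AniMatrix(["a", "b"], np.array([[100.0, 95.0],
                                                 [95.0, 100.0]]))
        d = eco.genetic_distance_matrix(ani)
        assert d.values[0, 1] == pytest.approx(0.05)

    def test_env_zscore_euclidean(self):
        m = meta({"env_1": [0.0, 2.0, 4.0], "env_2": [1.0, 1.0, 1.0]})
        d = eco.env_distance_matrix(m)
        # constant column contributes nothing; z-scores of 0,2,4 are -1,0,1
        assert d.values[0, 2] == pytest.approx(2.0)


class TestMantel:
    def _dm(self, vals, label=""):
        ids = [f"s{i}" for i in range(vals.shape[0])]
        return eco.DistanceMatrix(ids, vals, label)

    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (10, 10))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        r1 = self._dm(x)
        r2 = self._dm(2 * x)
        res = cs.mantel_test(r1, r2, n_perm=9_999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 10_000  # minimum attainable p with 9999 perms

    def test_r_equals_direct_pearson(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(0, 1, (8, 8))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        res = cs.mantel_test(self._dm(a), self._dm(b), n_perm=99, seed=0)
        iu = np.triu_indices(8, 1)
        expected = np.corrcoef(a[iu], b[iu])[0, 1]
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (9, 9))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = np.roll(a, 1, axis=0)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        p1 = cs.mantel_test(self._dm(a), self._dm(b), n_perm=999, seed=7).p
        p2 = cs.mantel_test(self._dm(a), self._dm(b), n_perm=999, seed=7).p
        assert p1 == p2

    def test_null_p_roughly_uniform(self):
        """Under independence the permutation p value is ~Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(120):
            a = rng.uniform(0, 1, (9, 9))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.uniform(0, 1, (9, 9))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            pvals.append(cs.mantel_test(self._dm(a), self._dm(b),
                                        n_perm=199, seed=0).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_size_mismatch_error(self):
        a = self._dm(np.zeros((3, 3)))
        ids = ["x0", "x1", "x2", "x3"]
        b = eco.DistanceMatrix(ids, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            cs.mantel_test(a, b, n_perm=99)


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        """On a star tree V = cI, so K = 1 exactly for any trait."""
        tree = star_tree(12)
        rng = np.random.default_rng(0)
        trait = {f"t{i}": float(rng.normal()) for i in range(12)}
        k, _ = cs.blomberg_k(tree, trait, n_perm=99, seed=0)
        assert k == pytest.approx(1.0, abs=1e-10)

    def test_bm_traits_mean_k_near_one(self):
        """BM traits on a 64-tip balanced tree give mean K ~ 1."""
        tree = balanced_tree(6)
        rng = np.random.default_rng(2)
        ks = []
        for _ in range(60):
            trait = simulate_bm(tree, rng)
            k, _ = cs.blomberg_k(tree, trait, n_perm=0 + 99, seed=0)
            ks.append(k)
        ks = np.array(ks)
        se = ks.std(ddof=1) / math.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 3 * se

    def test_shuffled_traits_low_k(self):
        tree = balanced_tree(5)
        rng = np.random.default_rng(3)
        low = 0
        for _ in range(40):
            trait = simulate_bm(tree, rng)
            vals = rng.permutation(list(trait.values()))
            shuffled = dict(zip(trait.keys(), map(float, vals)))
            k, _ = cs.blomberg_k(tree, shuffled, n_perm=99, seed=0)
            low += k < 1
        assert low >= 38  # >= 95% of replicates

    def test_zero_variance_nan(self):
        tree = star_tree(5)
        k, p = cs.blomberg_k(tree, {f"t{i}": 1.0 for i in range(5)})
        assert math.isnan(k)


class TestPagelLambda:
    def test_white_noise_low_lambda(self):
        tree = balanced_tree(5)
        rng = np.random.default_rng(4)
        lams = []
        for _ in range(40):
            trait = {f"t{i}": float(rng.normal()) for i in range(32)}
            lam, _, _ = cs.pagel_lambda(tree, trait)
            lams.append(lam)
        assert np.median(lams) <= 0.1

    def test_bm_high_lambda(self):
        # short terminal branches (densely sampled clades) make lambda
        # well identified; cross-checked against R phytools::phylosig
        tree = balanced_tree(6, tip_branch=0.3)
        rng = np.random.default_rng(5)
        high = 0
        for _ in range(40):
            lam, _, _ = cs.pagel_lambda(tree, simulate_bm(tree, rng))
            high += lam >= 0.9
        assert high >= 36  # >= 90%

    def test_location_invariance(self):
        tree = balanced_tree(4)
        rng = np.random.default_rng(6)
        trait = simulate_bm(tree, rng)
        lam1, _, _ = cs.pagel_lambda(tree, trait)
        lam2, _, _ = cs.pagel_lambda(tree, {k: v + 100.0
                                            for k, v in trait.items()})
        assert lam1 == pytest.approx(lam2, abs=1e-5)

    def test_loglik_matches_dense_grid(self):
        """Optimized lambda beats (or ties) a dense brute-force grid of the
        profile likelihood on a small tree."""
        tree = balanced_tree(4)
        rng = np.random.default_rng(7)
        trait = simulate_bm(tree, rng)
        lam_hat, ll_hat, _ = cs.pagel_lambda(tree, trait)
        tips = sorted(trait)
        x = np.array([trait[t] for t in tips])
        v = eco.tree_covariance(tree, tips)
        grid = [eco._lambda_loglik(l, x, v) for l in np.linspace(0, 1, 401)]
        assert ll_hat >= max(grid) - 1e-6


class TestGroupTests:
    def test_identical_groups(self):
        h, p = cs.kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert p > 0.5

    def test_hand_ranked_formula(self):
        """{1,2,3} vs {4,5,6}: H = 12/(6*7)*(3*4 + 3*25) - 3*7 = 3.857..."""
        h, _ = cs.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(12 / 42 * (3 * 4 + 3 * 25) - 21, abs=1e-9)

    def test_monotone_transform_invariance(self):
        g1 = {"a": [1.0, 2.0, 5.0], "b": [3.0, 8.0, 9.0]}
        g2 = {k: [math.exp(v) for v in vals] for k, vals in g1.items()}
        assert cs.kruskal_wallis(g1)[0] == pytest.approx(
            cs.kruskal_wallis(g2)[0])

    def test_all_identical_values(self):
        h, p = cs.kruskal_wallis({"a": [2, 2], "b": [2, 2]})
        assert h == 0.0 and p == 1.0

    def test_dunn_identical_groups(self):
        res = cs.dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert (res["p_adj"] == 1.0).all()

    def test_dunn_extreme_group_smallest_p(self):
        """Formula oracle: the extreme pair carries the smallest adjusted p,
        and z matches the hand-computed rank statistic."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
                  "c": [50.0, 60.0, 70.0]}
        res = cs.dunn_posthoc(groups).set_index(["group1", "group2"])
        assert res["p_adj"].idxmin() == ("a", "c")
        # hand computation for pair (a, c): mean ranks 2 and 8, N=9, no ties
        se = math.sqrt((9 * 10 / 12) * (2 / 3))
        z_expected = (2 - 8) / se
        assert res.loc[("a", "c"), "z"] == pytest.approx(z_expected, abs=1e-12)

    def test_bonferroni_monotonicity(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(size=5).tolist() for k in "abcd"}
        res = cs.dunn_posthoc(groups)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()


class TestAniCluster:
    def _ani(self, vals, ids=None):
        vals = np.asarray(vals, dtype=float)
        return cs.AniMatrix(ids or [f"s{i}" for i in range(len(vals))], vals)

    def test_two_blocks(self):
        vals = np.full((4, 4), 90.0)
        for i, j in [(0, 1), (2, 3)]:
            vals[i, j] = vals[j, i] = 97.0
        np.fill_diagonal(vals, 100.0)
        labels = cs.ani_cluster(self._ani(vals), threshold=95)
        assert labels["s0"] == labels["s1"] != labels["s2"]
        assert labels["s2"] == labels["s3"]

    def test_single_linkage_chain(self):
        vals = np.array([[100.0, 96, 90], [96, 100, 96], [90, 96, 100]])
        labels = cs.ani_cluster(self._ani(vals), threshold=95)
        assert len(set(labels.values())) == 1

    def test_threshold_above_all(self):
        vals = np.array([[100.0, 96.0], [96.0, 100.0]])
        labels = cs.ani_cluster(self._ani(vals), threshold=99.9)
        assert len(set(labels.values())) == 2


class TestHgt:
    def test_rate_normalization(self):
        m = meta({"hgt_count": [7000, 100], "genome_size_mb": [7.0, 1.0]})
        res = cs.hgt_per_mb(m)
        assert res["rate_per_mb"].iloc[0] == pytest.approx(1000.0)

    def test_proportional_counts_rho_one(self):
        m = meta({"hgt_count": [100, 200, 300, 400],
                  "genome_size_mb": [1.0, 2.0, 3.0, 4.0]})
        res = cs.hgt_per_mb(m)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["rate_per_mb"].nunique() == 1

    def test_poisson_noise_correlation(self):
        """Spearman rho under Poisson noise matches an independent
        simulation of the same generative model."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        sizes = rng.normal(7, 0.5, 200).clip(5, 9)
        counts = rng.poisson(50 * sizes)
        m = meta({"hgt_count": counts, "genome_size_mb": sizes})
        res = cs.hgt_per_mb(m)
        oracle = []
        for _ in range(200):
            s = rng.normal(7, 0.5, 200).clip(5, 9)
            c = rng.poisson(50 * s)
            oracle.append(spearmanr(c, s).statistic)
        se = np.std(oracle, ddof=1)
        assert abs(res["spearman_rho"] - np.mean(oracle)) < 3 * se

    def test_bad_size_error(self):
        m = meta({"hgt_count": [10], "genome_size_mb": [0.0]})
        with pytest.raises(ValueError):
            cs.hgt_per_mb(m)
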
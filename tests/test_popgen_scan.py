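"""Windowed statistics against brute-force oracles and known values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import contiscan as cs
from contiscan import popgen_scan as pg

from conftest import (
    brute_dxy,
    brute_fst,
    brute_pair_diffs,
    brute_pi,
    brute_S,
    brute_tajima_d,
    brute_watterson,
    random_alignment,
)


def g(rows):  # tiny genotype-matrix helper
    return np.array(rows, dtype=np.int8)


class TestWindows:
    @pytest.mark.parametrize(
        "glen,size,step,expected",
        [
            (100_000, 50_000, 12_500, 5),
            (50_000, 50_000, 12_500, 1),
            (59_999, 50_000, 12_500, 1),  # short tail dropped
        ],
    )
    def test_window_counts(self, glen, size, step, expected):
        wins = cs.iter_windows(glen, pg.WindowSpec(size, step))
        assert len(wins) == expected
        assert wins[0] == (1, size)
        assert wins[-1][1] <= glen

    def test_first_and_last_window(self):
        wins = cs.iter_windows(100_000, pg.WindowSpec(50_000, 12_500))
        assert wins[0] == (1, 50_000) and wins[-1] == (50_001, 100_000)

    def test_short_genome_clamped(self):
        with pytest.warns(UserWarning):
            wins = cs.iter_windows(30_000, pg.WindowSpec(50_000, 12_500))
        assert wins == [(1, 30_000)]

    @given(glen=st.integers(1_000, 500_000), size=st.integers(100, 50_000),
           step_frac=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_window_invariants(self, glen, size, step_frac):
        step = max(1, int(size * step_frac))
        if glen < size:
            return
        wins = cs.iter_windows(glen, pg.WindowSpec(size, step))
        assert all(e - s + 1 == size for s, e in wins)
        starts = [s for s, _ in wins]
        assert starts == sorted(starts)
        assert all(b - a == step for a, b in zip(starts, starts[1:]))
        assert wins[-1][1] + step > glen  # no further full window fits


class TestDiversity:
    def test_identical_pair_zero(self):
        assert cs.nucleotide_diversity(g([[0, 0], [0, 0]]), 10) == 0.0

    def test_two_seqs_two_diffs(self):
        assert cs.nucleotide_diversity(g([[0, 0], [1, 1]]), 10) == pytest.approx(0.2)

    def test_three_singletons_four_samples(self):
        """3 singleton SNPs in n=4: 6 pairs, mean pairwise diffs = 1.5."""
        geno = g([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        total, _ = brute_pair_diffs(geno)
        assert total == pytest.approx(1.5)
        assert cs.nucleotide_diversity(geno, 100) == pytest.approx(0.015)

    def test_single_sample_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(cs.nucleotide_diversity(g([[0, 1]]), 10))

    def test_monomorphic_site_changes_nothing(self, rng):
        aln = random_alignment(rng, 6, 30, 300)
        geno = aln.genotypes
        with_mono = np.hstack([geno, np.zeros((6, 1), dtype=np.int8)])
        assert cs.nucleotide_diversity(geno, 300) == \
            cs.nucleotide_diversity(with_mono, 300)
        assert cs.tajimas_d(geno) == cs.tajimas_d(with_mono)


class TestTajimasD:
    def test_no_segregating_sites_nan(self):
        assert math.isnan(cs.tajimas_d(g([[0, 0], [0, 0], [0, 0]])))

    def test_worked_example_three_singletons(self):
        """n=4 with 3 singletons: D = -0.754 (independent constants oracle)."""
        geno = g([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        d = cs.tajimas_d(geno)
        assert d == pytest.approx(brute_tajima_d(geno), abs=1e-12)
        assert d == pytest.approx(-0.754, abs=1e-3)

    def test_neutral_simulation_mean_near_zero(self):
        """Mean Tajima's D over neutral coalescent replicates is ~0."""
        vals = []
        for seed in range(120):
            cfg = cs.SimConfig(
                seed=seed, n_lineages=1, samples_per_lineage=[20],
                genome_length=20_000, theta=0.005, tract_rate=0.0,
                genes=cs.GeneConfig(n_genes=0), outgroup_divergence=0.0,
            )
            b = cs.simulate_continuum(cfg)
            vals.append(cs.tajimas_d(b.alignment.genotypes))
        vals = np.array(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 0.05


class TestFusF:
    def test_monomorphic_nan(self):
        assert math.isnan(cs.fus_f(g([[0, 0], [0, 0], [0, 0], [0, 0]])))

    def test_ewens_enumeration_oracle(self):
        """n=4, 4 distinct haplotypes, theta=1.5: F_S from exhaustive Ewens
        probabilities with the Stirling table for n=4 (|s(4,k)| = 6,11,6,1)."""
        theta = 1.5
        stirling = {1: 6, 2: 11, 3: 6, 4: 1}
        rising = theta * (theta + 1) * (theta + 2) * (theta + 3)
        pk = {k: stirling[k] * theta**k / rising for k in stirling}
        assert sum(pk.values()) == pytest.approx(1.0)
        s_prime = pk[4]
        expected = math.log(s_prime / (1 - s_prime))
        # genotype matrix with 4 distinct haplotypes and pi_total = 1.5
        geno = g([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        assert brute_pair_diffs(geno)[0] == pytest.approx(1.5)
        assert cs.fus_f(geno) == pytest.approx(expected, abs=1e-12)

    def test_fu_li_variant_available(self):
        geno = g([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        val = cs.fus_f(geno, variant="fu_li_fstar")
        assert np.isfinite(val)


class TestDxyFst:
    def test_monomorphic_lineages(self):
        a = g([[1, 1, 1] + [0] * 7] * 3)
        b = g([[0, 0, 0] + [0] * 7] * 3)
        assert cs.dxy(a, b, 10) == pytest.approx(0.3)

    def test_dxy_equals_pooled_pi_for_identical_groups(self, rng):
        """With A and B holding the same haplotype set, D_XY equals the
        brute-force mean cross-pair difference."""
        geno = rng.integers(0, 2, size=(4, 50)).astype(np.int8)
        assert cs.dxy(geno, geno, 100) == pytest.approx(
            brute_dxy(geno, geno, 100), abs=1e-12)

    def test_fixed_difference_fst_one(self):
        a = g([[0]] * 3)
        b = g([[1]] * 3)
        assert cs.fst_hudson(a, b, 1) == 1.0

    def test_identical_monomorphic_nan(self):
        a = g([[0, 0]] * 2)
        assert math.isnan(cs.fst_hudson(a, a, 10))

    def test_one_site_mixed_oracle(self):
        """A=(A,A,A,T), B=(T,T,T,A) at one site: value from all-pairs
        enumeration (6+6 within, 16 cross pairs)."""
        a = g([[0], [0], [0], [1]])
        b = g([[1], [1], [1], [0]])
        assert cs.fst_hudson(a, b, 1) == pytest.approx(
            brute_fst(a, b, 1), abs=1e-12)
        # closed form: Hw = (3/6 + 3/6)/2 = 0.5, Hb = 10/16
        assert cs.fst_hudson(a, b, 1) == pytest.approx(1 - 0.5 / (10 / 16))

    def test_symmetry(self, rng):
        a = rng.integers(0, 2, size=(3, 40)).astype(np.int8)
        b = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        assert cs.dxy(a, b, 50) == cs.dxy(b, a, 50)
        assert cs.fst_hudson(a, b, 50) == cs.fst_hudson(b, a, 50)


class TestBruteForceEquivalence:
    """Vectorized statistics equal O(n^2 L) loops on random fixtures,
    including missing data."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        L = int(rng.integers(20, 200))
        aln = random_alignment(rng, n, min(L, 150), L + 50,
                               missing_frac=0.1 if seed % 2 else 0.0)
        geno = aln.genotypes
        length = aln.genome_length
        assert cs.nucleotide_diversity(geno, length) == pytest.approx(
            brute_pi(geno, length), abs=1e-12)
        assert pg.segregating_sites(geno) == brute_S(geno)
        assert cs.watterson_theta(geno, length) == pytest.approx(
            brute_watterson(geno, length), abs=1e-12)
        d = cs.tajimas_d(geno)
        bd = brute_tajima_d(geno)
        assert (math.isnan(d) and math.isnan(bd)) or d == pytest.approx(
            bd, abs=1e-12)


class TestScanGenome:
    def test_island_has_max_dxy(self, demo_bundle):
        recs = cs.scan_genome(
            demo_bundle.alignment, demo_bundle.truth.lineage_map,
            {"div": pg.WindowSpec(5_000, 2_500)},
        )["div"]
        mean_dxy = [r.mean_pair_stat("dxy") for r in recs]
        best = recs[int(np.nanargmax(mean_dxy))]
        island = demo_bundle.truth.island
        assert best.start >= island[0] - 5_000 and best.end <= island[1] + 5_000

    def test_singleton_lineage_excluded(self, rng):
        aln = random_alignment(rng, 5, 50, 1_000)
        lmap = {"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "C"}
        with pytest.warns(UserWarning):
            recs = cs.scan_genome(aln, lmap,
                                  {"w": pg.WindowSpec(1_000, 1_000)})["w"]
        assert set(recs[0].per_lineage) == {"A"}
        assert recs[0].per_pair == {}

    def test_sample_order_invariance(self, rng):
        aln = random_alignment(rng, 6, 60, 1_000)
        lmap = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        perm = [3, 0, 5, 1, 4, 2]
        aln2 = cs.SnpAlignment(
            sample_ids=[aln.sample_ids[i] for i in perm],
            positions=aln.positions, ref_alleles=aln.ref_alleles,
            alt_alleles=aln.alt_alleles, genotypes=aln.genotypes[perm],
            genome_length=aln.genome_length)
        spec = {"w": pg.WindowSpec(500, 250)}
        r1 = cs.scan_genome(aln, lmap, spec)["w"]
        r2 = cs.scan_genome(aln2, lmap, spec)["w"]
        for a, b in zip(r1, r2):
            assert a.per_lineage == b.per_lineage
            assert a.per_pair == b.per_pair


class TestDepartureTest:
    def test_symmetric_values(self):
        res = cs.neutrality_departure_test([-1, 1, -1, 1])
        assert res["t"] == 0 and res["p"] == pytest.approx(1.0)

    def test_constant_nonzero_flagged(self):
        with pytest.warns(UserWarning):
            res = cs.neutrality_departure_test([0.5, 0.5, 0.5])
        assert math.isnan(res["t"])

    def test_closed_form_t(self):
        """{0.2,0.4,0.6,0.8}: t and p from the textbook one-sample formula."""
        vals = [0.2, 0.4, 0.6, 0.8]
        mean = sum(vals) / 4
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 3)
        t_expected = mean / (sd / 2)
        res = cs.neutrality_departure_test(vals)
        assert res["t"] == pytest.approx(t_expected, abs=1e-12)
        from scipy.stats import t as tdist
        assert res["p"] == pytest.approx(2 * tdist.sf(t_expected, 3), abs=1e-12)

    def test_all_nan_error(self):
        with pytest.raises(ValueError):
            cs.neutrality_departure_test([math.nan, math.nan])


class TestOutlierRegions:
    def _records(self, fst_vals, dxy_vals, size=1_000):
        recs = []
        for i, (f, d) in enumerate(zip(fst_vals, dxy_vals)):
            r = pg.WindowStatRecord(start=i * size + 1, end=(i + 1) * size)
            r.per_pair[("A", "B")] = {"fst": f, "dxy": d}
            recs.append(r)
        return recs

    @staticmethod
    def _background(n, lo, hi):
        # strictly increasing background so quantile thresholds are not tied
        return list(np.linspace(lo, hi, n))

    def test_adjacent_top_windows_merge(self):
        fst = self._background(198, 0.1, 0.2) + [0.9, 0.95]
        dxy = self._background(198, 0.01, 0.02) + [0.09, 0.095]
        regions = cs.outlier_regions(self._records(fst, dxy), q=0.99)
        assert len(regions) == 1
        assert regions[0].start == 198 * 1_000 + 1
        assert regions[0].end == 200 * 1_000
        assert len(regions[0].windows) == 2

    def test_disjoint_top_metrics_empty(self):
        fst = self._background(199, 0.1, 0.2) + [0.9]
        dxy = [0.09] + self._background(199, 0.02, 0.01)  # decreasing
        regions = cs.outlier_regions(self._records(fst, dxy), q=0.99)
        assert regions == []

    def test_gene_attachment(self):
        fst = self._background(199, 0.1, 0.2) + [0.9]
        dxy = self._background(199, 0.01, 0.02) + [0.09]
        genes = [cs.GeneModel("hit", 199_500, 199_700),
                 cs.GeneModel("miss", 10, 100)]
        regions = cs.outlier_regions(self._records(fst, dxy), q=0.99,
                                     genes=genes)
        assert regions[0].gene_ids == ["hit"]

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            cs.outlier_regions([], q=1.5)

    def test_island_recovery_on_truth(self, demo_bundle):
        recs = cs.scan_genome(
            demo_bundle.alignment, demo_bundle.truth.lineage_map,
            {"div": pg.WindowSpec(5_000, 1_250)},
        )["div"]
        regions = cs.outlier_regions(recs, q=0.9)
        island = demo_bundle.truth.island
        best = max(
            pg.jaccard_interval(island, (r.start, r.end)) for r in regions
        )
        assert best >= 0.5
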
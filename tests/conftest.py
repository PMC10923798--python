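"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute every statistic by explicit loops over
sample pairs and sites; they share no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pytest

import contiscan as cs


# ---------------------------------------------------------------------------
# Brute-force oracles (explicit O(n^2 L) loops)
# ---------------------------------------------------------------------------

def brute_pair_diffs(geno: np.ndarray) -> tuple[float, int]:
    """(total mean pairwise differences, n_pairs) with pairwise-complete
    per-site normalization: each site contributes its mean pairwise diff."""
    n, L = geno.shape
    total = 0.0
    for j in range(L):
        col = geno[:, j]
        diffs = pairs = 0
        for a, b in itertools.combinations(range(n), 2):
            if col[a] >= 0 and col[b] >= 0:
                pairs += 1
                diffs += col[a] != col[b]
        if pairs:
            total += diffs / pairs * 1.0
    return total, n * (n - 1) // 2


def brute_pi(geno: np.ndarray, length: int) -> float:
    return brute_pair_diffs(geno)[0] / length


def brute_S(geno: np.ndarray) -> int:
    s = 0
    for j in range(geno.shape[1]):
        col = [g for g in geno[:, j] if g >= 0]
        if len(set(col)) == 2:
            s += 1
    return s


def brute_watterson(geno: np.ndarray, length: int) -> float:
    n = geno.shape[0]
    a1 = sum(1.0 / i for i in range(1, n))
    return brute_S(geno) / (a1 * length)


def brute_tajima_d(geno: np.ndarray) -> float:
    """Direct evaluation of Tajima's variance constants, written from the
    published formulas rather than reusing the package's helper."""
    n = geno.shape[0]
    S = brute_S(geno)
    if n < 3 or S == 0:
        return math.nan
    pi_tot = brute_pair_diffs(geno)[0]
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (pi_tot - S / a1) / math.sqrt(var)


def brute_dxy(ga: np.ndarray, gb: np.ndarray, length: int) -> float:
    total = 0.0
    for j in range(ga.shape[1]):
        diffs = pairs = 0
        for a in range(ga.shape[0]):
            for b in range(gb.shape[0]):
                if ga[a, j] >= 0 and gb[b, j] >= 0:
                    pairs += 1
                    diffs += ga[a, j] != gb[b, j]
        if pairs:
            total += diffs / pairs
    return total / length


def brute_fst(ga: np.ndarray, gb: np.ndarray, length: int) -> float:
    hb = brute_dxy(ga, gb, length)
    if hb == 0:
        return math.nan
    hw = 0.5 * (brute_pi(ga, length) + brute_pi(gb, length))
    return 1 - hw / hb


def fisher_two_sided_enumeration(table) -> float:
    """Exhaustive two-sided Fisher p: enumerate all tables with the observed
    margins; sum hypergeometric probabilities <= P(observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, c1 + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def random_alignment(rng: np.random.Generator, n_samples: int, n_sites: int,
                     genome_length: int, missing_frac: float = 0.0) -> cs.SnpAlignment:
    pos = np.sort(rng.choice(np.arange(1, genome_length + 1), size=n_sites,
                             replace=False))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    bases = np.array(list("ACGT"))
    geno = rng.integers(0, 2, size=(n_samples, n_sites)).astype(np.int8)
    if missing_frac > 0:
        geno[rng.random(geno.shape) < missing_frac] = -1
    return cs.SnpAlignment(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        positions=pos,
        ref_alleles=bases[ref_idx],
        alt_alleles=bases[alt_idx],
        genotypes=geno,
        genome_length=genome_length,
    )


@pytest.fixture(scope="session")
def demo_bundle() -> cs.Bundle:
    """A small synthetic bundle with island, tracts and selected genes."""
    cfg = cs.SimConfig(
        seed=11,
        n_lineages=3,
        samples_per_lineage=[8, 8, 8],
        genome_length=60_000,
        island=cs.IslandConfig(start=25_001, end=35_000),
        genes=cs.GeneConfig(n_genes=20, codons_per_gene=100, n_selected=2,
                            omega_pos=10),
    )
    return cs.simulate_continuum(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
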
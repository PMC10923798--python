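# Methods

## Statistics

All population-genetic statistics operate on a samples × biallelic-SNP
matrix anchored to 1-based reference positions; monomorphic sites are
implicit (a window's per-site rates divide by the full window length, not
by the number of SNPs). Missing genotypes are handled pairwise-complete
per site: each site contributes its mean pairwise difference over the
samples called there.

- **π** — total mean pairwise differences in the window divided by window
  length.
- **θ_W** — S/(a₁·L) with a₁ = Σ_{i<n} 1/i.
- **Tajima's D** — (π̂_total − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants of the original derivation; NaN when S = 0 or n < 3. The
  worked value D ≈ −0.754 for the n = 4 / three-singleton fixture was
  verified by direct independent evaluation of the constants before being
  frozen into the tests.
- **Fu's F_S** — ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ̂ = π̂_total)
  under the Ewens sampling formula (unsigned Stirling numbers of the first
  kind over the rising factorial). "Fu's F" is ambiguous in common usage;
  F_S is the default and Fu & Li's F* (with the corrected u/v constants)
  is available via `fus_f(..., variant="fu_li_fstar")`. Haplotypes for
  k_obs are distinct genotype rows over the window's SNPs.
- **D_XY** — mean per-site between-group pairwise difference.
- **F_ST** — the Hudson-style estimator 1 − H_w/H_b with
  H_w = (π_A + π_B)/2 and H_b = D_XY; NaN when H_b = 0; negative values
  are reported as computed. A Nei-style G_ST is deliberately not offered as
  a silent default — the estimator choice is explicit in the function name.

Windows start at 1 and advance by the step; a tail shorter than the window
is dropped so that every window has identical length (keeping per-site
rates comparable). A genome shorter than one window yields a single
clamped window with a warning.

**Outlier regions** use a linear-interpolation quantile with ties included
at ≥ threshold; windows must exceed the threshold in *both* mean F_ST and
mean D_XY (mean across lineage pairs by default; a single pair may be
named). Adjacent or overlapping selected windows merge; genes overlapping
≥ 1 bp attach. Single-strain lineages are excluded from all population
statistics.

**MK test.** Divergence is polarized against the reference genome
sequence (an outgroup-reference design): a site is a fixed difference when
every non-missing ingroup allele is the alternate; it is polymorphic when
both alleles segregate in the ingroup. Synonymy is decided by translating
the codon (table 11) with the focal variant substituted into the
ingroup-consensus codon background; multiple SNPs per codon are resolved
one at a time against that background; minus-strand genes are
reverse-complemented. Genes with a frame-internal stop in the reference,
or a length not divisible by 3, are flagged and skipped. NI is undefined
whenever Ps, Ds or Dn is zero (no continuity correction by default);
classification requires both NI direction and Fisher p < α (α = 0.05, no
multiple-testing correction by default, Benjamini–Hochberg behind a flag
— the per-gene Fisher convention is the field default for this analysis).

**Gene flow.** Events are never deduplicated; an event intersecting k ≥ 2
lineages contributes to every intersected pair (the shared-and-unique
counting convention, under which summed fractions may exceed 100%).
Summed mode reproduces that convention; union mode measures the interval
union and is the only mode allowed to feed the divergence probability
P_div = 1 − fraction_between, since a probability must lie in [0, 1].
P_div is a *proxy* staging quantity; the stage thresholds
(species ≥ 0.89 > grey zone ≥ 0.85 > early) are presentation defaults
chosen to mirror the three published stage groups and are plain
configuration, not inference. Per-strain r/m counts the strain's
alternate-allele SNPs inside the union of its own tracts against those
outside; ρ/θ counts its events against outside SNPs; both are NaN (with a
warning) when no SNPs fall outside tracts. Single-carrier events count as
within-lineage (terminal-branch events) and are flagged.

**Isolation statistics.** Genetic distance is (100 − ANI)/100, which
equals 1 − ANI when ANI is supplied as a fraction. Geographic distance is
the haversine great-circle on the mean-radius sphere (R = 6371.0088 km);
the difference from an ellipsoidal geodesic is below 0.5% and accepted for
simplicity. Environmental variables are z-scored before Euclidean
distance because their units are heterogeneous. The Mantel test permutes
one matrix's labels, uses Pearson r on lower triangles, and reports
p = (#{r_perm ≥ r_obs}+1)/(n_perm+1) for the one-sided "greater"
alternative (distance decay is directional; two-sided is available);
p ≥ 1/(n_perm+1) always. Pagel's λ is the ML of the profile Gaussian
likelihood over λ ∈ [0, 1] (off-diagonals of the tree covariance scaled,
diagonal preserved; bounded scalar optimization at 1e−8, with explicit
boundary checks), and its LRT against λ = 0 uses the 50:50 χ²₀/χ²₁
mixture because λ = 0 sits on the parameter boundary. Blomberg's K is the
observed MSE₀/MSE ratio (phylogenetic mean â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x) over its
Brownian expectation (tr V − n/(1ᵀV⁻¹1))/(n−1), with a tip-shuffling
permutation p. Both agree with R implementations (phytools) to numerical
precision on shared fixtures. ANI clustering is single-linkage (connected
components of the ANI ≥ threshold graph); the linkage is a package choice
— a conventional, conservative reading of threshold clustering. Dunn's
post hoc uses the tie-corrected pooled-rank z statistic with Bonferroni
multiplication capped at 1.

## The synthetic-data generator

The generator produces data *with the statistical structure the analysis
assumes*, not realistic bacterial genomes (no operons, GC skew, indels, or
selection dynamics through time).

Model, in the order applied:

1. **Reference** — i.i.d. uniform nucleotides; gene reading frames are
   re-drawn codon-wise until stop-free. Every site has one fixed alternate
   allele, so the biallelic invariant holds by construction
   (infinite-sites with collision retry).
2. **Outgroup divergence** (`outgroup_divergence`, default 0.01) — flips
   shared by every founder, emulating polarization of divergence against
   an outgroup reference genome. Invisible to between-lineage statistics.
3. **Founder divergence** (`divergence` d, default 0.015) — each lineage
   founder independently flips sites with probability d/2 (star
   phylogeny), so founder pairs differ at rate d(1 − d/2). An optional
   island interval multiplies d locally (divergence-island emulation).
4. **Within-lineage coalescent** (`theta` θ, default 0.005) — per
   genealogy block (default 10 kb, emulating the quasi-independent local
   trees that pervasive homologous recombination produces), a Kingman
   coalescent with per-site mutation rate θ/2 on the branches, rooted at
   the founder. This gives the textbook neutral behavior E[π] = θ and
   E[Tajima's D] ≈ 0 (see calibration below).
5. **Purifying selection in genes** (`nonsyn_retention`, default 0.1 —
   typical bacterial core-gene dN/dS) — a nonsynonymous change inside a
   gene survives with this probability, applied identically to neutral
   mutations and founder flips, so neutral genes keep Dn:Ds ≈ Pn:Ps and
   the MK test stays calibrated.
6. **Selected genes** — the designated subset receives `omega_pos`
   implanted nonsynonymous fixed differences (default 20), bypassing
   purifying selection; sites are verified amino-acid-changing at
   generation time.
7. **Recombination tracts** — per strain Poisson(`tract_rate`) tracts of
   geometric length (`tract_mean_len`), donor chosen within-lineage or
   between (probability `between_tract_prob`, optionally weighted per
   lineage pair by `migration_weights` to create a gene-flow gradient);
   the donor haplotype overwrites the recipient (last writer wins) and the
   event is recorded with carriers {recipient, donor}.
8. **Geography / environment / HGT** — coordinates scatter normally
   around lineage centroids (`scatter_km`, default 50 km); environmental
   traits evolve by Brownian motion on the true tree (star of founder
   branches of length d/θ over the block-0 coalescent genealogies);
   HGT counts are Poisson(rate·genome size) with genome sizes ~N(7, 0.3²) Mb.

Closed forms used for validation (derived under this model and verified
by simulation before being frozen into tests):
E[π] = θ within lineages, and
E[D_XY] = d(1 − d/2) + θ_A(1 − 1/n_A) + θ_B(1 − 1/n_B)
(tip-to-founder distance contributes θ(1 − 1/n) per side). These hold for
neutral configurations (no genes or `nonsyn_retention = 1`); purifying
thinning lowers genic diversity below them, as intended.

Reproducibility: one seed per bundle; per-component child streams are
derived with fixed integer labels, so e.g. the coalescent is reproducible
independently of the geography stream. Identical config + seed yields
byte-identical output files (sha256-checked in tests).

## Calibration and validation experiments

Problem sizes were chosen so the full suite and the acceptance script
each run in a couple of minutes on one CPU.

- **Oracle equivalence** — all window statistics equal an explicit
  O(n²L) loop implementation on 50 random fixtures (≤ 10 samples × 200
  sites, with missing data) to 1e−12.
- **Neutral mean D** — 200 replicates, K = 2, n = 20 per lineage,
  θG = 100 (G = 20 kb, θ = 0.005), 2.5-kb windows sharing one genealogy
  per lineage; the grand mean of per-replicate windowed D lies within 3
  standard errors of zero. Note that Tajima's D has a small intrinsic
  negative mean under the neutral coalescent (measured ≈ −0.05 at
  θ_window = 10 up to ≈ −0.14 at θ_window = 100, confirmed against an
  independent coalescent oracle), so this check is necessarily a
  bias-versus-power compromise; the chosen window size keeps the bias
  within the test's resolution.
- **Departure-test type-I error** — 500 neutral replicates with
  genealogy blocks aligned to non-overlapping 2.5-kb windows (the
  independence regime the t-test assumes); the rejection rate at α = 0.05
  falls in [0.03, 0.07]. With overlapping windows (the field's scan
  convention) the t-test is anticonservative — a caveat that applies to
  real scans too.
- **MK recovery and false positives** — at n = 20 per lineage, 300-codon
  genes, θ = 0.01, outgroup divergence 0.01, and 20 implanted
  nonsynonymous fixed differences, ≥ 80% of selected genes classify
  positive at α = 0.05 while the neutral positive rate stays ≤ 0.08.
  These conditions were fixed from an a-priori Poisson/Fisher power model
  of the 2×2 table (target power ≥ 0.85) before the confirmatory runs.
- **Island recovery** — a 20-kb island (5× divergence) in a 200-kb
  genome, scanned at 10 kb / 2.5 kb, quantile q = 0.93 (selecting the top
  ~7% of windows, matching the island's genome fraction); the detected
  region overlaps truth with Jaccard ≥ 0.5 in 20/20 seeds.
- **Tract-fraction recovery** — a configuration whose expected
  between-lineage union coverage is 1 − exp(−N·l/G) ≈ 0.10 is recovered
  by the union-mode estimator within ±0.02 (mean of 10 seeds), and each
  seed's estimate equals the truth-set bookkeeping exactly.
- **Gene-flow gradient** — with migration weights 8 : 2 : 0.25 across
  three lineage pairs, the divergence probabilities order inversely to
  the weights.
- **λ recovery** — on a 64-tip balanced tree with terminal branches 0.3
  vs internal 1.0 (densely sampled clades, where λ is well identified),
  λ̂ ≥ 0.9 for ≥ 90% of 100 Brownian traits. The estimator was checked
  per-replicate against R phytools.

## What passing tests do and do not show

The generator's idealizations — star founder phylogeny, block-wise
independent genealogies, no indels, no population structure within
lineages, tracts recorded with exact boundaries and carriers — mean that
passing recovery tests demonstrates the *estimators and detectors are
correct under their own assumptions*, not that real data meet those
assumptions. In particular, real recombination detection has boundary
error and missed events (we consume its output as ground truth), real
window statistics face alignment and calling artifacts upstream of this
package, and real reference polarization conflates ancestral state with
outgroup state.

## Known limitations

- Single-contig genomes (multi-contig input must be concatenated or a
  contig named).
- Haploid genotype model ({ref, alt, missing}); no phasing, no LD-based
  statistics.
- The departure t-test treats windows as exchangeable; overlapping
  windows violate this (documented above, matching common practice).
- Fu's F_S becomes numerically inert for very large θ̂ (S′ → 1);
  windows are expected to keep θ̂ well below that regime.
- Stage thresholds on P_div are presentation, not inference; the
  divergence probability itself is a proxy built from tract coverage.
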
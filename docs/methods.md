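# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Allele harmonization

Two GWAS report signed effects relative to an *effect allele*; before signs
can be compared SNP-by-SNP the two studies must refer to the same allele.
For each shared SNP the secondary study's allele pair is matched to the
primary's in four orientations: identical, swapped (sign negated), strand
complement (A↔T, C↔G), and complement-plus-swap (sign negated).  Pairs that
match in none of the orientations are dropped and counted.

Palindromic SNPs (A/T and C/G pairs) are strand-ambiguous — the identity
and complement-swap orientations are indistinguishable from the allele
letters alone — and are **dropped by default**.  An optional
frequency-based rescue keeps them when both studies report an effect-allele
frequency at least 0.08 away from 0.5 and on a consistent side of 0.5;
this is off by default because allele frequencies in meta-analysed summary
statistics are often pooled across cohorts and unreliable for strand
inference.

p-values of exactly 0 (common in formatted downloads) are clamped to
1e-300 with a warning: every downstream quantity (BH ratios, TDR) needs
p strictly in (0, 1].  Chromosome labels are compared as normalized strings
("chr1" ≡ "1"); positions are 1-based.

## LD clumping

Greedy index-SNP selection with PLINK-compatible semantics: process SNPs in
ascending order of the ranking trait's p-value; each SNP not yet removed
becomes an index and removes every remaining non-index SNP on the same
chromosome within ±`window_bp` (default 500,000, inclusive) whose r² with
it exceeds `r2_threshold` (default 0.2, strict inequality).  Both
conditions are required for removal.  Ties in the ranking p-value are
broken by (chromosome, position, SNP id), making the output invariant to
input row order.  SNPs absent from the LD reference are treated as
unlinked (r² = 0 with everything) and form their own clumps; they are
counted in the log.  The default ranks on the *secondary* (conditioning)
trait, producing one independent SNP set per conditioning phenotype.

Clumping runs on the harmonized (intersected) SNP set.  The window is
interpreted as a half-width (±500 kb), the common clumping convention.

## SECA: grid tests and permutation summary

The analysis grid is the Cartesian product of p-value cutoffs
{0.01, 0.05, 0.1, 0.2, …, 0.9, 1.0} for each trait (144 cells);
both axes are configurable.  Per cell (t₁, t₂):

* **Pleiotropy**: the 2×2 table of (p₁ ≤ t₁) × (p₂ ≤ t₂) with fixed
  margins; the cell p-value is the one-sided hypergeometric upper tail
  P(X ≥ n_both) — the Fisher exact test for over-representation.
* **Concordance**: among the n_both SNPs in the cell, the number k with
  sign₁ = sign₂ is compared to Binomial(n_both, ½), one-sided in each
  direction: excess p = P(X ≥ k), deficit p = P(X ≤ k).  Empty cells get
  p = 1 and are non-informative.

Grid-level significance is assessed by permutation.  The null re-pairs the
secondary trait's (p, sign) *pairs* across SNPs: each trait's marginal
p-value and sign distributions are preserved exactly, while any cross-trait
linkage is destroyed.  Empirical p uses the add-one rule
(1 + #{permuted statistic ≥ observed}) / (1 + n_perm), which can never
return 0 and is exact-conservative; the 95% CI on that proportion is the
exact Clopper–Pearson (beta) interval.

**Grid summary statistic.**  Two summaries of the 144 cell p-values are
implemented:

* `min_p` (default): the smallest cell-level p across the grid (for
  concordance, separately for the excess and deficit directions).  Because
  the minimum over many cells takes many distinct values, its permutation
  distribution is nearly atom-free and the resulting empirical p is very
  close to uniform under the null (measured over 200 independent-trait
  simulations: rejection rate 6% at α = 0.05, KS uniformity p = 0.68).
* `count`: the number of cells with cell-level p ≤ 0.05 (`cell_alpha`).
  This summary is coarser — under the null the observed count is frequently
  0, placing a large atom of empirical p at exactly 1 — which makes it
  conservative in distribution although still valid (measured rejection
  rate 5.5% at α = 0.05).  It is retained because the count of nominally
  significant subset pairs is how grid-based concordance analyses usually
  present their statistic.

The default is `min_p` precisely because its null distribution is usable
for calibration checks; switch with `permutation_summary(..., summary="count")`.

For concordance, the reported empirical p is the smaller of the excess and
deficit one-sided results, *without* doubling — the companion direction
label carries the sidedness, mirroring how such tables are usually printed.
A reader wanting a two-sided p should double the reported value.  The
direction label is the sign of Σ(n_concordant − n_discordant) over all
informative cells, computed on the observed data only, falling back to the
full (1, 1) cell on a zero sum and to "none" when no cell is informative.
Residual discreteness in the min-p statistic (exact cell p-values tie
occasionally across permutations) leaves the empirical p very slightly
conservative; this is visible as null rejection rates a point or two below
the nominal level in some simulation batches.

Default n_perm = 9,999 (resolution 10⁻⁴); tests and the calibration runs
use 99–199 for speed, which is stated where it happens.

## Conditional FDR

Benjamini–Hochberg step-up q-values: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·n/j, capped at 1.
The plain BH procedure (not the dependence-adjusted BY variant) is used
because the input is LD-clumped to approximately independent SNPs.

For each conditioning level c in {10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.1, 0.2, …,
0.9, 1} the subset S_c = {SNP : conditioning-trait q ≤ c} gets its own BH
pass over the primary p-values restricted to S_c.  A SNP's conditional
q-value is the **minimum** across the levels whose subset contains it;
since level 1 is the full set, the conditional q can never exceed the
unconditional q (asserted exactly in tests).  Taking a minimum over nested
subsets is itself a multiplicity; it is documented rather than corrected,
because "significant conditioned on any subset at 5% FDR" is the decision
rule this realizes.  Empty subsets are skipped with a log note.

## Stratified TDR

For a stratum S = {SNP : conditioning p ≤ cutoff}, cutoffs
{1.0, 0.1, 0.01, 0.001}: F̂(t) = |{i ∈ S : p₁ᵢ ≤ t}| / |S| (self-inclusive,
so F̂ ≥ 1/|S| wherever any p ≤ t, avoiding division by zero), and
TDR(t) = max(0, 1 − t/F̂(t)), clamped to [0, 1] — a conservative empirical
Bayes bound on the true discovery rate.  The default evaluation grid is the
stratum's own sorted unique p-values (faithful per-SNP curves); a fixed
grid can be passed for matched-point comparisons across strata.

A caution on null behaviour: at very small t the ECDF's relative
fluctuation is large (at the smallest order statistic,
TDR = 1 − n·p₍₁₎ is approximately Uniform(0, 1) even under a global null),
so "TDR ≈ 0 under the null" is only a meaningful check on grid points whose
expected stratum count n·t is large.  The null-calibration check therefore
uses a fixed log-spaced grid on [0.05, 1], where with n = 10⁵ the bound
|TDR| ≤ 0.05 holds with ≥ 3.6 standard errors to spare.  Enrichment
comparisons between strata are unaffected (they use matched grid points in
the signal region).

## % variance explained

For a reported effect and standard error, z = effect/se and
r² = z²/(z² + n − 2) — the single-regressor identity between the t
statistic and the squared sample correlation — reported as a percentage.
This assumes a continuous trait and one degree of freedom, so it is
approximate for case-control traits; it is a reporting column only and no
inference depends on it.

## Multiple-testing policy

The family-wise threshold is p* = 0.05 / (n_traits × n_volumes ×
n_methods); with 3 traits, 8 volumes and 2 methods this is
0.05/48 ≈ 1.042 × 10⁻³.  Annotation bands applied to empirical p-values:
significant (p ≤ p*), nominal (p < 0.05), trending (p < 0.1), else ns —
mutually exclusive in that order.  Conditional-FDR discoveries are reported
per conditioning trait without an additional cross-trait correction.

## Synthetic-data generator

The generator produces the *joint* object every stage needs: two
summary-statistics tables over the same variants, the exact pairwise r²
table, and a ground-truth record.

* **Genome**: independent compound-symmetry LD blocks (default
  2 chromosomes × 250 blocks × 8 SNPs = 4,000 SNPs), within-block genotype
  r² = 0.5, 10 kb SNP spacing, 600 kb inter-block gaps.  Gaps exceed the
  clumping window, so "one index SNP per block" is exact ground truth and
  clumping correctness is decidable.
* **Effects**: each block is causal for trait 1 / trait 2 / both / neither
  with probabilities derived from (π₁, π₂, π_shared); shared blocks agree
  in sign with probability `p_sign_agree`.  One causal tag per block (the
  first SNP) carries β = sign·|N(0, effect_sd)|; the block's Z-scores are
  multivariate normal with mean √n·β·rᵢ (rᵢ = correlation with the tag:
  1 for the tag, √r² otherwise) and compound-symmetry correlation √r².
  Hence null SNPs have Z ~ N(0,1) and uniform p, and a causal tag's
  expected χ² is 1 + n·effect_sd² — both checked against simulation in the
  tests.
* **Defaults**: n₁ = n₂ = 10,000 and effect_sd = 0.02 (mean causal-tag
  χ² = 5), a regime where per-SNP power is modest but aggregate overlap is
  detectable — the situation the method exists for.  The `cfdr_enriched`
  scenario uses effect_sd = 0.032 so that shared SNPs sit near the
  genome-wide BH boundary, making conditional rescue visible at desk scale.
* **Allele re-orientation**: the secondary table's allele columns are
  randomly swapped and/or strand-complemented per SNP (with the reported
  sign and frequency adjusted), so the harmonization step is exercised on
  every simulated dataset, not just on toy fixtures.

What the generator does **not** emulate: realistic MAF spectra (p-values
are generated directly on the Z scale), case-control ascertainment and
liability-scale effects, population stratification or residual confounding,
variable block sizes and LD decay within blocks, and overlapping GWAS
samples (which induce correlation of null Z-scores between traits).
Consequently, passing calibration and recovery tests here shows the
*statistics and algorithms* behave as designed under their own model; it
does not certify robustness to cryptic sample overlap or stratification in
real summary statistics.

## Numerical and determinism conventions

* All randomness flows from a single integer seed through
  `numpy.random.default_rng` / `SeedSequence.spawn`; no global RNG state.
  `run_all` derives one child seed per trait pair and records them in the
  run log, so every table is recomputable from the log alone.
* Output TSVs are written with `%.6g` floats; re-running with the same
  config and seed produces byte-identical files.
* Simulation scale in tests: calibration uses 200 replicates at the default
  4,000-SNP genome with 199 permutations; recovery uses 50 replicates.
  These sizes give standard errors comfortably inside the asserted
  tolerances while keeping the default suite around a minute.
* Exact tests use scipy's hypergeometric and binomial distributions;
  enumeration oracles in the test suite verify them at small n, and the
  in-package BH implementation is verified against both an O(n²)
  brute-force minimization and statsmodels.
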
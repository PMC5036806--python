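# Methods

## Study design being modelled

A biparental RIL population (parents fully homozygous, lines advanced by
single-seed descent, so each marker is essentially two homozygote classes
with a small residual heterozygosity) is genotyped on a dense genetic map
and phenotyped for a continuous trait in many year × location environments.
The question is which *pairs* of markers interact on the trait — statistical
epistasis beyond additive effects — and which of those interactions recur
across environments.

## The MDR two-locus statistic

Multifactor dimensionality reduction collapses a multi-locus genotype table
to one binary predictor. Our two-locus version:

1. **Dichotomisation.** The trait has to become case/control before MDR can
   run. How the original study did this is not documented; we default to a
   per-environment **median split** (value > median → case, ties → control)
   because it yields balanced classes — the design MDR's risk ratio is
   calibrated for — and is invariant to monotone location shifts. A mean
   split is available (`binarize_rule="mean"`). This is the single largest
   reconstruction choice in the package and it affects which pairs are
   significant; all downstream numbers are conditional on it.
2. **Cell risk.** Lines are tallied into the 3×3 grid of genotype codes
   {0,1,2}² (the heterozygote class is kept as a real, if rare, cell; lines
   missing at either marker are excluded from the pair). A cell is
   high-risk iff cases_c/controls_c ≥ T with T = n_case/n_control over the
   table; case-only cells are high, ties go high (the classic MDR
   convention).
3. **Score.** The pooled high/low × case/control 2×2 is scored with the
   uncorrected 1-df Pearson chi-square (computed as n(ad−bc)² over the
   margin product; identical to Σ(O−E)²/E). A zero margin leaves the
   statistic undefined: such pairs are recorded with p = 1 and never
   emitted.

Because the high/low partition is chosen *after* seeing the data, the
statistic is anti-conservative relative to χ²₁: in our 10,000-pair null
simulation at n = 147 the empirical 99% quantile is ≈ 9.5 against the
nominal 6.63. The test suite freezes these empirical quantiles as a
regression fixture rather than pretending the null is chi-square. The
Bonferroni threshold applied in the scan is so deep (≈ 3.5×10⁻¹¹) that the
realised null emission rate is still essentially zero (measured directly by
the calibration tests).

### Cross-validated statistic

The reported `cv_mean_chi_square` is the mean over 10 repetitions of an
**out-of-fold aggregate**: per repetition, lines are dealt into 10
label-stratified folds; each fold's lines are pooled into high/low using
the partition learned on the other nine folds; the held-out 2×2 counts are
accumulated over the 10 folds and one chi-square is computed from the
aggregate. A per-fold mean was considered and rejected: a chi-square on a
fold of n/k lines lives on a 1/k scale, so per-fold averages are not
comparable to the full-data statistic that the significance filter uses,
whereas the out-of-fold aggregate preserves a perfectly generalising
pair's statistic exactly and collapses to ≈ 1 (the χ²₁ mean) for an
overfit null pair. Folds whose training table supports no risk model
contribute their lines as low-risk; a repetition with a zero margin
contributes 0. Significance filtering uses the full-data p-value; the CV
mean is reported alongside (and computed only for emitted pairs by
default — `cv="all"` forces it everywhere, `cv="none"` disables it for
large power studies).

## Scan and multiple testing

All m(m−1)/2 unordered pairs are scored per environment on the lines in the
genotype ∩ phenotype intersection. The Bonferroni threshold defaults to
α/(m(m−1)) ("ordered" mode): with α = 0.001 and m = 5,308 this reproduces
the published 3.55×10⁻¹¹ exactly, which is why ordered is the default even
though the scan enumerates unordered pairs; α/(m(m−1)/2) is available as
"unordered". The kernel is vectorised over chunks of pair indices; chunk
boundaries cannot affect any pair's statistic, and a test asserts
bit-identical output across chunk sizes. Per-pair CV seeds are derived from
(scan seed, marker indices) so results are independent of chunking and
iteration order.

## Stability across environments

`available_envs` — the denominator for the `half` preset — counts only
environments that yielded at least one significant pair (matching the
published "almost 50% of all" usage, where 12 of 23 environments had
pairs). Both published notions of stability are named presets: `gt2`
(detected in more than 2 environments) and `half` (≥ ⌈available/2⌉); the
pipeline default is `half`.

## Two-way ANOVA, epistatic value, contribution rate

Heterozygous and missing calls are dropped (RILs are ~99.8% homozygous; a
3×3 factorial at n ≈ 147 would be chronically rank-deficient), leaving a
2×2 factorial with effect coding x ∈ {−1,+1}. Fits use ordinary least
squares (statsmodels); each term's sum of squares is the residual-SS
increase when that term is dropped from the full model (partial,
Type III–equivalent for the 2×2), so the decomposition is order-invariant
even with unbalanced cells — necessary because real RIL cells are never
exactly balanced. The interaction F uses 1 and n−4 df. Pairs with an empty
genotype cell or no residual df are recorded NS with a reason, mirroring
the published supplement's NS convention.

The **epistatic value** is the unweighted cell-means interaction contrast
e = (m₀₀ + m₂₂ − m₀₂ − m₂₀)/4, the two-locus physiological-epistasis
measure restricted to the four homozygous cells; in a balanced design it
equals the effect-coded interaction regression coefficient (asserted by a
cross-check test). Values are emitted signed, with an absolute-value column
alongside, since the published range (0.01–0.89, all positive) does not
reveal whether signs were folded. The **contribution rate** is
SS_interaction/SS_total ("phenotypic variation"); the genetic-SS
denominator variant was considered and not used because the stage is
described as a share of phenotypic variation. Interaction significance is
uncorrected p < 0.01 per environment, as stated for this stage.

## Synthetic data generator

Genotypes: per linkage group, each line is a two-state Markov chain; the
switch probability between adjacent markers at distance d cM is
R = 2r/(1+2r) with r = ½(1−e^(−2d/100)) (Haldane, no interference; the
selfing-RIL expansion for an F₂-derived SSD population). Groups and lines
are independent. Residual heterozygosity (default 0.002 ≈ 2⁻⁹, the
expectation for F₂:₁₀-and-later lines) and missingness (default 0 —
published linkage-map genotypes are effectively complete after imputation)
are overlaid i.i.d. per entry rather than tracked through the pedigree.

Phenotypes: y_le = μ + Σ aᵢxᵢ + Σ w xᵢxⱼ + shift_e + ε, ε ~ N(0, σ_e²),
with x ∈ {−1,+1} and het/missing contributing 0. Effect coding makes
additive and interaction terms orthogonal in a balanced RIL, so a planted w
is recovered directly by the interaction contrast (mean recovered value
within 0.01 of the planted 0.5 in the 200-replicate study). The default
study conditions mirror the real design: n = 147 lines, 23 environments
whose means (19.07–21.48%) and SDs (0.36–1.39) come from the packaged
per-environment table, map geometry 5,308/20/2294.433 cM.

What the generator does **not** emulate: segregation distortion, genotyping
error, linkage-map error, replicate-level measurement structure (each line
value is already the plot-replicate mean), and genotype-by-environment
interaction beyond additive environment shifts. Passing recovery tests
therefore show the statistical machinery is correct under the assumed
model, not that the published biological findings re-derive — the
underlying genotype/phenotype data were never released.

## Problem sizes in tests and the acceptance script

Scans in the recovery and calibration studies use a 100-marker panel on 20
linkage groups at 20 cM spacing (a sparse subpanel of the full map
geometry): at 0.43 cM spacing adjacent markers are near-copies
(R ≈ 0.009), so "which exact pair ranks first" is not a meaningful recovery
criterion on the full map — a 20 cM panel keeps neighbouring pairs
distinguishable while preserving realistic within-group linkage. The
oracle-equivalence suite uses m ≤ 30 panels where the naive per-pair path
is cheap. The demo pipeline uses 30 markers, 3 environments, one planted
pair at w = 0.8.

## Numerical and degenerate-input conventions

- Counts and margin products use int64 throughout the chi-square closed
  form (exact up to n⁴, far beyond any RIL population size).
- Ties at the binarisation centre go to control; ties at the risk
  threshold go to high; both conventions are asserted in tests.
- Degenerate inputs raise typed errors: all-identical phenotypes,
  fewer than 4 lines, empty tables, zero margins, empty ANOVA cells;
  pipeline stages convert the per-pair ones into skips/NS records rather
  than aborting a whole scan.
- Pipeline reproducibility: one master seed, per-stage child seeds via
  `numpy.random.SeedSequence`; manifests from two runs of the same config
  and seed are identical apart from runtime.

## Known limitations

- The case/control construction (median split) is a reconstruction, not a
  documented choice of the original analysis; absolute pair counts are
  sensitive to it.
- The MDR p-values are nominal chi-square tails on an adaptive statistic;
  they are used, as in the original analysis, only against an extremely
  deep Bonferroni threshold, not as calibrated single-test p-values.
- Linked neighbours of a true interacting pair are routinely co-significant
  (they are proxies, not false positives); no LD-pruning or peak-collapsing
  is applied.
- Covariates are not supported — an inherent MDR limitation.
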
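# Methods

## Enhancement maps and region summaries

The pipeline works on a 4-D DCE series (precontrast phase 0 plus
postcontrast phases; default acquisition grid 0/120/210/300/390 s) and
two co-registered binary masks, breast and FGT, with FGT nested inside
breast. No resampling or registration is performed: masks must already
live on the series grid, and a nesting violation either raises or — with
an explicit repair flag — is intersected away with a logged warning.

Per voxel, PE = 100·(S_early − S_pre)/S_pre and
SER = (S_early − S_pre)/(S_delayed − S_pre). Defaults: early = phase 1
(120 s), delayed = the last phase (390 s). Numerical guards: PE is
computed only where S_pre exceeds ε (default 10⁻⁶ × the median
precontrast signal); SER additionally requires the delayed enhancement
S_delayed − S_pre > ε and is evaluated only on *enhancing* voxels, i.e.
those with PE at or above the voxel threshold — ratios of two
near-noise differences in non-enhancing tissue are meaningless and the
SER literature computes SER on enhancing tissue. Negative PE is kept in
the map (it is informative) but can never count as enhancing, since the
threshold test is one-sided (≥).

The four region measurements are **volume fractions**: PE_region is the
percent of region voxels with PE ≥ 30%, SER_region the percent with
valid SER ≥ 0.90, for region ∈ {FGT mask, breast mask}. Voxels with
undefined PE or SER stay in the denominator. Two interpretive choices
deserve emphasis because the summary definition admits alternatives:

* *Fraction vs median.* Typical FGT-wise PE values of order 10% lie far
  below the 30% voxel threshold, which is only consistent with a
  volume-fraction reading of the summary, not a median voxel value; a
  median-over-enhancing-voxels summary is nevertheless available behind
  `ThresholdConfig(summary="median")`.
* *SER denominator.* Whether the SER fraction should be taken over all
  region voxels or only over enhancing ones is a genuine open choice;
  all region voxels is the default (`ser_denominator="region"`), the
  alternative is a config switch. With the default, SER_region ≤
  PE_region always holds, matching the observed ordering of the two
  measures.

Thresholds (30% PE, 0.90 SER) are the conventional values from the
prior quantitative-BPE literature; the sensitivity of every conclusion
to them is exactly what `threshold_phase_sweep` measures (PE thresholds
10–90% in steps of 10, plus early/delayed phase grids, one unadjusted
Mann–Whitney p per grid point × measure × group pair, with the 0.05
reference level recorded per row).

## Kinetic eigenvector, IER and DER

FGT voxel time courses (voxels with positive precontrast signal) are
stacked into an n_voxels × n_phases matrix X and the leading right
singular vector of the **uncentered** X is taken, computed from the
n_phases × n_phases second-moment matrix XᵀX for efficiency. Uncentered
rather than mean-centered is a deliberate and consequential choice: the
derived quantities are ratios v[t]/v[0], which are only meaningful if
the eigenvector lives on the signal scale with a positive baseline
component; centering removes the baseline and makes v[0] ≈ 0. The
convention is isolated in one function so it can be swapped. Sign is
fixed by requiring a positive precontrast component (tie broken by a
positive vector sum); IER and DER are then the percent increases of the
eigenvector at the phases nearest 120 s and 390 s over the precontrast
component, with a logged note when no exact-time phase exists. With
additive i.i.d. noise the second moment is XᵀX + σ²nI in expectation, so
noise shifts eigenvalues but not the leading eigenvector — which is why
recovery degrades only through finite-sample effects.

## Statistics

* **Mann–Whitney.** U from midrank summation. Two-sided p: for
  n_x·n_y ≤ 400 the exact null distribution of the rank sum is built by
  dynamic programming over the (doubled) midrank multiset — equivalent
  to enumerating all C(n, n_x) labelings, and valid under ties; larger
  samples use the normal approximation with tie-corrected variance and
  continuity correction (scipy).
* **Bonferroni.** adjusted p = min(1, m·p), significant iff adjusted
  p < FWER (default m = 6 measures, FWER 0.1) — decision-equivalent to
  testing the unadjusted p against FWER/m. The multiply-p direction is
  used even though the adjustment is sometimes loosely described as
  dividing the p-value by m; dividing would make every result *more*
  significant and cannot be the intended correction.
* **Chi-squared.** Pearson's test with Yates continuity correction on
  2×2 tables only; all-zero rows/columns are dropped first and a table
  collapsing below 2×2 is an error. This convention exactly reproduces
  the published characteristic-table p-values the test suite freezes
  (0.20, 0.08, 0.002, 0.03, 0.02, and three < 0.001).
* **Regression.** OLS with intercept (statsmodels); 95% t-based CIs.
  Binary covariates enter as 0/1, FGT level as its ordinal 1–4 value,
  BRCA carrier status as 0/1. Univariate mode fits one covariate at a
  time. Rank-deficient designs raise an error naming the offending
  columns.
* **Propensity matching.** Propensity = logistic regression (GLM,
  binomial) of treated-group membership on age, BMI, menopausal status,
  hormonal treatment and FGT level. Greedy 1:1 nearest-neighbour on the
  logit scale, without replacement, treated subjects processed in
  descending propensity order (hardest-to-match first), ties broken by
  subject id; the treated group must be the smaller one, and no caliper
  is applied by default (a logit-SD caliper is available). Balance is
  reported as SMDs — difference in means over the pooled SD, with the
  proportion-based variance for binaries. Non-overlapping supports
  produce a warning, not a failure. Matched-cohort comparisons reuse
  exactly the matched subjects.
* **Strata.** dense = FGT levels {3,4} (heterogeneous, extreme);
  nondense = {1,2}; pre/postmenopausal by status. An empty stratum
  raises in the library and is skipped with a warning by the pipeline.

## Synthetic data

The phantom voxel model is S(t) = S0·(1 + a·w(t)) with w rising
linearly from 0 to 1 over the first 120 s and continuing with slope b
(b < 0 washout, b = 0 plateau, b > 0 persistent), plus additive
Gaussian noise. This is the simplest kinetic family that spans the SER
regimes a 0.90 threshold distinguishes (SER = 1/(1 + 270·b) at the
default phase grid) and gives closed-form PE and SER per voxel, stored
as `PhantomTruth` for oracle tests. Gaussian rather than Rician noise
keeps expectations closed-form; at the simulated SNR the difference is
immaterial to threshold-crossing behaviour. Tissue classes (default:
fat, non-enhancing FGT, persistent FGT with SER 0.5, washout FGT with
SER 1.25) occupy contiguous blocks by default for readable mask
geometry, or are scattered voxelwise behind a flag. The breast mask is
the full grid and FGT the flagged classes, so nesting holds by
construction. The phantoms emulate enhancement kinetics and noise only —
no anatomy, bias field, motion, or pharmacokinetic modelling — so
passing tests certify the quantification arithmetic, not robustness to
acquisition artifacts.

The cohort generator draws per-group covariates (truncated-normal age
and BMI, Bernoulli menopause/hormone status, categorical FGT level)
and the six BPE measures from a linear model on covariates plus group
offsets and Gaussian noise, clipping the four fraction measures to
[0, 100]. The default parameters are anchored to the published cohort
summaries: group sizes 299/71/165; nonhigh-risk women older (56 vs 46),
mostly postmenopausal (73% vs 34%) and lower in FGT level; BRCA
carriers youngest with slightly higher BMI; group effects oriented so
high-risk non-BRCA sits highest on PE/IER/DER and lowest on SER_FGT.
Only the summary statistics are anchored — the real joint distribution
is unknown and not claimed. A zero-effect variant (`null_bpe_model`)
underlies type-I-error calibration, and `shifted_cohort_spec` adds a
pure group shift on one measure for power checks.

`confounded_cohort_spec` is the matching test-bed: two groups confounded
in the study's directions (treated older, more postmenopausal, slightly
more hormone treatment, lower FGT) at **half** the study's shift
magnitudes, with pe_breast driven entirely by the confounders (zero
group effect). Two sizing decisions are deliberate. Half-magnitude
shifts preserve common propensity support — at the full 10-year age gap
the oldest treated subjects have no plausible controls in a 4:1
reservoir, so residual age bias survives any matcher. And the default
500 treated / 2000 controls gives a matched sample in which the
per-covariate SMD noise (order √(2(1−ρ)/n) for within-pair correlation
ρ) sits well below the 0.1 balance convention; with the study's own 71
pairs the diagnostic mostly measures sampling noise. The full-strength,
study-sized spec remains the package default everywhere else, and the
suite separately checks that matching reduces SMD there.

## Problem sizes and tolerances

Noiseless round-trips are asserted at 10⁻⁹ relative tolerance; region
summaries must equal the brute-force voxel count exactly (they are
ratios of integer counts). Monte-Carlo suites use 2000 null replicates
for Mann–Whitney calibration (tolerance ±1.5% around 5%), 1000 cohort
replicates for generator null calibration (±2%), 200 replicates for OLS
coverage (±3% around 95%), 100 seeds for matching balance (≥90%
all-balanced), 50 noisy phantoms at 2%-of-baseline noise for IER/DER
recovery (±3 points), and 100 random ≤16³ phantoms for the counting
oracle. The full suite runs in under a minute on one core.

## Known limitations

* The PE/SER summary definitions (volume fraction; SER gating and
  denominator) are declared conventions with config switches, not
  settled facts; conclusions sensitive to them should be checked against
  the sweep output.
* Uncentered PCA is a convention; centered-and-rescaled variants would
  change IER/DER on strongly heterogeneous FGT.
* Greedy matching is order-dependent by design (documented order,
  seeded ties); optimal matching is out of scope.
* The cohort generator reproduces marginal summaries and signed
  confounding directions, not the true joint distribution; absolute
  medians of real cohorts are not reproducible from it.
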
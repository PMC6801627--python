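# Methods

## Problem setting

A cohort of women with pelvic masses scheduled for surgery provides one
urine sample each, assayed for 23 candidate protein markers, plus the
post-operative pathology (benign / borderline / malignant), histology,
FIGO stage, menopausal status and age.  Borderline tumors (low malignant
potential) are excluded before analysis, leaving a benign-vs-cancer
classification problem at roughly 125 vs 158 samples.  The package
implements marker screening, single-marker ranking, joint importance
ranking, and nested cross-validated panel selection for this setting, and
a calibrated generator of synthetic cohorts with the same structure.

## Empirical AUC and DeLong inference (`roc.py`)

The AUC is the Mann–Whitney pair statistic: the probability that a random
cancer sample scores above a random benign sample, ties counting ½.  It is
computed via midranks in O(n log n), identical to explicit pair counting.

Variance and covariance of correlated AUCs use DeLong's
structural-components estimator.  For positive scores `x_i` and negative
scores `y_j`, the placements `V10_i = mean_j ψ(x_i, y_j)` and
`V01_j = mean_i ψ(x_i, y_j)` (ψ = 1, ½, 0 for win/tie/loss) give

    var(AUC) = S10/m + S01/n,

with `S10`, `S01` the sample variances of the placements, and analogous
cross-covariances for two scorings of the same samples.  Both placements
are computed by midranks rather than explicit pairs.  Confidence intervals
are Wald intervals clipped to [0, 1]; degenerate inputs (perfect
separation) legitimately give zero variance and a point interval.  The
paired test uses `z = (AUC_a − AUC_b)/√(var_a + var_b − 2 cov)` with a
two-sided normal p-value; a zero-variance difference returns p = 1 when
the AUCs agree and p = 0 (with a warning) when they do not.

### Stratified resampling

`stratified_subsample_auc` draws a fraction of each class — without
replacement by default (random subsets), with replacement as a bootstrap
option, since both readings of the protocol are defensible — and reports
the mean AUC across iterations next to the full-data DeLong interval.
Whether the interval should instead be aggregated across subsets is
ambiguous in protocols of this kind; the full-sample DeLong interval is
reported and labeled as such.  Per-class draw counts preserve the
cancer-to-benign ratio by largest-remainder rounding: the total is
`round(frac·N)`, per-class quotas are floored, and leftover units go to
the largest fractional remainders (ties to the larger class).  Iteration
`i` uses an independent substream spawned from the master seed
(`SeedSequence.spawn`), making results reproducible and independent of
iteration order or count.

## Marker screening (`screen.py`)

The benign-vs-cancer test per marker is Welch's t on
`log10(x + ε)`, ε = half the smallest positive observed value of that
marker.  The log scale matches concentration data spanning orders of
magnitude; Welch avoids assuming equal class variances.  Familywise
correction is Bonferroni by default (Benjamini–Hochberg by flag) over the
markers actually testable; markers with an entirely-missing class are
flagged untestable and excluded from the correction denominator.  The
effect direction is the sign of the difference of raw class medians —
robust and scale-free.  Three-or-more-group contrasts (benign / early /
advanced) use one-way ANOVA with Tukey's HSD (`scipy.stats.tukey_hsd`).

Single-marker ranking applies the stratified resampling above per marker,
overall and for each stage subgroup (that subgroup's cancers vs all benign
samples).  A marker lower in cancer keeps its AUC below 0.5 — orientation
is informative and captured separately by the screening direction.

## LASSO importance ranking (`lasso.py`, `_fast.py`)

Concentrations are log10-transformed (same ε rule) and standardized to
mean 0, sd 1, so penalized coefficients are comparable across markers;
constant columns are dropped and recorded.  Standardization parameters are
stored and re-applied to held-out data using training statistics only.

The L1-penalized logistic path minimizes
`(1/n) Σ log-loss + λ‖β‖₁` (intercept unpenalized) by coordinate descent
with an IRLS outer loop and active-set inner loop, warm-started along a
100-point log-spaced grid from λ_max (the smallest λ with an all-zero
solution, `max_j |x_jᵀ(y − ȳ)|/n`) down to `10⁻⁴ λ_max`.  The solver is a
compiled (numba) kernel because the ranking procedure fits on the order of
10⁵ paths; it reproduces R `glmnet` coefficients to ~10⁻⁷ on shared
fixtures, and that agreement is enforced by a test that runs glmnet as an
independent oracle.  λ is chosen per fit to minimize the mean 10-fold
cross-validated binomial deviance over stratified, shuffled folds; grid
points that fail to converge in any fold are excluded with a warning.

`rank_by_lasso` repeats the CV-tuned fit under re-randomized folds
(default 2000 iterations; reduced counts are used throughout the test
suite) and ranks markers by the mean absolute standardized coefficient,
reporting the selection frequency (fraction of fits with β ≠ 0) alongside.
Two caveats, both verified empirically and visible in the tests: with a
flat deviance curve (little or no signal) the arg-min λ is noisy, so
null-cohort coefficient bounds hold typically rather than per-cohort; and
near the deviance-minimizing λ the model is close to the unpenalized MLE,
whose coefficients absorb sampling partial-correlation noise — weakly
informative markers (d ≈ 0.45 at n ≈ 283) are therefore recovered into
the top ranks in roughly three cohorts out of four, not always.

## Panel selection and evaluation (`panel.py`)

Candidate panels are all 2–4-marker subsets of a pool — by default the
top-8 LASSO-ranked markers (the full 23-marker space of 10 879 subsets is
available but wasteful).  Nested cross-validation separates selection from
assessment:

* **Outer loop** (default 2000 repetitions; 50–200 at desk scale): a
  class-ratio-preserving 80% training draw (largest-remainder counts).
* **Inner loop**: stratified 10-fold CV on the training set (1 round by
  default; configurable) scores every candidate panel by the mean
  held-out-fold AUC of an unpenalized logistic model.  Because logistic
  scores are invariant to affine transforms of the predictors, inner fits
  run on log-transformed values directly; the panel ranking is identical
  to fitting on standardized values.  Folds that would lack a class are
  redrawn (logged).
* The per-split winner of each size is refit on the full training 80% and
  measured on the untouched 20%; the modal winner across repetitions is
  refit on the full cohort as the final `PanelModel`, with its full-data
  DeLong interval reported next to the outer held-out mean AUC.  The two
  numbers answer different questions (optimism vs generalization) and are
  always labeled distinctly.

Final fits are damped-Newton logistic regressions with a 10⁻¹⁰ ridge;
apparent separation triggers a 10⁻⁶ ridge stabilizer with a warning.  The
decision threshold maximizes the F-score (F1 by default, β configurable)
over all midpoints between adjacent distinct training scores plus {0, 1},
cancer as the positive class, ties resolved toward the higher threshold
(higher specificity).  Evaluation reports AUC with DeLong CI, SN/SP/PPV/
NPV at the threshold, and the sensitivity at fixed specificities
SP ∈ {70, 75, 80, 85, 90, 95}% on the step-function ROC (no
interpolation), with the achieved SP printed alongside; subgroup
evaluations compare each stage group's cancers against all benign
samples.  Menopausal status (post = 1, pre = 0) can be added as a
covariate; samples with unknown status are excluded from covariate models
only.

## Synthetic cohorts (`simulate.py`)

The generator draws log10 concentrations multivariate normal with unit
marginal variances: benign mean 0, cancer mean `±d` per marker (stage-
specific where configured), borderline tumors at half the average cancer
offset.  Under this equal-variance binormal model the population AUC of a
single marker is `Φ(d/√2)`, so effects can be calibrated to target AUCs
exactly — the minimal distributional family with that closed form.  A
per-marker baseline (uniform in 1–4 log10 units) gives realistic
concentration scales without affecting any contrast.  Cohort composition
defaults to 125 benign / 12 borderline / 48 early- / 110 advanced-stage
cancer samples; menopausal status is Bernoulli with post-probability
25/124 (benign) and 92/158 (cancer), one benign teratoma patient carrying
unknown status; ages are truncated normal (40.6 ± 12.2 benign,
53.8 ± 10.4 cancer, ≥ 18), used as metadata only.

The default `paperlike_scenario` plants four informative markers — HE4
(AUC 0.822), TTR (0.789 early / 0.757 advanced), CEA (0.627, lower in
cancer), creatinine (0.622, lower in cancer) — among 19 null markers
carrying the remaining panel names.  Inter-marker correlation is identity
by default; a `correlated` preset (r = 0.3 among the informative markers)
exists for panel-level stress tests, because independence understates the
joint separation real marker panels achieve and no real covariance is
available to emulate.  What passing tests show is therefore recovery and
calibration under independence and log-normality — not performance under
real assay noise floors, detection limits, urine-dilution physiology or
the true inter-marker covariance, none of which are modeled.

## Numerical and procedural choices

* Tie handling: midranks everywhere; ties contribute ½ to the AUC.
* Rounding in cohort accounting: percentages are half-up to one decimal
  (`floor(10·pct + 0.5)/10`).
* Coordinate-descent tolerance 10⁻⁷ on the maximum coefficient update;
  Newton tolerance 10⁻¹⁰ for final fits, 10⁻⁶ inside panel scoring (AUC
  ranking is insensitive to the last Newton digits).
* Missing values: complete-case per analysis; a sample missing any marker
  used by a given analysis is dropped from that analysis only.
* All procedures take one master seed; every resampling iteration or
  repetition derives an independent substream, so results are
  bit-reproducible and order-independent.
* Reported tables use three-decimal AUCs and one-decimal percentages.

## Problem sizes used in the test suite

Simulation-backed tests run at reduced repetition counts chosen as the
package's own desk-scale defaults: 100–200 resampling iterations for
single-marker tables, 4–200 LASSO iterations, 6–100 outer repetitions for
nested CV, and 25–500 generated cohorts per calibration check.  The
deviation between reduced and full-scale runs is itself covered by
reproducibility and stability tests.

## Known limitations

* The generator's independence default makes multimarker AUCs add more
  optimistically than correlated real panels would; panel-level absolute
  AUCs from real cohorts are not reproducible from it.
* DeLong intervals are asymptotic; no exact small-sample AUC inference.
* No partial AUC, time-dependent ROC, elastic-net variants, or
  post-selection inference on coefficients.
* Weak markers near the noise floor of the cohort size are not reliably
  recovered by coefficient-magnitude ranking (see the LASSO section); the
  single-marker AUC table is the more sensitive screen at that scale.
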
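# Methods

This note records the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## Cognition model and resilience scores

The composite cognitive z-score follows a linear mixed model with fixed
age (in decades past 70), sex and education effects and a correlated
participant-level random intercept and slope. Time is coded
(age − 70)/10 so the fixed slope reads in SD-units per decade and the
random slope — the resilience score — in the same units. Estimation is
REML via statsmodels `MixedLM`; scores are the BLUPs of the random
slope, i.e. the conditional means given the data, which shrink noisy
per-person slopes toward zero. "Person-specific slope minus overall
slope" equals the BLUP deviation exactly, so the score function is an
identity on the fitted deviations. If the full 2×2 random covariance
fails to converge the model is refit with the intercept–slope
correlation fixed at zero and flagged
(`correlation_fixed_at_zero=True`). A noise-free degenerate cohort
(zero heterogeneity, zero residual) is detected by an exact OLS fit and
returns zero deviations without invoking the mixed-model machinery.

The BLUP was chosen over per-person OLS refits because it is the
conditional mean under the fitted model; an unshrunken per-person OLS
slope helper is exposed (`per_participant_ols_slopes`) and the tests
confirm rank agreement at low noise.

## Synthetic study conditions

The generator emulates a ~237-participant population cohort with three
serum visits. Defaults and their reasoning:

| parameter | default | unit | why |
|---|---|---|---|
| n_participants | 237 | — | cohort size of the emulated study |
| n_visits | 3 | — | serum sampling occasions |
| visit_spacing | 7.5 | years | three consecutive visits spanning ≥ 15 years |
| baseline_age_mean / sd | 70 / 3 | years | selected-visit age ~74 (3.0) after follow-up |
| population_slope | −0.7 | SD/decade | cohort-level cognitive decline after 70 |
| slope_sd | 0.3 | SD/decade | between-person heterogeneity; scores then have SD ≈ 0.3–0.4, matching the reported score spread |
| resid_sd | 0.25 | SD | occasion-level noise of a four-test composite; gives per-person slope reliability ≈ 0.6 at 3 visits, so score recovery r ≈ 0.8 |
| effect_size_resilience | 1.0 | log-area per SD/decade | per-feature abundance shift ⇒ feature–score correlations ≈ 0.3, typical of the highlighted metabolite classes |
| effect_size_age | 0.03 | log-area per year | detectable but not dominant over a 15-year span |
| feature_log_sd | 0.5 | ln units | ≈ 65% CV per feature, realistic for untargeted LC-MS |
| detection_limit | 3 × 10⁴ | area | left-censoring; feature-level means (U[ln 2·10⁴, ln 2·10⁶]) then span presence fractions ~0.2–1 |
| fragment_noise_sd | 0.002 | Da | instrument mass error, well inside the 0.01 Da query tolerance |

Zeros arise **only** by left-censoring at the detection limit, so
presence/absence is informative about abundance — precisely the
structure the hurdle model targets. The resilience effect is applied
through the **true** random slope, not the estimated score, so recovery
tests measure end-to-end estimation error. Sex (0.2 SD) and education
(0.05 SD/yr) offsets exist only to exercise the covariate machinery.
Blank channels sit at a low background level; a small set of contaminant
features dominates the blanks and is removed by the 5× blank filter,
while all planted signal features survive it.

The spectra plant: glucuronides (fragment at precursor − 176.0321 Da,
half also − 194.0425), two β-blocker-like parents carrying all four
backbone ions, metabolites per parent (≥ 3 backbone ions, precursor =
parent + modification delta, earlier RT, occurrences nested in the
parent's), and distractors violating exactly one property each (wrong
loss, too few fragments, later RT, disjoint occurrence).

What the generator does **not** emulate: chromatographic drift and batch
effects, correlated feature blocks (adducts, isotopologues), intensity-
dependent mass error, missingness not caused by censoring, non-linear
cognitive trajectories, and dropout. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data pathologies.

## Preprocessing

Resilience branch: dead volume (RT ≥ 0.7 min) → blank filter (keep iff
mean non-zero sample area ≥ 5 × mean non-zero blank area; mean|max
configurable; blank aggregate 0 keeps the feature) → single-visit
selection → presence ≥ 0.4 → RCLR → age residualization → near-zero
variance. Aging branch: dead volume → blank filter → presence ≥ 0.3 →
per-feature pseudocount (half the minimum non-zero area) → natural log.
The published description of the sparsity cutoff is ambiguous between
"< 70%" and "≥ 40%" readings, so the threshold is an explicit
minimum-presence-fraction parameter with per-branch defaults.

RCLR centers each sample's log areas on the mean over that sample's
*detected* features only; zeros stay missing (NaN) and are mean-filled
per feature just before the sparse fit (recorded in the fit). RCLR is
invariant to per-sample multiplicative scaling, which the tests assert.

Visit selection minimizes the cohort SD of selected ages by coordinate
descent (re-choose each participant's visit to minimize the SD, ties to
the earlier visit) from a deterministic set of starts: every uniform
visit index plus every closest-to-target-age assignment at the
breakpoints between a participant's consecutive ages. Any coordinate-
descent fixed point assigns each participant the age closest to the mean
of the others, so these starts cover the optimum's basin; the result
matched exhaustive search on every random small instance tried (200+),
and is never worse than the best uniform choice by construction. The
external visit is the unselected one closest in age to the selected one,
ties to the earlier visit.

## Sparse PLS

One response, one component, hard-wired. For this case the loading
weight is the soft-thresholded cross-covariance keeping the `keep`
largest |entries| — provably the top-|covariance| set, which the tests
verify against brute force on random problems. Columns are centered and
unit-variance scaled by default (recorded in the fit). Monotone
containment in `keep` and sign-flip equivariance follow from the
construction and are asserted.

`keep` is tuned by locating the knee of the ranked |covariance| curve
(max gap below the endpoint chord after normalizing both axes — a
unit-invariant stand-in for a scree read-off, not a reconstruction of
any particular tool) and scoring candidate keeps near it by 10-fold CV
RMSE with a one-standard-error rule toward smaller keep. Under a pure-
noise response the smallest keep is the most selection-overfit, so the
one-SE rule picks the grid minimum only ~75% of the time — an honest
property of CV under selection, frozen as such in the tests.

Performance: out-of-fold predictions assembled over folds; observed
r = Pearson(y, ŷ_oof); cv R² = r²; RMSE on out-of-fold predictions.
Stability = fraction of folds a feature is selected. Permutation p =
(1 + #{R²_perm ≥ R²_obs})/(n_perm + 1), floor 1/101 at n_perm = 100.
The variance-explained p-value is the regression F-test of y on the
latent score. External validation reports projection R² and p, external
CV observed r, Jaccard of the selected sets, loading-weight Pearson
correlation over the **union** of both selected sets (unselected = 0;
the intersection convention is equally defensible but unstated in the
source analyses), and the reselection fraction of the top 5% |weights|.

## Per-feature inference

Hurdle step 1 is a logistic regression of detection on resilience
(Newton IRLS via statsmodels), p from the likelihood-ratio test against
the intercept-only model; it is skipped when either presence group has
fewer than `min_group` = 5 samples, or under (quasi-)separation,
detected by non-convergence or |coefficient| > 50. Step 2 is OLS of
ln(area) on resilience over detected samples (exact t-test). BH runs
within each step over estimable features. Under the null generator both
steps' raw p-values are KS-uniform and the step-2 BH discovery fraction
is ~0 (verified at 2000 features).

Age mixed models fit ln(abundance) ~ centered age with participant
random intercept + random age slope. The `singular_fit` flag marks
**absence of detectable slope heterogeneity**: the random-slope variance
on its zero boundary, or a non-significant REML likelihood-ratio test of
that variance against the random-intercept-only model (0.5χ²₀ + 0.5χ²₁
boundary mixture, α = 0.05). A raw boundary check alone is vacuous with
three visits, since REML rarely lands exactly on zero. Because the
source analyses describe the aging selection in opposite terms in
different places, both rules (`require_singular`, the default, and
`require_nonsingular`) are implemented and both counts always reported.

Fold changes are log2 of high/low group means of raw areas over detected
samples, tested by two-sided Wilcoxon rank-sum on log areas, BH within
the tested family; features absent in a whole group get ±inf-coded FC
and no test. The median split assigns median-tied samples to the low
group.

## Spectral queries

Element masses are monoisotopic on the carbon-12 scale; every
modification delta is derived from a stated composition change
(glucuronidation = +C6H8O6 = +176.0321; combinations sum). The quoted
hydrated glucuronide loss 194.0425 differs from the computed
C6H8O6+H2O = 194.0427 by 0.0002 Da; both sit far inside the 0.01 Da
default tolerance, so the quoted constant is used as the query value.
Matching is presence-based (intensities ignored; optional relative
floor), invariant to peak order and intensity scaling. The default
tolerance of 0.01 Da is stricter than the 0.05 Da used for library
searching; 3 of 4 backbone fragments are required by default. Parent
assignment picks the parent whose precursor delta is nearest to a known
modification delta (ties flagged ambiguous); candidates within tolerance
of a parent's own precursor are labeled as the parent and excluded from
the metabolite pipeline. RT precedence is strict (equal RT fails;
missing RT is indeterminate, not false).

## Problem sizes and determinism

Tests and the acceptance script run on deliberately scaled problems
chosen as the smallest sizes at which the statistical claims are
meaningful: oracle checks on 20×15 matrices (100 draws), visit selection
vs brute force at 6–8 participants × 3 visits (3⁶–3⁸ combinations),
score recovery at the full 237 × 3 design over 20 seeds, support
recovery at n = 240, p = 2000 with 100 planted features, null
calibration at 2000 features, and spectral checks on the full planted
spectrum set. All randomness flows through explicit seeds
(`numpy.random.default_rng`); the pipeline manifest records SHA-256
hashes of every output and reruns are byte-identical.

## Known limitations

- One sparse-PLS component only; multi-component or multi-block designs
  are out of scope.
- The hurdle model conditions on the preprocessing; presence is defined
  after blank filtering, not on raw detections.
- The knee criterion is a generic unit-invariant rule, not a
  reconstruction of any specific tuning tool.
- Mixed models use a single optimizer configuration; pathological
  features fall back to OLS with a convergence flag rather than being
  re-tried across optimizers.
- The generator's independence of features understates the multiplicity
  burden of correlated real metabolomes; FDR calibration results carry
  that caveat.
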
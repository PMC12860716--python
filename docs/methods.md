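# Methods

This note documents the models behind `tautrial`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Generating model for synthetic cohorts

Each outcome (clinical score or regional MRI measure) of subject *i*
follows a subject-level linear trajectory in months,

    y_it = (μ0 + b0_i + s_site) + (β1 + b1_i) · t + ε_it,

with `(b0_i, b1_i)` bivariate normal (SDs `sd_intercept`, `sd_slope`,
correlation `corr`) and `ε_it ~ N(0, sd_residual²)`. Linearity is
deliberate: the downstream estimand is the mean slope, and the analysis
models are linear in time, so the generator matches the estimand rather
than modelling floor/ceiling or stage-dependent nonlinearity. When a
12-month change is specified in percent, the fixed slope is scaled to the
subject's *own* baseline (`β1_i = Δ12/100 · y_i0 / 12`), which makes the
noiseless percent change at month 12 exactly `Δ12` regardless of baseline
spread.

Visit schedules are nominal times (baseline 0, gaps ≥ 4 months — the
same spacing floor the inclusion filter enforces) with optional Gaussian
jitter; a `fixed` schedule reproduces trial designs with exact visits and
no attrition. Attrition is monotone dropout with a per-visit hazard: the
baseline visit is never removed, and subjects left without two visits ≥ 4
months apart are excluded and counted, exactly as the reader excludes
them on ingest. Among retained subjects the fraction missing the final
visit of a three-visit schedule equals the hazard, which is what the
moment tests check.

Site effects are an additive shift plus a multiplicative scale per site,
both defaulting to zero so that harmonization is not needed for the core
analyses; users with harmonizers can switch them on. Plasma pTau-217 is
drawn from two log-normal components conditional on amyloid-PET status
(medians 0.45 and 0.12 pg/mL, log-SDs 0.45/0.50), chosen so the 0.25
pg/mL positivity threshold separates the components at roughly 90%
concordance each way — imperfectly, as in real assays.

**What the generator does not emulate.** Outcomes are generated
independently of one another: there is no shared disease-severity factor
linking, say, the PSPRS slope to regional atrophy slopes, and no spatial
covariance among regions. Consequently, tests of the clinical-relevance
regression use explicitly constructed relations (deterministic or null),
and a passing suite says nothing about the strength of clinical-imaging
coupling in real cohorts — only that the regression machinery recovers
whatever coupling exists. Similarly, there is no scanner drift, no
intermittent missingness (dropout is monotone), and no disease-stage
dependence of slopes.

**Default preset magnitudes.** The observational preset uses three
etiologies with mixed clinical phenotypes. Baseline means/SDs (PSPRS
33 ± 14 in PSP, 21 ± 13 in CBD, 15 ± 11 in AD; midbrain 4826 ± 536 mm³ in
PSP vs ≈ 5940 ± 610 mm³ in CBD/AD) and 12-month changes (PSPRS +11.9 /
+8.4 / +8.5 points; midbrain −5.3 % / −6.6 % / −0.9 %) follow the
magnitudes published for these populations. Variance components are not
published for such cohorts, so they were set once to values that put
single-endpoint trial sizes in the few-hundred range typical of published
designs: PSPRS slope SD 0.75 points/month and residual SD 5 points; for
MRI measures, residual noise 1.5 % (volumes) or 1.2 % (thickness) of the
regional mean and slope SD ≈ 2 %/year (volumes) or 1 %/year (thickness).
Cortical regions differ by etiology (temporal/frontal atrophy faster in
PSP; superior frontal, insula and banks of the superior temporal sulcus
faster in CBD; pericalcarine spared) so that signature search has a real
structure to find.

## Enrichment

The etiologic classifier is a multinomial logistic regression on z-scored
baseline features (regional measures, age, sex), fitted by maximum
likelihood with a ridge penalty of 1e-6 so that a finite solution exists
under perfect separation (detected separation emits a warning). Which
regional features enter is configuration, not dogma — the default is
every catalogued region. A PSP-vs-any variant (all non-PSP labels
collapsed) is available behind `collapse_other=True`; the two-class
PSP-vs-CBD contrast is the default. TIV-ratio adjustment of volumes is
left to the caller (the `tiv` column is carried through ingest).

Cut-point optimization scans candidate thresholds exhaustively — the
midpoints between sorted unique predicted probabilities — and maximizes
the Youden index by default (configurable to accuracy). The metric to
optimize and the aggregation of bootstrap optima are genuinely open
choices; we default to Youden and to the mean of per-resample optima
(median available) because they are the conventional defaults of cutpoint
tooling and reproduce the expected sensitivity/specificity trade-off
shape. Ties among equal-metric candidates resolve to the midpoint of the
optimal interval. Degenerate bootstrap resamples (single class) are
dropped, not redrawn. AUC uses the Mann-Whitney rank statistic with
midranks for ties.

Reclassification rules run in a fixed order: (1) CBS participants
positive on AD biomarkers become AD (pTau-217 ≥ 0.25 pg/mL; amyloid-PET
is the reference when the two disagree); (2) everyone else is labelled
MRI-PSP or MRI-CBD by thresholding baseline `p_PSP`; (3) RS participants
with positive AD biomarkers keep the MRI label and are flagged as likely
co-pathology. Subjects with no usable biomarkers fall through to the MRI
rule with a logged note. Every subject receives exactly one label.

## Longitudinal models

Mixed models are fitted by REML through `statsmodels.MixedLM` with random
intercept and slope on time. Numerical decisions:

* **Optimizer retries.** Boundary-adjacent REML surfaces (slope variance
  or correlation near its limit) defeat single optimizers regularly; the
  fit walks lbfgs → bfgs → powell and keeps the first converged result.
  Non-convergence is flagged on the fit, and downstream consumers refuse
  flagged fits unless forced.
* **Degenerate inputs.** Noise-free cohorts (an exact linear fit) are
  detected via the OLS residual sum of squares and resolved by OLS with
  zero variance components, avoiding a singular REML problem.
* **Singular random-effects covariance** triggers a refit with a
  slope-only random effect and a warning.
* **Inference.** Contrast p-values and CIs use the large-sample normal
  (Wald) reference rather than a finite-sample degree-of-freedom
  approximation. At the cohort sizes this package targets (tens to
  hundreds of subjects) the difference is immaterial, and the choice is
  consistent with the z-quantile design formula; a Satterthwaite-style
  correction was considered and not implemented.
* **Covariates.** The default adjustment set is baseline age, sex and the
  baseline outcome value. Baseline-outcome adjustment is retained even
  though modelled change at baseline is zero, because it absorbs
  between-subject variability at entry; when the outcome is a percent
  change (identically zero at baseline) the raw measure's baseline is
  used instead. Marginal 12-month changes are `12 × slope`; covariates
  enter without time interactions, so covariate reference values cancel
  out of the change.
* **Time** is months since baseline, centred at 0, throughout.

Fixed two-visit designs use ordinary least squares on follow-up-minus-
baseline change scores with the same adjustment set; for balanced
complete data the mixed-model group-slope contrast and the change-score
OLS contrast coincide, which the tests verify directly.

## Trial design

The sample-size formula is the conditional random-slope (Edland-family)
expression given in the README; the formula family is deliberately
auditable because every analytic `n` is cross-checked by Monte Carlo
simulation. Rounding order is: ceil per arm, inflate the two-arm total by
1/(1−a), ceil again. Attrition is handled as inflation of enrolment, not
as within-trial missingness, matching how attrition rates enter such
formulas; the simulator supports both interpretations
(`enrollment_loss`, where dropouts contribute nothing, and `staggered`,
where dropouts stop attending at a random visit but contribute noisier
slopes if they retain two visits).

`simulate_power` generates per-subject OLS slope estimates directly from
the generating model (true slope plus the residual projection
`Σ w_j ε_j`, `w = (t−t̄)/Sxx` — algebraically identical to running the
per-subject regression) and rejects on the pooled two-sample statistic
against the **normal** reference. The normal reference is the analysis
the z-quantile formula assumes and matches the package-wide Wald
convention; with a t reference the empirical power at the designed n sits
a fraction below the nominal target purely through the
degrees-of-freedom correction the formula ignores. The cost is a type-I
rate a shade above nominal at small n (≈ 0.053 at ~45 subjects/arm),
which the calibration tests bound.

"Jackknife bootstrapping" for CIs on `n_total` is implemented as the
leave-one-subject-out jackknife with the standard jackknife variance
estimator around the full-sample estimate; a subject-level percentile
bootstrap is provided as an alternative. Failed leave-one-out refits are
dropped with a warning and counted.

## Signature search

Candidate regions are those whose single-group percent-change mixed model
shows a negative time effect with raw p < 0.05 — a screen, not an
inference, hence no multiplicity correction (configurable). The composite
is the unweighted mean of per-region percent changes: percent change
makes mixed units commensurable, the equal weighting keeps the endpoint
interpretable and pre-specifiable, and a z-score-weighted alternative was
considered and rejected as harder to justify prospectively. The search
enumerates every subset of size 1..5 (guarded at 50,000 subsets for
computational feasibility), fits the pilot model per subset, and sorts by
`(n_total, subset size, lexicographic names)` so ranking is deterministic
and permutation-invariant. Non-convergent pilot fits skip the subset with
a log entry.

Clinical relevance of a signature is a per-subject OLS of clinical change
(last visit minus baseline) on signature percent change, adjusting for
baseline age, baseline clinical score and the baseline values of the
constituent regions; all terms are z-scored so the reported coefficient
is a standardized β, and zero-variance covariates are dropped (they carry
no information and would otherwise poison the standardization).

## Problem sizes used in the tests

The suite exercises the full pipeline at sizes chosen to keep the
Monte Carlo error bounds meaningful: 2000 replicate trials for the
power/type-I calibration (binomial SE ≈ 0.9 %/0.5 %), 50 replicate
cohorts of 300 subjects for slope/variance recovery, 200 replicates of
100 subjects for CI coverage, and a 6-candidate exhaustive search (62
subsets) for the enumeration-equivalence check. The pipeline tests run a
~80-subject cohort end to end twice to verify byte-level determinism.

## Known limitations

* Sample sizes estimated on the same cohort that selected the signature
  are optimistic; the search is not cross-validated (by design — the
  selection procedure itself is the object under test).
* The classifier's feature set and the enrichment cut-off are
  cohort-dependent; thresholds should be recalibrated per clinical
  context rather than copied.
* The generator's independence across outcomes limits what relevance
  analyses can show on synthetic data (see above).
* ComBat-style harmonization is out of scope; the generator can produce
  site effects so external harmonizers can be plugged in and assessed.
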
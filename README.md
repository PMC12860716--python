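# tautrial

**MRI-guided clinical-trial design for 4-repeat tauopathies.**

Disease-modifying trials in progressive supranuclear palsy (PSP) and
corticobasal degeneration (CBD) face two structural problems. First,
entry criteria based on clinical phenotype (Richardson's syndrome as a
proxy for PSP pathology, corticobasal syndrome for CBD) misclassify a
substantial minority of participants, diluting any pathology-specific
treatment effect. Second, clinical rating scales (PSPRS, SEADL) are noisy
progression endpoints, so slope-slowing trials powered on them need
hundreds of participants. `tautrial` implements, as a tested and reusable
pipeline, a two-step MRI-guided remedy: **enrich** the trial population
with an MRI-based etiologic classifier plus AD-biomarker reclassification
rules, and **track progression** with data-driven composite MRI atrophy
signatures chosen to minimize the required trial size.

The package is aimed at biostatisticians and neuroimaging researchers
designing longitudinal trials; all stages run end-to-end on synthetic
cohorts with the statistical structure of multi-site observational 4RT
studies, so every method is testable without access to restricted patient
data.

## What it computes

**Enrichment.** A multinomial logistic model on baseline regional MRI
measures, age and sex yields each participant's probability of underlying
PSP pathology, `p_PSP`. The operating cut-off `c` is optimized by
exhaustive scan over midpoints of the sorted predicted probabilities
inside a bootstrap (default metric: Youden index `J = sens + spec − 1`).
Corticobasal-syndrome participants positive on AD biomarkers (plasma
pTau-217 ≥ 0.25 pg/mL; amyloid-PET is the reference when discordant) are
reclassified as AD; the rest become MRI-PSP (`p_PSP ≥ c`) or MRI-CBD.

**Progression.** Linear mixed-effects models with random per-subject
intercepts and slopes on time (months),

&nbsp;&nbsp;&nbsp;&nbsp;`y_it = (β0 + b0_i) + (β1_g + b1_i)·t + covariates + ε_it`,

fitted by REML, give each group's mean slope `β1_g` and the 12-month
change `12·β1_g` with its CI. Fixed two-visit trial cohorts use
baseline-adjusted change-score OLS instead.

**Trial size.** For a two-arm trial detecting a fractional slowing `f` of
the control slope with two-sided level `α`, power `1−β` and attrition `a`:

```
V        = σ²_b1 + σ²_ε / Σ_j (t_j − t̄)²          (per-subject slope variance)
n/arm    = ⌈ 2 (z_{1−α/2} + z_{1−β})² V / (f·|β1|)² ⌉
n_total  = ⌈ 2·(n/arm) / (1 − a) ⌉
```

the random-slope (Edland-family) formula. Confidence intervals on
`n_total` come from a leave-one-subject-out jackknife over the pilot
cohort, and every analytic `n` can be verified by seeded Monte Carlo
trial simulation (`simulate_power`).

**Signature search.** Among regions showing longitudinal atrophy, every
subset of ≤ 5 regions is evaluated: the composite endpoint is the
unweighted mean of per-region percent changes from baseline (dimensionless,
so brainstem volumes and cortical thicknesses combine), a pilot mixed
model is fitted on the composite, and subsets are ranked by the trial
size they imply. The search is exactly exhaustive with deterministic
tie-breaking.

## Worked example

```python
import tautrial as tt
from tautrial.longitudinal import LMMSpec

cohort = tt.generate_cohort(tt.observational_4rt_config(seed=1))

train = cohort.subset(cohort.data["group"].isin(["PSP", "CBD"]))
model = tt.fit_diagnostic_model(train)
base = train.baseline()
cut = tt.optimize_cutpoint(model.p_positive(base).to_numpy(),
                           (base["group"] == "PSP").to_numpy(),
                           n_boot=1000, seed=2)

fit = tt.fit_lmm(cohort, LMMSpec(outcome="PSPRS"))
for g in fit.group_levels:
    ch, ci = tt.estimate_12mo_change(fit, g)
    print(f"{g}: 12-month PSPRS change {ch:.2f} (95% CI {ci[0]:.2f} to {ci[1]:.2f})")

psp = cohort.for_group("PSP")
pilot = tt.fit_lmm(psp, LMMSpec(outcome="Midbrain", transform="pct_change",
                                covariates=("age_baseline", "sex")))
res = tt.required_n_slope(tt.design_from_fit(pilot))
check = tt.simulate_power(res.n_total, tt.design_from_fit(pilot), n_reps=2000, seed=3)
ranked = tt.search_best_signature(psp, design=tt.DesignInput(), max_size=4)
```

prints, with these seeds:

```
AD: 12-month PSPRS change 1.97 (95% CI -4.96 to 8.90)
CBD: 12-month PSPRS change 6.92 (95% CI 3.16 to 10.67)
PSP: 12-month PSPRS change 13.38 (95% CI 10.02 to 16.73)
```

and the design stage reports `cutoff=0.64, AUC=0.99` for the classifier,
a midbrain percent-change slope of −0.426 %/month giving `n_total = 169`
for the 30 %-slowing trial (empirical power at that n: 0.804 ± 0.009 over
2000 simulated trials), and best composite signature
`Midbrain+Pons+RostralMiddleFrontal+SuperiorTemporal` with `n_total = 54`
— a three-fold reduction against single-region midbrain volumetry,
the pattern that motivates composite endpoints: averaging percent change
over several atrophy-sensitive regions cancels region-specific measurement
noise while preserving the progression signal.

## Command line

```bash
tautrial simulate --preset observational --seed 1 --out cohort.csv
tautrial enrich   --cohort cohort.csv --cutoff auto --n-boot 10000 --out-prefix enr
tautrial fit      --cohort cohort.csv --outcome Midbrain --transform pct_change --out fit.json
tautrial design   --fit fit.json --group PSP --effect 0.30 --attrition 0.10 --out design.json
tautrial search   --cohort cohort.csv --group PSP --max-size 5 --out ranked.csv
tautrial run      --config run.yaml     # full pipeline with one global seed
```

`tautrial run` writes per-stage artifacts (cohort, labels, cut-point
metrics, ranked subsets, fit summaries) and a report table comparing
`n_total` across selection strategies (clinical phenotype vs MRI/biomarker
enrichment) and endpoints (clinical scale vs midbrain vs signature).

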
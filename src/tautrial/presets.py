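"""Default synthetic-cohort configurations.

Two presets mirror the designs this package targets:

* an observational multi-site 4R-tauopathy cohort (three generating
  etiologies — PSP, CBD, AD — with mixed clinical phenotypes, 2-4 visits on
  a nominal 0/6/12-month schedule with jitter and attrition), and
* a trial-like cohort (RS-phenotype participants, fixed baseline and
  12-month visits, complete data).

Baseline means/SDs and 12-month changes follow the magnitudes published
for these populations (PSPRS in the low-to-mid 30s for PSP with a roughly
+12-point/year rise; midbrain volume near 4.8 cm^3 in PSP vs 5.9 cm^3 in
CBD/AD with 5-7%/year loss in 4RT but near-stability in AD).  Variance
components were chosen so that single-endpoint trial sizes computed from
these cohorts land in the few-hundred range typical of published designs:
slope SD about 0.75 PSPRS points/month, residual SD 5 points for PSPRS;
for MRI measures, residual noise of 1-1.5% of the regional mean and a
slope SD near 2%/year.
"""

from __future__ import annotations

from .cohort import (
    BRAINSTEM_VOLUME,
    CORTICAL_THICKNESS,
    CohortConfig,
    GroupSpec,
    OutcomeSpec,
    SiteSpec,
    VisitSchedule,
)


def _score(name, mean, sd, delta12, sd_slope, sd_resid):
    return OutcomeSpec(
        name=name, kind="score", baseline_mean=mean, sd_intercept=sd,
        delta12=delta12, sd_slope=sd_slope, sd_residual=sd_resid,
        lower=0.0, upper=100.0,
    )


def _volume(name, mean, sd, delta12_pct, kind=BRAINSTEM_VOLUME):
    # slope SD ~2%/year of the mean; residual ~1.5% of the mean
    return OutcomeSpec(
        name=name, kind=kind, baseline_mean=mean, sd_intercept=sd,
        delta12=delta12_pct, delta12_is_percent=True,
        sd_slope=0.02 * mean / 12.0, sd_residual=0.015 * mean,
        lower=1.0,
    )


def _thickness(name, mean, sd, delta12_pct):
    # slope SD ~1%/year of the mean; residual ~1.2% of the mean
    return OutcomeSpec(
        name=name, kind=CORTICAL_THICKNESS, baseline_mean=mean, sd_intercept=sd,
        delta12=delta12_pct, delta12_is_percent=True,
        sd_slope=0.01 * mean / 12.0, sd_residual=0.012 * mean,
        lower=0.5, upper=5.9,
    )


def _psp_outcomes():
    return (
        _score("PSPRS", 33.0, 14.0, 11.91, 0.75, 5.0),
        _score("SEADL", 59.0, 24.0, -10.0, 0.60, 6.0),
        _volume("Midbrain", 4826.0, 536.0, -5.27),
        _volume("Pons", 14500.0, 1500.0, -4.5),
        _thickness("SuperiorTemporal", 2.55, 0.15, -2.5),
        _thickness("RostralMiddleFrontal", 2.30, 0.14, -2.5),
        _thickness("SuperiorFrontal", 2.55, 0.15, -1.5),
        _thickness("Insula", 2.85, 0.15, -1.2),
        _thickness("BanksSTS", 2.40, 0.14, -1.0),
        _thickness("Pericalcarine", 1.55, 0.12, 0.0),
    )


def _cbd_outcomes():
    return (
        _score("PSPRS", 21.0, 13.0, 8.37, 0.75, 5.0),
        _score("SEADL", 66.0, 22.0, -8.0, 0.60, 6.0),
        _volume("Midbrain", 5940.0, 618.0, -6.63),
        _volume("Pons", 15200.0, 1500.0, -5.0),
        _thickness("SuperiorTemporal", 2.60, 0.15, -1.5),
        _thickness("RostralMiddleFrontal", 2.35, 0.14, -1.2),
        _thickness("SuperiorFrontal", 2.50, 0.15, -3.0),
        _thickness("Insula", 2.80, 0.15, -3.0),
        _thickness("BanksSTS", 2.38, 0.14, -2.8),
        _thickness("Pericalcarine", 1.55, 0.12, 0.0),
    )


def _ad_outcomes():
    return (
        _score("PSPRS", 15.0, 11.0, 8.54, 0.75, 5.0),
        _score("SEADL", 70.0, 21.0, -6.0, 0.60, 6.0),
        _volume("Midbrain", 5936.0, 604.0, -0.94),
        _volume("Pons", 15300.0, 1500.0, -0.8),
        _thickness("SuperiorTemporal", 2.50, 0.15, -1.5),
        _thickness("RostralMiddleFrontal", 2.30, 0.14, -1.0),
        _thickness("SuperiorFrontal", 2.50, 0.15, -1.0),
        _thickness("Insula", 2.75, 0.15, -1.2),
        _thickness("BanksSTS", 2.35, 0.14, -1.0),
        _thickness("Pericalcarine", 1.55, 0.12, 0.0),
    )


def observational_4rt_config(
    seed: int = 0,
    n_psp: int = 51,
    n_cbd: int = 41,
    n_ad: int = 14,
    attrition_hazard: float = 0.10,
    n_sites: int = 7,
) -> CohortConfig:
    """Observational multi-etiology cohort with variable follow-up."""
    groups = (
        GroupSpec(
            label="PSP", n_subjects=n_psp, outcomes=_psp_outcomes(),
            phenotype_probs={"RS": 0.76, "CBS": 0.24},
            age_mean=70.0, prob_female=0.61, amyloid_prevalence=0.10,
        ),
        GroupSpec(
            label="CBD", n_subjects=n_cbd, outcomes=_cbd_outcomes(),
            phenotype_probs={"CBS": 0.66, "RS": 0.20, "nfvPPA": 0.14},
            age_mean=65.0, prob_female=0.41, amyloid_prevalence=0.05,
        ),
        GroupSpec(
            label="AD", n_subjects=n_ad, outcomes=_ad_outcomes(),
            phenotype_probs={"CBS": 0.86, "nfvPPA": 0.14},
            age_mean=67.0, prob_female=0.36, amyloid_prevalence=1.0,
        ),
    )
    return CohortConfig(
        groups=groups,
        schedule=VisitSchedule(nominal_times=(0.0, 6.0, 12.0), jitter_sd=1.0),
        attrition_hazard=attrition_hazard,
        site=SiteSpec(n_sites=n_sites),
        seed=seed,
    )


def trial_config(seed: int = 0, n_psp: int = 85, n_cbd: int = 15) -> CohortConfig:
    """Trial-like cohort: RS phenotype only, fixed 0/12-month visits,
    complete data (no jitter, no attrition)."""
    groups = (
        GroupSpec(
            label="PSP", n_subjects=n_psp, outcomes=_psp_outcomes(),
            phenotype_probs={"RS": 1.0}, age_mean=68.0, prob_female=0.56,
        ),
        GroupSpec(
            label="CBD", n_subjects=n_cbd, outcomes=_cbd_outcomes(),
            phenotype_probs={"RS": 1.0}, age_mean=61.0, prob_female=0.40,
        ),
    )
    return CohortConfig(
        groups=groups,
        schedule=VisitSchedule(nominal_times=(0.0, 12.0), fixed=True),
        attrition_hazard=0.0,
        seed=seed,
    )
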
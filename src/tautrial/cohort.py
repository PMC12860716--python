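"""Longitudinal cohort container and synthetic cohort generator.

The analyses in this package operate on long-format visit tables: one row
per subject per scan/assessment, carrying clinical scores (PSPRS, SEADL,
...) and regional MRI measures (hemisphere-averaged cortical thickness in
mm, subcortical/brainstem volumes in mm^3).  Because multi-site 4R-tauopathy
imaging cohorts are not openly redistributable, the generator here produces
cohorts with the statistical structure those analyses assume: subject-level
linear trajectories with correlated random intercepts and slopes, residual
measurement noise, variable visit schedules, monotone attrition, optional
additive/multiplicative site effects, and AD biomarkers (amyloid-PET status
plus a plasma pTau-217 value drawn from a two-component log-normal mixture).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# region kinds
SCORE = "score"
CORTICAL_THICKNESS = "cortical_thickness"
SUBCORTICAL_VOLUME = "subcortical_volume"
BRAINSTEM_VOLUME = "brainstem_volume"
REGION_KINDS = (CORTICAL_THICKNESS, SUBCORTICAL_VOLUME, BRAINSTEM_VOLUME)

#: columns every cohort table carries before score/region columns
ID_COLUMNS = [
    "subject_id",
    "group",
    "phenotype",
    "time_months",
    "age_baseline",
    "sex",
    "site_id",
    "amyloid_pet",
    "ptau217_pgml",
]
MANDATORY_COLUMNS = ["subject_id", "group", "time_months"]

#: inclusion filter: at least two visits spanning at least this many months
MIN_INTERVAL_MONTHS = 4.0

#: plasma pTau-217 positivity threshold (pg/mL)
PTAU217_THRESHOLD = 0.25


class CohortValidationError(ValueError):
    """A cohort table or cohort configuration violates an invariant."""


class MissingColumnError(CohortValidationError):
    pass


class DuplicateVisitError(CohortValidationError):
    pass


class MissingBaselineError(CohortValidationError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """Generating model for one outcome (clinical score or regional measure).

    The subject-level trajectory is linear in time (months):

        y_it = (mu0 + b0_i + site_shift) + (beta1 + b1_i) * t + eps_it

    with (b0_i, b1_i) bivariate normal (SDs ``sd_intercept``/``sd_slope``,
    correlation ``corr``) and eps_it ~ N(0, sd_residual^2).  The fixed slope
    is ``delta12 / 12`` in native units per month; when ``delta12_is_percent``
    the 12-month change is ``delta12`` percent of the subject's own baseline,
    so a noiseless cohort shows exactly that percent change at month 12.
    """

    name: str
    kind: str = SCORE
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    delta12: float = 0.0
    delta12_is_percent: bool = False
    sd_intercept: float = 0.0
    sd_slope: float = 0.0  # per month, native units
    corr: float = 0.0
    sd_residual: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def validate(self) -> None:
        if self.kind not in (SCORE,) + REGION_KINDS:
            raise CohortValidationError(f"outcome {self.name!r}: unknown kind {self.kind!r}")
        for fname in ("baseline_sd", "sd_intercept", "sd_slope", "sd_residual"):
            if getattr(self, fname) < 0:
                raise CohortValidationError(f"outcome {self.name!r}: {fname} must be >= 0")
        if not -1.0 <= self.corr <= 1.0:
            raise CohortValidationError(f"outcome {self.name!r}: corr must lie in [-1, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """One generating diagnostic group (e.g. PSP / CBD / AD)."""

    label: str
    n_subjects: int
    outcomes: tuple[OutcomeSpec, ...]
    phenotype_probs: Mapping[str, float] = field(default_factory=lambda: {"RS": 1.0})
    age_mean: float = 68.0
    age_sd: float = 8.0
    prob_female: float = 0.5
    amyloid_prevalence: float = 0.0
    amyloid_missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise CohortValidationError(f"group {self.label!r}: n_subjects must be >= 2")
        if abs(sum(self.phenotype_probs.values()) - 1.0) > 1e-9:
            raise CohortValidationError(f"group {self.label!r}: phenotype_probs must sum to 1")
        for spec in self.outcomes:
            spec.validate()


@dataclass(frozen=True)
class VisitSchedule:
    """Nominal visit times in months; baseline is always month 0.

    ``fixed=True`` reproduces a trial-like design (every subject seen exactly
    at the nominal times, no jitter, no attrition); otherwise observational
    follow-up with Gaussian jitter on post-baseline visits, floored so that
    consecutive visits stay >= 4 months apart.
    """

    nominal_times: tuple[float, ...] = (0.0, 6.0, 12.0)
    jitter_sd: float = 0.0
    fixed: bool = False

    def validate(self) -> None:
        t = self.nominal_times
        if len(t) < 2:
            raise CohortValidationError("schedule.nominal_times needs at least 2 visits")
        if t[0] != 0:
            raise CohortValidationError("schedule.nominal_times must start at 0")
        diffs = np.diff(t)
        if np.any(diffs < MIN_INTERVAL_MONTHS):
            raise CohortValidationError(
                f"schedule.nominal_times: consecutive visits must be >= {MIN_INTERVAL_MONTHS} months apart"
            )
        if self.jitter_sd < 0:
            raise CohortValidationError("schedule.jitter_sd must be >= 0")


@dataclass(frozen=True)
class SiteSpec:
    """Multi-site measurement effects: y_site = scale * y + shift."""

    n_sites: int = 1
    shift_sd: float = 0.0
    scale_sd: float = 0.0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise CohortValidationError("site.n_sites must be >= 1")
        if self.shift_sd < 0 or self.scale_sd < 0:
            raise CohortValidationError("site shift/scale SDs must be >= 0")


@dataclass(frozen=True)
class PTauSpec:
    """Plasma pTau-217 mixture, conditional on amyloid-PET status.

    Defaults place the positive component's median at 0.45 pg/mL and the
    negative component's at 0.12 pg/mL, so the 0.25 pg/mL positivity
    threshold separates the components imperfectly (roughly 90% concordance
    each way) rather than deterministically.
    """

    log_mean_positive: float = math.log(0.45)
    log_sd_positive: float = 0.45
    log_mean_negative: float = math.log(0.12)
    log_sd_negative: float = 0.50
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.log_sd_positive < 0 or self.log_sd_negative < 0:
            raise CohortValidationError("ptau log SDs must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise CohortValidationError("ptau.missing_rate must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    schedule: VisitSchedule = field(default_factory=VisitSchedule)
    attrition_hazard: float = 0.0  # per post-baseline visit dropout probability
    site: SiteSpec = field(default_factory=SiteSpec)
    ptau: PTauSpec = field(default_factory=PTauSpec)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise CohortValidationError("groups must be non-empty")
        for g in self.groups:
            g.validate()
        self.schedule.validate()
        if not 0.0 <= self.attrition_hazard < 1.0:
            raise CohortValidationError("attrition_hazard must lie in [0, 1)")
        self.site.validate()
        self.ptau.validate()

    @property
    def region_catalog(self) -> dict[str, str]:
        catalog: dict[str, str] = {}
        for g in self.groups:
            for spec in g.outcomes:
                if spec.kind != SCORE:
                    catalog[spec.name] = spec.kind
        return catalog


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Long-format visit table plus a catalog of region kinds.

    ``data`` has one row per (subject, visit); ``region_catalog`` maps every
    region column to one of ``REGION_KINDS``.  Columns not in ``ID_COLUMNS``
    and not in the catalog are treated as clinical scores / derived outcomes.
    """

    data: pd.DataFrame
    region_catalog: dict[str, str] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise MissingColumnError(f"cohort table lacks mandatory columns: {missing}")
        unknown = [r for r in self.region_catalog if r not in self.data.columns]
        if unknown:
            raise CohortValidationError(f"region_catalog names absent from table: {unknown}")

    @property
    def region_names(self) -> list[str]:
        return list(self.region_catalog)

    @property
    def score_names(self) -> list[str]:
        skip = set(ID_COLUMNS) | set(self.region_catalog) | {"tiv"}
        return [c for c in self.data.columns if c not in skip]

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["time_months"] == 0.0]

    def subset(self, mask) -> "Cohort":
        return Cohort(self.data[mask].reset_index(drop=True), dict(self.region_catalog))

    def for_group(self, label: str, group_col: str = "group") -> "Cohort":
        return self.subset(self.data[group_col] == label)

    def with_column(self, name: str, values) -> "Cohort":
        data = self.data.copy()
        data[name] = np.asarray(values)
        return Cohort(data, dict(self.region_catalog), self.n_excluded)


def validate_cohort_table(df: pd.DataFrame) -> None:
    """Structural checks shared by the reader and the generator."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing mandatory columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "time_months"])
    if dup.any():
        rows = df.loc[dup, ["subject_id", "time_months"]].drop_duplicates()
        raise DuplicateVisitError(
            f"duplicate (subject_id, time_months) rows: {rows.to_dict('records')}"
        )
    has_baseline = df.groupby("subject_id")["time_months"].min()
    lacking = has_baseline[has_baseline != 0.0].index.tolist()
    if lacking:
        raise MissingBaselineError(f"subjects lacking a baseline (time 0) visit: {lacking}")


def apply_inclusion_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Retain subjects with >= 2 visits spanning >= 4 months.

    Returns the filtered table and the number of excluded subjects; each
    exclusion is logged (mirrors the quality-control step applied to real
    longitudinal imaging cohorts before modelling).
    """
    span = df.groupby("subject_id")["time_months"].agg(["min", "max", "count"])
    ok = (span["count"] >= 2) & (span["max"] - span["min"] >= MIN_INTERVAL_MONTHS)
    excluded = span.index[~ok].tolist()
    if excluded:
        logger.warning(
            "excluding %d subject(s) failing the >=2 visits / >=%g months filter: %s",
            len(excluded), MIN_INTERVAL_MONTHS, excluded,
        )
    out = df[df["subject_id"].isin(span.index[ok])].reset_index(drop=True)
    return out, len(excluded)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def _subject_times(rng: np.random.Generator, schedule: VisitSchedule) -> np.ndarray:
    times = np.asarray(schedule.nominal_times, dtype=float)
    if schedule.fixed or schedule.jitter_sd == 0:
        return times.copy()
    out = [0.0]
    for t in times[1:]:
        jittered = t + rng.normal(0.0, schedule.jitter_sd)
        out.append(max(out[-1] + MIN_INTERVAL_MONTHS, jittered))
    return np.asarray(out)


def _n_visits_after_attrition(rng: np.random.Generator, m: int, hazard: float) -> int:
    """Monotone dropout: before each post-baseline visit a subject drops
    with the configured hazard.  The baseline visit is never removed."""
    n = 1
    for _ in range(m - 1):
        if rng.random() < hazard:
            break
        n += 1
    return n


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a synthetic longitudinal cohort from ``config``.

    Deterministic given ``config.seed``.  Subjects left with fewer than two
    visits by attrition are excluded (counted in ``Cohort.n_excluded``),
    mirroring the inclusion filter applied on ingest of real data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule
    site = config.site

    site_shift = rng.normal(0.0, site.shift_sd, size=site.n_sites) if site.shift_sd else np.zeros(site.n_sites)
    site_scale = (
        1.0 + rng.normal(0.0, site.scale_sd, size=site.n_sites) if site.scale_sd else np.ones(site.n_sites)
    )

    rows: list[dict] = []
    sid = 0
    for g in config.groups:
        phen_labels = list(g.phenotype_probs)
        phen_p = np.array([g.phenotype_probs[k] for k in phen_labels])
        for _ in range(g.n_subjects):
            sid += 1
            subject = f"{g.label}_{sid:04d}"
            phenotype = phen_labels[int(rng.choice(len(phen_labels), p=phen_p))]
            age = rng.normal(g.age_mean, g.age_sd)
            sex = "F" if rng.random() < g.prob_female else "M"
            site_id = int(rng.integers(site.n_sites))

            times = _subject_times(rng, schedule)
            if not schedule.fixed and config.attrition_hazard > 0:
                keep = _n_visits_after_attrition(rng, len(times), config.attrition_hazard)
                times = times[:keep]

            amyloid_pos = rng.random() < g.amyloid_prevalence
            if rng.random() < g.amyloid_missing_rate:
                amyloid = "missing"
            else:
                amyloid = "positive" if amyloid_pos else "negative"
            pt = config.ptau
            if rng.random() < pt.missing_rate:
                ptau = np.nan
            elif amyloid_pos:
                ptau = float(rng.lognormal(pt.log_mean_positive, pt.log_sd_positive))
            else:
                ptau = float(rng.lognormal(pt.log_mean_negative, pt.log_sd_negative))

            values: dict[str, np.ndarray] = {}
            for spec in g.outcomes:
                cov = np.array(
                    [
                        [spec.sd_intercept**2, spec.corr * spec.sd_intercept * spec.sd_slope],
                        [spec.corr * spec.sd_intercept * spec.sd_slope, spec.sd_slope**2],
                    ]
                )
                b0, b1 = rng.multivariate_normal([0.0, 0.0], cov) if cov.any() else (0.0, 0.0)
                base = spec.baseline_mean + rng.normal(0.0, spec.baseline_sd) + b0
                if spec.delta12_is_percent:
                    beta1 = (spec.delta12 / 100.0) * base / 12.0
                else:
                    beta1 = spec.delta12 / 12.0
                eps = rng.normal(0.0, spec.sd_residual, size=len(times)) if spec.sd_residual else 0.0
                y = base + (beta1 + b1) * times + eps
                y = site_scale[site_id] * y + site_shift[site_id]
                if spec.lower is not None or spec.upper is not None:
                    y = np.clip(y, spec.lower, spec.upper)
                values[spec.name] = np.atleast_1d(y)

            for j, t in enumerate(times):
                row = {
                    "subject_id": subject,
                    "group": g.label,
                    "phenotype": phenotype,
                    "time_months": float(t),
                    "age_baseline": age,
                    "sex": sex,
                    "site_id": site_id,
                    "amyloid_pet": amyloid,
                    "ptau217_pgml": ptau,
                }
                for name, y in values.items():
                    row[name] = float(y[j])
                rows.append(row)

    df = pd.DataFrame(rows)
    validate_cohort_table(df)
    df, n_excluded = apply_inclusion_filter(df)
    return Cohort(df, config.region_catalog, n_excluded=n_excluded)
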
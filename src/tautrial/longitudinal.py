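"""Longitudinal progression models.

Variable-schedule cohorts are analyzed with linear mixed-effects models:
fixed effects for time (months), diagnostic group and their interaction,
plus baseline age, sex and the baseline outcome value; random per-subject
intercepts and slopes on time.  Fixed two-visit trial cohorts are analyzed
with baseline-adjusted ordinary-least-squares change-score regressions.
Both produce the 12-month change estimates and pairwise group contrasts
that feed the trial-design machinery.

Estimation is restricted maximum likelihood through
:class:`statsmodels.regression.mixed_linear_model.MixedLM`.  Contrast
p-values and confidence intervals use the normal (Wald) approximation;
this is the package-wide default because subject counts in the intended
use cases are large enough that finite-sample degree-of-freedom
corrections change nothing material.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import Cohort

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


class ModelError(ValueError):
    pass


class NotConvergedError(ModelError):
    pass


# ---------------------------------------------------------------------------
# outcome transforms
# ---------------------------------------------------------------------------


def percent_change_transform(cohort: Cohort, measure: str) -> pd.Series:
    """Percent change from each subject's own baseline:
    ``100 * (v_it - v_i0) / v_i0`` (exactly 0 at baseline).

    Raises when a subject's baseline value is not strictly positive, since
    percent change is then undefined.
    """
    df = cohort.data
    if measure not in df.columns:
        raise ModelError(f"measure {measure!r} absent from cohort")
    base = df[df["time_months"] == 0.0].set_index("subject_id")[measure]
    bad = base[base <= 0]
    if len(bad):
        raise ModelError(f"non-positive baseline {measure!r} for subjects: {bad.index.tolist()}")
    b = df["subject_id"].map(base)
    out = 100.0 * (df[measure] - b) / b
    out.name = f"{measure}_pct"
    return out


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMMSpec:
    """What to fit: outcome, optional percent-change transform, grouping
    column and adjustment covariates.

    ``baseline_value`` in ``covariates`` adjusts for the subject's baseline
    outcome (per-protocol in the intended analyses: it controls
    between-subject variability at entry).  When the outcome is a percent
    change the raw measure's baseline is used instead, because the
    transformed outcome is identically zero at baseline.
    """

    outcome: str
    transform: str = "none"  # none | pct_change
    group_col: str = "group"
    covariates: tuple[str, ...] = ("age_baseline", "sex", "baseline_value")
    time_col: str = "time_months"


@dataclass
class LMMFit:
    """Fixed effects, variance components and metadata from one fit."""

    spec: LMMSpec
    group_levels: list[str]
    reference: str | None
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    sigma2_b0: float
    sigma2_b1: float
    rho: float
    sigma2_resid: float
    n_subjects: int
    n_obs: int
    converged: bool
    singular: bool = False
    degenerate: bool = False

    def _slope_terms(self, group: str | None) -> list[str]:
        terms = [self.spec.time_col]
        if group is not None and self.reference is not None and group != self.reference:
            if group not in self.group_levels:
                raise ModelError(f"group {group!r} not in fit (levels: {self.group_levels})")
            terms.append(f"{self.spec.time_col}:C(__group)[T.{group}]")
        return terms

    def slope(self, group: str | None = None) -> tuple[float, float]:
        """Estimated mean slope (units/month) and its SE for ``group``."""
        terms = self._slope_terms(group)
        w = pd.Series(0.0, index=self.params.index)
        w[terms] = 1.0
        est = float(w @ self.params)
        se = float(np.sqrt(w @ self.cov @ w))
        return est, se

    def slope_contrast(self, group_a: str, group_b: str) -> tuple[float, float]:
        """Slope difference (a - b) and its SE."""
        w = pd.Series(0.0, index=self.params.index)
        for t in self._slope_terms(group_a):
            w[t] += 1.0
        for t in self._slope_terms(group_b):
            w[t] -= 1.0
        est = float(w @ self.params)
        se = float(np.sqrt(w @ self.cov @ w))
        return est, se

    def require_converged(self, force: bool = False) -> None:
        if not self.converged and not force:
            raise NotConvergedError(
                "mixed-model fit did not converge; pass force=True to use it anyway"
            )


def _analysis_table(cohort: Cohort, spec: LMMSpec) -> pd.DataFrame:
    df = cohort.data.copy()
    if spec.transform == "pct_change":
        df["__y"] = percent_change_transform(cohort, spec.outcome).to_numpy()
        raw_baseline_col = spec.outcome
    elif spec.transform == "none":
        if spec.outcome not in df.columns:
            raise ModelError(f"outcome {spec.outcome!r} absent from cohort")
        df["__y"] = df[spec.outcome]
        raw_baseline_col = spec.outcome
    else:
        raise ModelError(f"unknown transform {spec.transform!r}")
    if "baseline_value" in spec.covariates:
        base = df[df["time_months"] == 0.0].set_index("subject_id")[raw_baseline_col]
        df["__baseline"] = df["subject_id"].map(base)
    df["__group"] = df[spec.group_col].astype(str)
    needed = [c for c in spec.covariates if c not in ("baseline_value",)]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ModelError(f"covariates absent from cohort: {missing}")
    return df


def _formula(spec: LMMSpec, n_levels: int) -> str:
    rhs = [spec.time_col] if n_levels < 2 else [f"{spec.time_col} * C(__group)"]
    for cov in spec.covariates:
        if cov == "baseline_value":
            rhs.append("__baseline")
        elif cov == "sex":
            rhs.append("C(sex)")
        else:
            rhs.append(cov)
    return "__y ~ " + " + ".join(rhs)


def fit_lmm(cohort: Cohort, spec: LMMSpec) -> LMMFit:
    """REML fit of the random-intercept + random-slope model.

    Degenerate (noise-free) inputs are detected and resolved by ordinary
    least squares with zero variance components.  A singular random-effects
    covariance triggers a refit with a slope-only random effect and a
    warning.  Non-convergence is flagged on the returned fit rather than
    raised; downstream consumers refuse flagged fits unless forced.
    """
    df = _analysis_table(cohort, spec)
    counts = df.groupby("subject_id").size()
    if (counts < 2).any():
        raise ModelError(f"subjects with < 2 visits: {counts[counts < 2].index.tolist()}")
    levels = sorted(df["__group"].unique())
    formula = _formula(spec, len(levels))
    reference = levels[0] if len(levels) > 1 else None

    # degenerate (exact-fit) shortcut: zero-noise cohorts make the REML
    # problem singular, but the fixed effects are just the exact OLS solution
    ols = smf.ols(formula, df).fit()
    y_var = float(np.var(df["__y"].to_numpy()))
    if ols.ssr <= 1e-10 * max(y_var, 1.0) * len(df):
        cov = pd.DataFrame(0.0, index=ols.params.index, columns=ols.params.index)
        return LMMFit(
            spec=spec, group_levels=levels, reference=reference,
            params=ols.params, bse=ols.bse * 0.0, cov=cov,
            sigma2_b0=0.0, sigma2_b1=0.0, rho=0.0, sigma2_resid=0.0,
            n_subjects=int(df["subject_id"].nunique()), n_obs=len(df),
            converged=True, degenerate=True,
        )

    def _run(re_formula: str):
        # boundary-adjacent REML surfaces defeat single optimizers regularly;
        # walk a retry chain and keep the first fit that reports convergence
        model = smf.mixedlm(formula, df, groups=df["subject_id"], re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = None
            for method in ("lbfgs", "bfgs", "powell"):
                res = model.fit(reml=True, method=method, maxiter=500, disp=False)
                if res.converged:
                    break
            return res

    singular = False
    slope_only = False
    try:
        res = _run(f"~{spec.time_col}")
        cov_re = res.cov_re.to_numpy()
        eig = np.linalg.eigvalsh(cov_re)
        if eig.min() <= 1e-10 * max(res.scale, 1e-12):
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "random-effects covariance singular; refitting with slope-only random effect",
            stacklevel=2,
        )
        singular = True
        slope_only = True
        res = _run(f"~0 + {spec.time_col}")
        cov_re = res.cov_re.to_numpy()

    fe = res.fe_params
    cov_fe = res.cov_params().loc[fe.index, fe.index]
    if slope_only:
        sigma2_b0, sigma2_b1, rho = 0.0, float(cov_re[0, 0]), 0.0
    else:
        sigma2_b0 = float(cov_re[0, 0])
        sigma2_b1 = float(cov_re[1, 1])
        denom = np.sqrt(sigma2_b0 * sigma2_b1)
        rho = float(cov_re[0, 1] / denom) if denom > 0 else 0.0
    return LMMFit(
        spec=spec, group_levels=levels, reference=reference,
        params=fe, bse=res.bse.loc[fe.index], cov=cov_fe,
        sigma2_b0=sigma2_b0, sigma2_b1=sigma2_b1, rho=rho,
        sigma2_resid=float(res.scale),
        n_subjects=int(df["subject_id"].nunique()), n_obs=len(df),
        converged=bool(res.converged), singular=singular,
    )


def estimate_12mo_change(
    fit: LMMFit, group: str | None = None, horizon: float = 12.0, force: bool = False
) -> tuple[float, tuple[float, float]]:
    """Marginal change over ``horizon`` months for ``group`` with 95% CI.

    Covariates enter without time interactions, so the marginal change at
    covariate reference values is ``horizon * slope``; the CI follows by
    the delta method (here linear, hence exact given the slope SE).
    """
    fit.require_converged(force)
    est, se = fit.slope(group)
    change = horizon * est
    half = Z975 * horizon * se
    return change, (change - half, change + half)


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    estimate: float  # slope difference, units/month
    ci: tuple[float, float]
    p_raw: float
    p_adjusted: float
    n_comparisons: int


def pairwise_contrasts(
    fit: LMMFit, correction: str = "bonferroni", force: bool = False
) -> list[ContrastResult]:
    """All pairwise group slope differences with Bonferroni-adjusted p."""
    fit.require_converged(force)
    pairs = list(combinations(fit.group_levels, 2))
    if not pairs:
        raise ModelError("pairwise contrasts need >= 2 groups")
    if correction not in ("bonferroni", "none"):
        raise ModelError(f"unknown correction {correction!r}")
    m = len(pairs)
    out = []
    for a, b in pairs:
        est, se = fit.slope_contrast(a, b)
        if se == 0:
            p = 0.0 if est != 0 else 1.0
        else:
            p = 2.0 * stats.norm.sf(abs(est) / se)
        p_adj = min(1.0, m * p) if correction == "bonferroni" else p
        out.append(
            ContrastResult(a, b, est, (est - Z975 * se, est + Z975 * se), p, p_adj, m)
        )
    return out


# ---------------------------------------------------------------------------
# two-visit change-score regression
# ---------------------------------------------------------------------------


@dataclass
class ChangeRegression:
    outcome: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    n_subjects: int
    n_excluded: int
    result: object = field(repr=False, default=None)


def fit_change_regression(
    cohort: Cohort,
    outcome: str,
    covariates: tuple[str, ...] = ("group", "sex", "age_baseline", "baseline_value"),
) -> ChangeRegression:
    """OLS of the follow-up-minus-baseline change on group and covariates.

    Intended for fixed two-visit designs (trial-like cohorts with complete
    data).  Subjects without exactly two visits are excluded with a warning.
    """
    df = cohort.data
    if outcome not in df.columns:
        raise ModelError(f"outcome {outcome!r} absent from cohort")
    counts = df.groupby("subject_id").size()
    bad = counts[counts != 2].index
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} subject(s) without exactly two visits", stacklevel=2
        )
    keep = df[df["subject_id"].isin(counts[counts == 2].index)]
    wide = keep.sort_values("time_months").groupby("subject_id")
    first = wide.first()
    last = wide.last()
    tab = pd.DataFrame({"__change": last[outcome] - first[outcome]})
    rhs = []
    for cov in covariates:
        if cov == "baseline_value":
            tab["__baseline"] = first[outcome]
            rhs.append("__baseline")
        elif cov in ("group", "sex", "phenotype"):
            tab[cov] = first[cov]
            rhs.append(f"C({cov})")
        else:
            tab[cov] = first[cov]
            rhs.append(cov)
    formula = "__change ~ " + (" + ".join(rhs) if rhs else "1")
    res = smf.ols(formula, tab).fit()
    return ChangeRegression(
        outcome=outcome,
        params=res.params, bse=res.bse, conf_int=res.conf_int(), pvalues=res.pvalues,
        n_subjects=len(tab), n_excluded=len(bad), result=res,
    )
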
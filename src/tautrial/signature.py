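"""Data-driven composite MRI endpoints.

Single-region volumetry (classically, midbrain volume) is a noisy
progression endpoint.  Averaging percent change from baseline across a
small set of atrophy-sensitive regions — brainstem volumes and cortical
thicknesses combine because percent change is dimensionless — yields a
composite whose slope is estimated more precisely, which translates
directly into smaller trials.  The search below is exactly exhaustive over
every subset of at most five candidate regions, ranking subsets by the
estimated total trial size their composite yields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import Cohort
from .design import DesignInput, DesignResult, required_n_slope
from .longitudinal import LMMFit, LMMSpec, ModelError, fit_lmm, percent_change_transform

logger = logging.getLogger(__name__)

#: guard against combinatorially infeasible searches
MAX_SUBSETS = 50_000


class SignatureError(ValueError):
    pass


def candidate_regions(
    cohort: Cohort,
    group: str | None = None,
    group_col: str = "group",
    p_threshold: float = 0.05,
    covariates: tuple[str, ...] = (),
) -> list[str]:
    """Regions showing longitudinal atrophy in ``group``.

    For each catalogued region a single-group percent-change mixed model is
    fitted; regions qualify when the time fixed effect is negative with raw
    p below ``p_threshold`` (no multiplicity correction: the filter is a
    screen, not an inference).
    """
    sub = cohort.for_group(group, group_col) if group is not None else cohort
    sub = _pooled(sub)
    selected = []
    for region in cohort.region_names:
        spec = LMMSpec(outcome=region, transform="pct_change", group_col="__pooled",
                       covariates=covariates)
        try:
            fit = fit_lmm(sub, spec)
        except (ModelError, np.linalg.LinAlgError) as exc:
            logger.warning("region %s: pilot fit failed (%s); not a candidate", region, exc)
            continue
        if not fit.converged:
            continue
        est, se = fit.slope()
        if se == 0:
            qualifies = est < 0
        else:
            qualifies = est < 0 and 2.0 * stats.norm.sf(abs(est) / se) < p_threshold
        if qualifies:
            selected.append(region)
    if not selected:
        raise SignatureError(
            "no region qualifies as longitudinally atrophic; relax p_threshold"
        )
    return selected


def composite_signature(cohort: Cohort, regions: list[str] | tuple[str, ...]) -> pd.Series:
    """Unweighted mean of per-region percent changes from baseline.

    Dimensionless by construction, so thicknesses (mm) and volumes (mm^3)
    combine; identically 0 at baseline.  Visits missing any constituent
    region are returned as NaN with a warning (downstream fits drop them).
    """
    if not regions:
        raise SignatureError("signature needs >= 1 region")
    missing = [r for r in regions if r not in cohort.data.columns]
    if missing:
        raise SignatureError(f"regions absent from cohort: {missing}")
    parts = [percent_change_transform(cohort, r) for r in regions]
    mat = pd.concat(parts, axis=1)
    nan_rows = mat.isna().any(axis=1)
    if nan_rows.any():
        warnings.warn(
            f"{int(nan_rows.sum())} visit(s) missing a constituent region; "
            "dropped from the composite", stacklevel=2,
        )
    out = mat.mean(axis=1, skipna=False)
    out.name = "signature_pct"
    return out


@dataclass
class SignatureResult:
    regions: tuple[str, ...]
    fit: LMMFit
    design: DesignResult
    rank: int = 0

    @property
    def n_total(self) -> int:
        return self.design.n_total


def _pooled(cohort: Cohort) -> Cohort:
    """The selected population is analyzed as a single trial arm."""
    return cohort.with_column("__pooled", ["all"] * len(cohort.data))


def _pilot_fit_on_composite(
    sub: Cohort, regions: tuple[str, ...], covariates: tuple[str, ...]
) -> LMMFit:
    series = composite_signature(sub, regions)
    work = sub.with_column("signature_pct", series.to_numpy())
    keep = ~work.data["signature_pct"].isna()
    if not keep.all():
        work = work.subset(keep)
    spec = LMMSpec(outcome="signature_pct", transform="none", group_col="__pooled",
                   covariates=covariates)
    return fit_lmm(_pooled(work), spec)


def search_best_signature(
    cohort: Cohort,
    group: str | None = None,
    design: DesignInput | None = None,
    max_size: int = 5,
    candidates: list[str] | None = None,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age_baseline", "sex"),
    p_threshold: float = 0.05,
) -> list[SignatureResult]:
    """Exhaustively rank every region subset of size 1..max_size.

    For each subset the composite endpoint is built, a single-group pilot
    mixed model fitted, and the trial size from :func:`required_n_slope`
    recorded.  Results are sorted ascending by total n, ties broken by
    smaller subset then lexicographic region names; ranks start at 1.
    Subsets whose pilot fit fails or does not converge are skipped and
    logged.
    """
    if design is None:
        design = DesignInput()
    design.validate(need_pilot=False)
    if candidates is None:
        candidates = candidate_regions(cohort, group, group_col, p_threshold=p_threshold)
    k = len(candidates)
    max_size = min(max_size, k)
    n_subsets = sum(comb(k, s) for s in range(1, max_size + 1))
    if n_subsets > MAX_SUBSETS:
        raise SignatureError(
            f"{n_subsets} subsets exceed the feasibility guard of {MAX_SUBSETS}; "
            "shrink the candidate list or max_size"
        )
    sub = cohort.for_group(group, group_col) if group is not None else cohort

    results: list[SignatureResult] = []
    for size in range(1, max_size + 1):
        for regions in combinations(sorted(candidates), size):
            try:
                fit = _pilot_fit_on_composite(sub, regions, covariates)
                if not fit.converged:
                    raise ModelError("pilot fit did not converge")
                slope, _ = fit.slope()
                d = replace(design, beta1=slope, sigma2_slope=fit.sigma2_b1,
                            sigma2_resid=fit.sigma2_resid)
                res = required_n_slope(d)
            except Exception as exc:  # noqa: BLE001 - skip-and-log per subset
                logger.warning("subset %s skipped: %s", regions, exc)
                continue
            results.append(SignatureResult(regions=regions, fit=fit, design=res))

    results.sort(key=lambda r: (r.n_total, len(r.regions), r.regions))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def ranking_frame(results: list[SignatureResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "regions": ["+".join(r.regions) for r in results],
            "size": [len(r.regions) for r in results],
            "n_total": [r.n_total for r in results],
            "slope_pct_per_month": [r.design.design.beta1 for r in results],
            "sigma2_slope": [r.design.design.sigma2_slope for r in results],
            "sigma2_resid": [r.design.design.sigma2_resid for r in results],
        }
    )


@dataclass
class RelevanceResult:
    beta_standardized: float
    adj_r2: float
    p_value: float
    n_subjects: int


def signature_clinical_relevance(
    cohort: Cohort,
    regions: list[str] | tuple[str, ...],
    clinical_outcome: str = "PSPRS",
    group: str | None = None,
    group_col: str = "group",
) -> RelevanceResult:
    """Association between signature change and clinical change.

    Per subject, the clinical change (last visit minus baseline) is
    regressed on the signature percent change at the last visit, adjusting
    for baseline age, baseline clinical score and the baseline values of
    the constituent regions.  All terms are z-scored so the signature
    coefficient is a standardized beta; the model's adjusted R^2 and the
    coefficient's p-value are returned.
    """
    sub = cohort.for_group(group, group_col) if group is not None else cohort
    df = sub.data
    if clinical_outcome not in df.columns:
        raise SignatureError(f"clinical outcome {clinical_outcome!r} absent from cohort")
    sig = composite_signature(sub, regions)
    work = df.assign(__sig=sig.to_numpy()).sort_values("time_months").groupby("subject_id")
    first, last = work.first(), work.last()
    tab = pd.DataFrame(
        {
            "clin_change": last[clinical_outcome] - first[clinical_outcome],
            "sig_change": last["__sig"],
            "age_baseline": first["age_baseline"],
            "clin_baseline": first[clinical_outcome],
        }
    )
    for r in regions:
        tab[f"base_{r}"] = first[r]
    tab = tab.dropna()
    if len(tab) < 10:
        raise SignatureError("fewer than 10 subjects with both changes computable")
    sds = tab.std(ddof=1)
    if sds["sig_change"] == 0 or sds["clin_change"] == 0:
        raise SignatureError("signature or clinical change has zero variance")
    keep = sds[sds > 0].index  # constant covariates carry no information
    z = (tab[keep] - tab[keep].mean()) / sds[keep]
    rhs = " + ".join(c for c in z.columns if c != "clin_change")
    res = smf.ols(f"clin_change ~ {rhs}", z).fit()
    return RelevanceResult(
        beta_standardized=float(res.params["sig_change"]),
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.pvalues["sig_change"]),
        n_subjects=len(tab),
    )
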
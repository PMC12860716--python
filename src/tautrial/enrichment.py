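"""MRI-based cohort enrichment.

Trial entry in 4R-tauopathy studies is usually gated on clinical phenotype
(Richardson's syndrome as a proxy for PSP pathology), which misclassifies a
substantial minority of participants.  The enrichment strategy implemented
here instead (1) reclassifies corticobasal-syndrome participants who are
positive on AD biomarkers as AD (plasma pTau-217 >= 0.25 pg/mL, with
amyloid-PET as the reference when the two disagree), and (2) assigns the
remainder to MRI-PSP or MRI-CBD by thresholding the predicted probability
of PSP from a logistic model built on regional MRI measures, age and sex.
The probability cut-off is optimized by exhaustive scan over candidate
thresholds inside a bootstrap, maximizing the Youden index by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import PTAU217_THRESHOLD, Cohort

logger = logging.getLogger(__name__)

LABEL_AD = "AD"
LABEL_PSP = "MRI-PSP"
LABEL_CBD = "MRI-CBD"


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# diagnostic model
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticModel:
    """Multinomial logistic etiologic classifier on standardized features.

    Features are z-scored with the training means/SDs stored on the model,
    so prediction is deterministic given the coefficients.  ``positive_class``
    is the class whose predicted probability is thresholded downstream
    (PSP vs CBD by default; a PSP-vs-any model is obtained by training with
    all non-PSP labels collapsed).
    """

    feature_names: list[str]
    classes: list[str]
    coef: np.ndarray
    intercept: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    positive_class: str = "PSP"
    sex_codes: dict[str, float] = field(default_factory=lambda: {"F": 0.0, "M": 1.0})

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.feature_names:
            if name == "sex":
                cols.append(table["sex"].map(self.sex_codes).to_numpy(dtype=float))
            else:
                if name not in table.columns:
                    raise EnrichmentError(f"feature {name!r} absent from table")
                cols.append(table[name].to_numpy(dtype=float))
        X = np.column_stack(cols)
        bad = np.isnan(X).any(axis=1)
        if bad.any():
            subjects = table.loc[bad, "subject_id"].tolist() if "subject_id" in table else np.where(bad)[0].tolist()
            raise EnrichmentError(f"missing feature values for subjects: {subjects}")
        return (X - self.feature_means) / self.feature_sds

    def predict_proba(self, table: pd.DataFrame) -> pd.DataFrame:
        """Class-probability table (rows sum to 1) for each input row."""
        Z = self._design(table) @ self.coef.T + self.intercept
        Z = Z - Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        return pd.DataFrame(P, columns=self.classes, index=table.index)

    def p_positive(self, table: pd.DataFrame) -> pd.Series:
        return self.predict_proba(table)[self.positive_class]


def fit_diagnostic_model(
    training: Cohort,
    features: list[str] | None = None,
    label_col: str = "group",
    positive_class: str = "PSP",
    collapse_other: bool = False,
    ridge: float = 1e-6,
) -> DiagnosticModel:
    """Fit the etiologic classifier on baseline scans of a labelled cohort.

    A small ridge penalty guarantees a finite maximum-likelihood solution
    under perfect separation (a warning is emitted when separation is
    detected).  ``collapse_other=True`` trains the positive class against
    everything else (the PSP-vs-any variant); the default contrasts the
    labels as given (PSP vs CBD when those are the two labels present).
    """
    base = training.baseline().copy()
    if features is None:
        features = training.region_names + ["age_baseline", "sex"]
    labels = base[label_col].astype(str)
    if collapse_other:
        labels = labels.where(labels == positive_class, other=f"non-{positive_class}")
    if labels.nunique() < 2:
        raise EnrichmentError("training labels contain a single class")

    # standardization parameters from the training sample
    proto = DiagnosticModel(
        feature_names=list(features),
        classes=[],
        coef=np.zeros((1, len(features))),
        intercept=np.zeros(1),
        feature_means=np.zeros(len(features)),
        feature_sds=np.ones(len(features)),
        positive_class=positive_class,
    )
    X_raw = proto._design(base)
    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X_raw - mu) / sd

    # sklearn's penalty is ||w||^2 / (2C): C = 1/ridge matches an L2 ridge
    clf = LogisticRegression(C=1.0 / ridge, max_iter=5000)
    clf.fit(X, labels)
    if clf.score(X, labels) == 1.0:
        proba = clf.predict_proba(X)
        if proba.max(axis=1).min() > 0.999:
            warnings.warn(
                "training classes are perfectly separated; coefficients are "
                "determined by the ridge penalty", stacklevel=2,
            )

    classes = list(clf.classes_)
    coef, intercept = clf.coef_, clf.intercept_
    if len(classes) == 2 and coef.shape[0] == 1:
        # expand the binary fit to one row per class for a uniform softmax form
        coef = np.vstack([-coef[0], coef[0]]) / 2.0
        intercept = np.array([-intercept[0], intercept[0]]) / 2.0
    if positive_class not in classes:
        raise EnrichmentError(f"positive_class {positive_class!r} not among labels {classes}")
    return DiagnosticModel(
        feature_names=list(features),
        classes=classes,
        coef=coef,
        intercept=intercept,
        feature_means=mu,
        feature_sds=sd,
        positive_class=positive_class,
    )


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    ppv_defined: bool = True
    npv_defined: bool = True


def auc_rank(probs: np.ndarray, positive: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic, ties handled by midranks."""
    probs = np.asarray(probs, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos, n_neg = positive.sum(), (~positive).sum()
    if n_pos == 0 or n_neg == 0:
        raise EnrichmentError("AUC requires both classes present")
    ranks = stats.rankdata(probs)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(probs, labels, cutoff: float, positive_label=True) -> ConfusionMetrics:
    """2x2 operating characteristics at ``cutoff`` (predicted positive iff
    prob >= cutoff) plus the rank-statistic AUC."""
    probs = np.asarray(probs, dtype=float)
    positive = np.asarray(labels) == positive_label
    pred = probs >= cutoff
    tp = int(np.sum(pred & positive))
    fn = int(np.sum(~pred & positive))
    tn = int(np.sum(~pred & ~positive))
    fp = int(np.sum(pred & ~positive))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv_defined = (tp + fp) > 0
    npv_defined = (tn + fn) > 0
    ppv = tp / (tp + fp) if ppv_defined else np.nan
    npv = tn / (tn + fn) if npv_defined else np.nan
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        auc=auc_rank(probs, positive),
        tp=tp, fn=fn, tn=tn, fp=fp,
        ppv_defined=ppv_defined, npv_defined=npv_defined,
    )


# ---------------------------------------------------------------------------
# cutpoint optimization
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    boot_cutoffs: np.ndarray
    n_boot: int
    metric: str = "youden"


def _metric_fn(name: str):
    if name == "youden":
        return lambda m: m.sensitivity + m.specificity
    if name == "accuracy":
        return lambda m: (m.tp + m.tn) / (m.tp + m.tn + m.fp + m.fn)
    raise EnrichmentError(f"unknown cutpoint metric {name!r}")


def _scan_cutoff(probs: np.ndarray, positive: np.ndarray, metric: str) -> float:
    """Exhaustive scan over midpoints between sorted unique probabilities.

    Among equal-metric candidates the midpoint of the optimal interval is
    reported (mean of the lowest and highest tied candidate).
    """
    uniq = np.unique(probs)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    score = _metric_fn(metric)
    vals = np.array([score(confusion_metrics(probs, positive, c)) for c in candidates])
    best = vals >= vals.max() - 1e-12
    tied = candidates[best]
    return float((tied[0] + tied[-1]) / 2.0)


def optimize_cutpoint(
    probs,
    labels,
    n_boot: int = 10_000,
    metric: str = "youden",
    positive_label=True,
    aggregate: str = "mean",
    seed: int | None = None,
    resample: bool = True,
) -> CutpointResult:
    """Bootstrap-optimized probability cut-off.

    For each of ``n_boot`` resamples the metric-maximizing cutoff is found
    by exhaustive scan; the reported cutoff aggregates the bootstrap
    distribution (mean by default, median optional) and the operating
    characteristics are evaluated at that cutoff on the full sample.
    ``n_boot=0`` gives the single-pass (non-bootstrap) result;
    ``resample=False`` disables resampling (each replicate sees the full
    sample), which is useful for verifying bootstrap plumbing.
    """
    probs = np.asarray(probs, dtype=float)
    positive = np.asarray(labels) == positive_label
    if positive.all() or not positive.any():
        raise EnrichmentError("cutpoint optimization requires both classes present")
    if np.any((probs < 0) | (probs > 1)):
        raise EnrichmentError("probabilities must lie in [0, 1]")

    if n_boot == 0:
        cut = _scan_cutoff(probs, positive, metric)
        boot = np.array([cut])
    else:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        n = len(probs)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n) if resample else np.arange(n)
            p, y = probs[idx], positive[idx]
            if y.all() or not y.any():  # degenerate resample: redraw
                boot[b] = np.nan
                continue
            boot[b] = _scan_cutoff(p, y, metric)
        boot = boot[~np.isnan(boot)]
        cut = float(np.mean(boot) if aggregate == "mean" else np.median(boot))

    m = confusion_metrics(probs, positive, cut)
    return CutpointResult(
        cutoff=cut, auc=m.auc,
        sensitivity=m.sensitivity, specificity=m.specificity,
        ppv=m.ppv, npv=m.npv,
        boot_cutoffs=boot, n_boot=n_boot, metric=metric,
    )


# ---------------------------------------------------------------------------
# enrichment rules
# ---------------------------------------------------------------------------


@dataclass
class EnrichedLabel:
    subject_id: str
    label: str  # one of LABEL_AD / LABEL_PSP / LABEL_CBD
    p_psp: dict[float, float]  # predicted probability of PSP at each scan time
    rule_fired: str  # mri_threshold | ad_reclassified | copathology_retained


def ad_biomarker_positive(amyloid_pet, ptau217, threshold: float = PTAU217_THRESHOLD) -> bool | None:
    """AD-biomarker positivity with amyloid-PET as the reference.

    pTau-217 is positive iff >= ``threshold`` pg/mL; when both biomarkers
    are available and discordant, amyloid-PET decides.  Returns ``None``
    when neither biomarker is available.
    """
    amyloid_known = amyloid_pet in ("positive", "negative")
    ptau_known = ptau217 is not None and not (isinstance(ptau217, float) and np.isnan(ptau217))
    if amyloid_known:
        return amyloid_pet == "positive"
    if ptau_known:
        return float(ptau217) >= threshold
    return None


def apply_enrichment(
    cohort: Cohort,
    model: DiagnosticModel,
    cutoff: float,
    ad_rules_on: bool = True,
) -> list[EnrichedLabel]:
    """Assign exactly one of {AD, MRI-PSP, MRI-CBD} per subject.

    Rule order: (1) CBS participants positive on AD biomarkers are
    reclassified as AD; (2) everyone else is labelled by thresholding the
    baseline predicted probability of PSP; (3) RS participants with
    positive AD biomarkers keep their MRI label (likely co-pathology).
    Subjects with no usable AD biomarkers fall through to the MRI rule
    with a logged note.
    """
    df = cohort.data
    p_all = model.p_positive(df)
    out: list[EnrichedLabel] = []
    for subject, rows in df.groupby("subject_id", sort=False):
        rows = rows.sort_values("time_months")
        p_by_time = {float(t): float(p_all[i]) for i, t in zip(rows.index, rows["time_months"])}
        base = rows.iloc[0]
        p_baseline = p_by_time[float(base["time_months"])]
        phenotype = str(base.get("phenotype", ""))
        ad_pos = None
        if ad_rules_on:
            ad_pos = ad_biomarker_positive(base.get("amyloid_pet"), base.get("ptau217_pgml"))
            if ad_pos is None:
                logger.info("subject %s: no usable AD biomarkers; using MRI rule", subject)
        if ad_rules_on and phenotype == "CBS" and ad_pos:
            out.append(EnrichedLabel(subject, LABEL_AD, p_by_time, "ad_reclassified"))
            continue
        mri_label = LABEL_PSP if p_baseline >= cutoff else LABEL_CBD
        if ad_rules_on and phenotype == "RS" and ad_pos:
            out.append(EnrichedLabel(subject, mri_label, p_by_time, "copathology_retained"))
        else:
            out.append(EnrichedLabel(subject, mri_label, p_by_time, "mri_threshold"))
    return out


def labels_frame(labels: list[EnrichedLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [l.subject_id for l in labels],
            "label": [l.label for l in labels],
            "p_psp_baseline": [l.p_psp[min(l.p_psp)] for l in labels],
            "rule_fired": [l.rule_fired for l in labels],
        }
    )


def classification_stability(cohort: Cohort, model: DiagnosticModel, cutoff: float) -> pd.DataFrame:
    """Baseline vs last-scan MRI classification transitions.

    Each subject's scans are classified independently with the same model
    and cutoff; the table counts CBD->PSP and PSP->CBD switches and stable
    classifications, with percentages of the whole sample and of the
    subject's baseline class.
    """
    df = cohort.data
    p_all = model.p_positive(df)
    records = []
    for subject, rows in df.groupby("subject_id", sort=False):
        rows = rows.sort_values("time_months")
        if len(rows) < 2:
            continue
        cls = [LABEL_PSP if p_all[i] >= cutoff else LABEL_CBD for i in rows.index]
        records.append((subject, cls[0], cls[-1]))
    if not records:
        raise EnrichmentError("stability requires subjects with >= 2 scans")
    tab = pd.DataFrame(records, columns=["subject_id", "baseline", "followup"])
    n_total = len(tab)
    n_base = tab["baseline"].value_counts()

    def _row(name, mask, base_class):
        n = int(mask.sum())
        denom = int(n_base.get(base_class, 0)) if base_class else n_total
        return {
            "transition": name,
            "n": n,
            "pct_of_total": 100.0 * n / n_total,
            "pct_of_baseline_class": 100.0 * n / denom if denom else np.nan,
        }

    cbd_to_psp = (tab["baseline"] == LABEL_CBD) & (tab["followup"] == LABEL_PSP)
    psp_to_cbd = (tab["baseline"] == LABEL_PSP) & (tab["followup"] == LABEL_CBD)
    stable = tab["baseline"] == tab["followup"]
    return pd.DataFrame(
        [
            _row("CBD to PSP", cbd_to_psp, LABEL_CBD),
            _row("PSP to CBD", psp_to_cbd, LABEL_PSP),
            _row("Stable", stable, None),
        ]
    )
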
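"""Classifier, cutpoint optimization, reclassification rules, stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import tautrial as tt
from tautrial.cohort import Cohort
from tautrial.enrichment import (
    EnrichmentError,
    LABEL_AD,
    LABEL_CBD,
    LABEL_PSP,
    apply_enrichment,
    auc_rank,
    classification_stability,
    confusion_metrics,
    fit_diagnostic_model,
    optimize_cutpoint,
)

from conftest import config, outcome


def _brute_force_youden(probs, positive):
    """Independent oracle: direct enumeration of all midpoint cutoffs."""
    uniq = np.unique(probs)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_val, best = -np.inf, []
    for c in cands:
        pred = probs >= c
        sens = (pred & positive).sum() / positive.sum()
        spec = (~pred & ~positive).sum() / (~positive).sum()
        v = sens + spec
        if v > best_val + 1e-12:
            best_val, best = v, [c]
        elif abs(v - best_val) <= 1e-12:
            best.append(c)
    return (best[0] + best[-1]) / 2.0


def _two_class_cohort(seed=0, n=40, gap=3.0):
    cfg = config({"PSP": [outcome(mean=4800, sd_intercept=500, sd_residual=30)],
                  "CBD": [outcome(mean=4800 + gap * 500, sd_intercept=500, sd_residual=30)]},
                 n=n, groups=("PSP", "CBD"), seed=seed)
    return tt.generate_cohort(cfg)


def test_separable_classes_give_near_perfect_in_sample_auc():
    c = _two_class_cohort(gap=6.0)
    m = fit_diagnostic_model(c)
    base = c.baseline()
    probs = m.p_positive(base)
    cm = confusion_metrics(probs.to_numpy(), (base["group"] == "PSP").to_numpy(), 0.5)
    assert cm.auc >= 0.99
    # probabilities over classes sum to 1
    assert np.allclose(m.predict_proba(base).sum(axis=1), 1.0)


def test_permuted_labels_give_chance_auc(rng):
    c = _two_class_cohort(seed=4, n=250, gap=2.0)
    base = c.baseline()
    labels = rng.permutation((base["group"] == "PSP").to_numpy())
    perm = Cohort(base.assign(group=np.where(labels, "PSP", "CBD")), dict(c.region_catalog))
    m = fit_diagnostic_model(perm)
    auc = auc_rank(m.p_positive(base).to_numpy(), labels)
    n1 = labels.sum()
    n0 = len(labels) - n1
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(auc - 0.5) < 4 * se


def test_separable_four_point_cutoff_is_midpoint():
    probs = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([True, True, False, False])
    res = optimize_cutpoint(probs, labels, n_boot=0)
    assert res.auc == 1.0
    assert res.cutoff == pytest.approx(0.5)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_cutoff_matches_brute_force_on_overlapping_fixture():
    rng = np.random.default_rng(7)
    probs = np.round(np.r_[rng.beta(4, 2, 10), rng.beta(2, 4, 10)], 3)
    positive = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    res = optimize_cutpoint(probs, positive, n_boot=0)
    assert res.cutoff == pytest.approx(_brute_force_youden(probs, positive))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_cutoff_scan_equals_brute_force(data):
    n = data.draw(st.integers(6, 60))
    probs = np.array(data.draw(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
    assume(len(np.unique(probs)) > 1)
    k = data.draw(st.integers(1, n - 1))
    positive = np.zeros(n, bool)
    positive[:k] = True
    res = optimize_cutpoint(probs, positive, n_boot=0)
    assert res.cutoff == pytest.approx(_brute_force_youden(probs, positive))


def test_auc_invariant_under_monotone_transform(rng):
    probs = rng.uniform(0, 1, 50)
    positive = rng.uniform(0, 1, 50) < 0.4
    positive[0], positive[1] = True, False
    a1 = auc_rank(probs, positive)
    a2 = auc_rank(1 / (1 + np.exp(-5 * probs)), positive)
    assert a1 == pytest.approx(a2)


def test_identity_resample_bootstrap_equals_single_pass(rng):
    probs = rng.uniform(0, 1, 30)
    positive = np.r_[np.ones(15, bool), np.zeros(15, bool)]
    single = optimize_cutpoint(probs, positive, n_boot=0)
    ident = optimize_cutpoint(probs, positive, n_boot=1, resample=False)
    assert ident.cutoff == pytest.approx(single.cutoff)
    assert ident.auc == pytest.approx(single.auc)


def test_hand_computed_two_by_two_metrics():
    # TP=8, FN=2, TN=11, FP=1 at cutoff 0.5
    probs = np.r_[np.full(8, 0.9), np.full(2, 0.1), np.full(11, 0.2), np.full(1, 0.8)]
    labels = np.r_[np.ones(10, bool), np.zeros(12, bool)]
    m = confusion_metrics(probs, labels, 0.5)
    assert m.sensitivity == pytest.approx(0.8)
    assert m.specificity == pytest.approx(11 / 12)
    assert m.ppv == pytest.approx(8 / 9)
    assert m.npv == pytest.approx(11 / 13)


def test_degenerate_auc_cases():
    ties = confusion_metrics(np.full(10, 0.5), np.r_[np.ones(5, bool), np.zeros(5, bool)], 0.5)
    assert ties.auc == pytest.approx(0.5)
    perfect = confusion_metrics(np.r_[np.full(5, 0.9), np.full(5, 0.1)],
                                np.r_[np.ones(5, bool), np.zeros(5, bool)], 0.5)
    assert perfect.auc == 1.0
    assert perfect.sensitivity == perfect.specificity == perfect.ppv == perfect.npv == 1.0


def test_empty_prediction_class_flags_undefined_metrics():
    probs = np.array([0.1, 0.2, 0.3, 0.4])
    labels = np.array([True, True, False, False])
    m = confusion_metrics(probs, labels, 0.9)  # nothing predicted positive
    assert not m.ppv_defined and np.isnan(m.ppv)
    assert m.npv_defined


def test_single_class_labels_rejected():
    with pytest.raises(EnrichmentError):
        optimize_cutpoint(np.array([0.1, 0.9]), np.array([True, True]))


def _rule_cohort():
    """One subject per rule scenario, with fully controlled features."""
    rows = []
    scenarios = [
        # (sid, phenotype, amyloid, ptau, midbrain) midbrain drives p_psp
        ("cbs_adpos", "CBS", "positive", 0.30, 4000.0),
        ("cbs_discord", "CBS", "negative", 0.40, 6000.0),
        ("rs_copath", "RS", "positive", 0.30, 4000.0),
        ("rs_plain", "RS", "negative", 0.10, 4000.0),
        ("cbs_plain", "CBS", "negative", 0.10, 6000.0),
    ]
    for sid, phen, amy, ptau, mb in scenarios:
        for t in (0.0, 12.0):
            rows.append({"subject_id": sid, "group": "?", "phenotype": phen,
                         "time_months": t, "age_baseline": 68.0, "sex": "F",
                         "site_id": 0, "amyloid_pet": amy, "ptau217_pgml": ptau,
                         "Midbrain": mb})
    return Cohort(pd.DataFrame(rows), {"Midbrain": "brainstem_volume"})


def test_enrichment_rule_precedence_and_exhaustiveness():
    c = _rule_cohort()
    train = tt.generate_cohort(config(
        {"PSP": [outcome(mean=4000, sd_intercept=200, sd_residual=10)],
         "CBD": [outcome(mean=6000, sd_intercept=200, sd_residual=10)]},
        n=30, groups=("PSP", "CBD"), seed=1))
    model = fit_diagnostic_model(train)
    labels = {l.subject_id: l for l in apply_enrichment(c, model, cutoff=0.5)}
    # CBS + AD-biomarker positive -> AD regardless of p_psp
    assert labels["cbs_adpos"].label == LABEL_AD
    assert labels["cbs_adpos"].rule_fired == "ad_reclassified"
    # discordant biomarkers: amyloid-PET is the reference -> negative -> MRI rule
    assert labels["cbs_discord"].label == LABEL_CBD
    assert labels["cbs_discord"].rule_fired == "mri_threshold"
    # RS with positive AD biomarkers keeps the MRI label (co-pathology)
    assert labels["rs_copath"].label == LABEL_PSP
    assert labels["rs_copath"].rule_fired == "copathology_retained"
    # exhaustive + mutually exclusive
    assert set(l.label for l in labels.values()) <= {LABEL_AD, LABEL_PSP, LABEL_CBD}
    assert len(labels) == c.n_subjects


def test_stability_identical_scans_are_fully_stable():
    c = _rule_cohort()
    train = tt.generate_cohort(config(
        {"PSP": [outcome(mean=4000, sd_intercept=200, sd_residual=10)],
         "CBD": [outcome(mean=6000, sd_intercept=200, sd_residual=10)]},
        n=30, groups=("PSP", "CBD"), seed=1))
    model = fit_diagnostic_model(train)
    tab = classification_stability(c, model, cutoff=0.5).set_index("transition")
    assert tab.loc["Stable", "pct_of_total"] == 100.0


def test_stability_counts_constructed_crossings():
    # 10 subjects classified CBD at baseline; 3 cross to PSP at follow-up
    rows = []
    for i in range(10):
        crosses = i < 3
        rows.append({"subject_id": f"s{i}", "group": "?", "phenotype": "CBS",
                     "time_months": 0.0, "age_baseline": 68.0, "sex": "M", "site_id": 0,
                     "amyloid_pet": "negative", "ptau217_pgml": 0.1, "Midbrain": 6000.0})
        rows.append({"subject_id": f"s{i}", "group": "?", "phenotype": "CBS",
                     "time_months": 12.0, "age_baseline": 68.0, "sex": "M", "site_id": 0,
                     "amyloid_pet": "negative", "ptau217_pgml": 0.1,
                     "Midbrain": 4000.0 if crosses else 6000.0})
    c = Cohort(pd.DataFrame(rows), {"Midbrain": "brainstem_volume"})
    train = tt.generate_cohort(config(
        {"PSP": [outcome(mean=4000, sd_intercept=200, sd_residual=10)],
         "CBD": [outcome(mean=6000, sd_intercept=200, sd_residual=10)]},
        n=30, groups=("PSP", "CBD"), seed=1))
    model = fit_diagnostic_model(train)
    tab = classification_stability(c, model, cutoff=0.5).set_index("transition")
    assert tab.loc["CBD to PSP", "n"] == 3
    assert tab.loc["CBD to PSP", "pct_of_baseline_class"] == pytest.approx(30.0)
    assert tab.loc["Stable", "n"] == 7
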
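"""Generator and I/O behaviour: determinism, noiseless limits, moment
recovery, attrition, inclusion filtering, round-trips, FreeSurfer parsing."""

import numpy as np
import pandas as pd
import pytest

import tautrial as tt
from tautrial.cohort import (
    CohortConfig,
    CohortValidationError,
    DuplicateVisitError,
    GroupSpec,
    MissingBaselineError,
    MissingColumnError,
    OutcomeSpec,
    VisitSchedule,
    generate_cohort,
    validate_cohort_table,
)
from tautrial.io import (
    parse_aparc_stats,
    parse_aseg_stats,
    read_cohort,
    read_freesurfer_cohort,
    write_cohort,
)
from tautrial.longitudinal import percent_change_transform

from conftest import config, outcome


def test_same_seed_gives_identical_cohorts():
    cfg = config([outcome(sd_intercept=100, sd_slope=5, sd_residual=50)], n=30, seed=42,
                 jitter=1.0, attrition=0.1)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert a.region_catalog == b.region_catalog


def test_noiseless_percent_decline_is_exact():
    cfg = config([outcome(delta12=-6.0)], n=5)
    c = generate_cohort(cfg)
    pct = percent_change_transform(c, "Midbrain")
    at12 = pct[c.data["time_months"] == 12.0]
    assert np.allclose(at12, -6.0, atol=1e-10)
    assert np.allclose(pct[c.data["time_months"] == 0.0], 0.0)


def test_noiseless_percent_decline_exact_even_with_baseline_spread():
    # the percent-change parameterization scales the slope to each subject's
    # own baseline, so spread in baselines does not break the noiseless limit
    cfg = config([outcome(delta12=-6.0, sd_intercept=400.0)], n=10, seed=3)
    c = generate_cohort(cfg)
    pct = percent_change_transform(c, "Midbrain")
    assert np.allclose(pct[c.data["time_months"] == 12.0], -6.0, atol=1e-9)


def test_group_mean_change_recovers_configured_delta():
    spec = OutcomeSpec(name="PSPRS", baseline_mean=30.0, delta12=12.0,
                       sd_intercept=10.0, sd_slope=0.5, sd_residual=3.0)
    cfg = config([spec], n=500, times=(0.0, 12.0), fixed=True, seed=11)
    c = generate_cohort(cfg)
    wide = c.data.pivot(index="subject_id", columns="time_months", values="PSPRS")
    change = wide[12.0] - wide[0.0]
    se = change.std(ddof=1) / np.sqrt(len(change))
    assert abs(change.mean() - 12.0) < 3 * se


def test_slope_mean_and_sd_match_generating_model():
    spec = OutcomeSpec(name="y", baseline_mean=100.0, delta12=12.0,
                       sd_intercept=5.0, sd_slope=0.1, sd_residual=0.01)
    cfg = config([spec], n=1000, seed=5)
    c = generate_cohort(cfg)

    def ols_slope(g):
        t, y = g["time_months"].to_numpy(), g["y"].to_numpy()
        return np.polyfit(t, y, 1)[0]

    slopes = c.data.groupby("subject_id").apply(ols_slope, include_groups=False)
    n = len(slopes)
    assert abs(slopes.mean() - 1.0) < 3 * 0.1 / np.sqrt(n)
    # residual noise is negligible, so the slope SD is essentially sd_slope
    assert abs(slopes.std(ddof=1) - 0.1) < 3 * 0.1 / np.sqrt(2 * n)


def test_attrition_hazard_matches_missing_final_visit_fraction():
    cfg = config([outcome(sd_residual=10.0)], n=800, attrition=0.2, seed=9)
    c = generate_cohort(cfg)
    counts = c.data.groupby("subject_id").size()
    # among retained subjects the missing-final-visit fraction equals the hazard
    frac = (counts == 2).mean()
    se = np.sqrt(0.2 * 0.8 / len(counts))
    assert abs(frac - 0.2) < 3 * se
    # baseline never removed; all retained subjects satisfy the filter
    assert (c.data.groupby("subject_id")["time_months"].min() == 0).all()
    assert (counts >= 2).all()


@pytest.mark.parametrize(
    "breaker, field_hint",
    [
        (lambda: OutcomeSpec(name="y", sd_slope=-1.0), "sd_slope"),
        (lambda: OutcomeSpec(name="y", corr=1.5), "corr"),
        (lambda: VisitSchedule(nominal_times=(0.0, 2.0)), "nominal_times"),
        (lambda: VisitSchedule(nominal_times=(1.0, 6.0)), "start at 0"),
        (lambda: GroupSpec(label="G", n_subjects=1, outcomes=(OutcomeSpec(name="y"),)),
         "n_subjects"),
    ],
)
def test_invalid_config_errors_name_the_offending_field(breaker, field_hint):
    obj = breaker()
    with pytest.raises(CohortValidationError, match=field_hint):
        obj.validate()


def test_roundtrip_write_read_preserves_values(tmp_path):
    cfg = config([outcome(sd_intercept=100, sd_residual=30),
                  outcome(name="PSPRS", kind="score", mean=30, delta12=10, pct=False,
                          sd_residual=2)], n=3, seed=1)
    c = generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(c, path)
    back = read_cohort(path)
    pd.testing.assert_frame_equal(back.data, c.data)
    assert back.region_catalog == c.region_catalog


def test_hemisphere_columns_are_averaged(tmp_path):
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "group": ["PSP", "PSP"],
            "time_months": [0.0, 12.0],
            "lh_superiortemporal": [2.4, 2.3],
            "rh_superiortemporal": [2.6, 2.5],
        }
    )
    path = tmp_path / "c.csv"
    df.to_csv(path, index=False)
    c = read_cohort(path, region_catalog={"superiortemporal": "cortical_thickness"})
    assert np.allclose(c.data["superiortemporal"], [2.5, 2.4])
    assert c.region_catalog == {"superiortemporal": "cortical_thickness"}


def test_single_visit_subjects_excluded_with_count(tmp_path, caplog):
    rows = []
    for s, times in {"a": [0, 12], "b": [0], "c": [0, 6, 12], "d": [0], "e": [0, 8]}.items():
        for t in times:
            rows.append({"subject_id": s, "group": "G", "time_months": float(t), "y": 1.0})
    path = tmp_path / "c.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    with caplog.at_level("WARNING"):
        c = read_cohort(path, region_catalog={})
    assert c.n_excluded == 2
    assert set(c.subjects) == {"a", "c", "e"}
    assert "excluding 2 subject" in caplog.text


def test_structural_errors_are_distinct():
    base = pd.DataFrame(
        {"subject_id": ["a", "a"], "group": ["G", "G"], "time_months": [0.0, 12.0]}
    )
    with pytest.raises(MissingColumnError):
        validate_cohort_table(base.drop(columns=["group"]))
    dup = pd.concat([base, base.iloc[[1]]])
    with pytest.raises(DuplicateVisitError):
        validate_cohort_table(dup)
    nobase = base.assign(time_months=[6.0, 12.0])
    with pytest.raises(MissingBaselineError):
        validate_cohort_table(nobase)


APARC = """# Table of FreeSurfer cortical parcellation anatomical statistics
# hemi lh
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd
bankssts 1000 700 1800 {b:.3f} 0.5 0.1 0.02 10 1.0
superiortemporal 2000 1400 4000 {s:.3f} 0.5 0.1 0.02 12 1.2
"""

ASEG = """# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1500000.000000, mm^3
# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax normRange
 1 10 5000 {mb:.1f} Midbrain 100 5 80 120 40
 2 11 14000 14000.0 Pons 100 5 80 120 40
 3 12 3000 3500.0 Putamen 80 5 60 100 40
"""


def test_freesurfer_stats_parsing(tmp_path):
    p = tmp_path / "lh.aparc.stats"
    p.write_text(APARC.format(b=2.4, s=2.6))
    thick = parse_aparc_stats(p)
    assert thick == {"bankssts": 2.4, "superiortemporal": 2.6}
    a = tmp_path / "aseg.stats"
    a.write_text(ASEG.format(mb=5000.0))
    vols, etiv = parse_aseg_stats(a)
    assert vols["Midbrain"] == 5000.0 and vols["Putamen"] == 3500.0
    assert etiv == 1500000.0


def test_freesurfer_manifest_builds_hemisphere_averaged_cohort(tmp_path):
    for visit, (lh, rh, mb) in {"v0": (2.4, 2.6, 5000.0), "v1": (2.2, 2.4, 4700.0)}.items():
        (tmp_path / f"{visit}_lh.stats").write_text(APARC.format(b=lh, s=lh + 0.2))
        (tmp_path / f"{visit}_rh.stats").write_text(APARC.format(b=rh, s=rh + 0.2))
        (tmp_path / f"{visit}_aseg.stats").write_text(ASEG.format(mb=mb))
    manifest = pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "time_months": [0.0, 12.0],
            "group": ["PSP", "PSP"],
            "lh_aparc": ["v0_lh.stats", "v1_lh.stats"],
            "rh_aparc": ["v0_rh.stats", "v1_rh.stats"],
            "aseg": ["v0_aseg.stats", "v1_aseg.stats"],
        }
    )
    mpath = tmp_path / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    c = read_freesurfer_cohort(mpath)
    row0 = c.data[c.data["time_months"] == 0.0].iloc[0]
    assert row0["bankssts"] == pytest.approx(2.5)
    assert row0["Midbrain"] == 5000.0
    assert row0["tiv"] == 1500000.0
    assert c.region_catalog["Midbrain"] == "brainstem_volume"
    assert c.region_catalog["Putamen"] == "subcortical_volume"
    assert c.region_catalog["bankssts"] == "cortical_thickness"


def test_ptau_mixture_straddles_threshold():
    cfg = CohortConfig(
        groups=(
            GroupSpec(label="AD", n_subjects=300, outcomes=(OutcomeSpec(name="y"),),
                      amyloid_prevalence=1.0),
            GroupSpec(label="CBD", n_subjects=300, outcomes=(OutcomeSpec(name="y"),),
                      amyloid_prevalence=0.0),
        ),
        seed=2,
    )
    c = generate_cohort(cfg)
    base = c.baseline()
    pos = base[base["amyloid_pet"] == "positive"]["ptau217_pgml"]
    neg = base[base["amyloid_pet"] == "negative"]["ptau217_pgml"]
    # the printed positivity threshold separates the components imperfectly
    assert 0.7 < (pos >= 0.25).mean() < 1.0
    assert 0.7 < (neg < 0.25).mean() < 1.0
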
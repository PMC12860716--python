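import numpy as np
import pytest

from tautrial.cohort import (
    BRAINSTEM_VOLUME,
    CohortConfig,
    GroupSpec,
    OutcomeSpec,
    VisitSchedule,
)


def outcome(
    name="Midbrain",
    kind=BRAINSTEM_VOLUME,
    mean=5000.0,
    delta12=-6.0,
    pct=True,
    sd_intercept=0.0,
    sd_slope=0.0,
    corr=0.0,
    sd_residual=0.0,
    **kw,
):
    return OutcomeSpec(
        name=name, kind=kind, baseline_mean=mean, delta12=delta12,
        delta12_is_percent=pct, sd_intercept=sd_intercept, sd_slope=sd_slope,
        corr=corr, sd_residual=sd_residual, **kw,
    )


def config(
    outcomes,
    n=20,
    groups=("G",),
    times=(0.0, 6.0, 12.0),
    jitter=0.0,
    fixed=False,
    attrition=0.0,
    seed=0,
    **group_kw,
):
    """Small single- or multi-group cohort config for tests."""
    if not isinstance(outcomes, dict):
        outcomes = {g: tuple(outcomes) for g in groups}
    else:
        groups = tuple(outcomes)
    gs = tuple(
        GroupSpec(label=g, n_subjects=n, outcomes=tuple(outcomes[g]), **group_kw)
        for g in groups
    )
    return CohortConfig(
        groups=gs,
        schedule=VisitSchedule(nominal_times=tuple(times), jitter_sd=jitter, fixed=fixed),
        attrition_hazard=attrition,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
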
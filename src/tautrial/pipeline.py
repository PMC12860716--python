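"""End-to-end pipeline: simulate/load -> enrich -> fit -> design -> search.

The run report compares estimated trial sizes across participant-selection
strategies (clinical phenotype vs MRI/biomarker enrichment) and endpoints
(clinical scale, single-region midbrain percent change, composite MRI
signature), the summary a trial designer needs to choose both the entry
criterion and the primary outcome.

Determinism: one global seed; each stochastic stage derives its own seed by
a fixed offset (cohort +1, cutpoint bootstrap +2, anything downstream +3…)
and every derived seed is recorded in the resolved config written next to
the artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .design import DesignInput, design_from_fit, jackknife_ci, required_n_slope
from .enrichment import fit_diagnostic_model, labels_frame, apply_enrichment, optimize_cutpoint
from .io import read_cohort, write_cohort
from .longitudinal import LMMSpec, fit_lmm
from .presets import observational_4rt_config
from .signature import ranking_frame, search_best_signature

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    output_dir: str = "tautrial_run"
    seed: int = 0
    cohort_path: str | None = None  # read instead of simulating
    n_psp: int = 51
    n_cbd: int = 41
    n_ad: int = 14
    enrichment_n_boot: int = 500
    enrichment_metric: str = "youden"
    enrichment_cutoff: str | float = "auto"
    ad_rules: bool = True
    clinical_outcome: str = "PSPRS"
    mri_outcome: str = "Midbrain"
    clinical_selection_phenotype: str = "RS"
    enriched_selection_label: str = "MRI-PSP"
    effect: float = 0.30
    power: float = 0.80
    alpha: float = 0.05
    attrition: float = 0.10
    schedule: tuple[float, ...] = (0.0, 6.0, 12.0)
    search_max_size: int = 3
    search_p_threshold: float = 0.05
    jackknife: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for bookkeeping in ("version", "derived_seeds"):
            raw.pop(bookkeeping, None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "schedule" in raw:
            raw["schedule"] = tuple(float(t) for t in raw["schedule"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["schedule"] = list(self.schedule)
        d["version"] = __version__
        d["derived_seeds"] = {"cohort": self.seed + 1, "cutpoint_bootstrap": self.seed + 2}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunReport:
    report: pd.DataFrame
    best_signature: tuple[str, ...]
    artifacts: dict[str, Path] = field(default_factory=dict)


def _pilot_design(cohort: Cohort, mask, outcome: str, transform: str, base: DesignInput,
                  covariates: tuple[str, ...], jackknife: bool):
    sub = cohort.subset(mask)
    spec = LMMSpec(outcome=outcome, transform=transform, group_col="__one", covariates=covariates)
    sub = sub.with_column("__one", ["all"] * len(sub.data))
    fit = fit_lmm(sub, spec)
    design = design_from_fit(fit, force=True, **{
        f.name: getattr(base, f.name)
        for f in dataclasses.fields(DesignInput)
        if f.name not in ("beta1", "sigma2_slope", "sigma2_resid")
    })
    result = required_n_slope(design)
    ci = None
    if jackknife:
        def _fn(c: Cohort):
            f2 = fit_lmm(c, spec)
            d2 = design_from_fit(f2, force=True, effect=base.effect, power=base.power,
                                 alpha=base.alpha, attrition=base.attrition,
                                 schedule=base.schedule)
            return required_n_slope(d2)
        ci = jackknife_ci(sub, _fn)
    return fit, result, ci


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages, writing per-stage artifacts under ``output_dir``.

    Idempotent for a fixed config: artifacts carry no timestamps and all
    randomness is seeded, so two runs produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # stage 1: cohort
    if config.cohort_path is not None:
        src = Path(config.cohort_path)
        if not src.exists():
            raise PipelineError(f"cohort path does not exist: {src}")
        cohort = read_cohort(src)
    else:
        cfg = observational_4rt_config(
            seed=config.seed + 1, n_psp=config.n_psp, n_cbd=config.n_cbd, n_ad=config.n_ad
        )
        from .cohort import generate_cohort

        cohort = generate_cohort(cfg)
    artifacts["cohort"] = write_cohort(cohort, out / "cohort.csv")

    # stage 2: enrichment — the classifier is trained on the cohort's
    # etiology labels (standing in for an autopsy-confirmed training set)
    model = fit_diagnostic_model(cohort.subset(cohort.data["group"].isin(["PSP", "CBD"])))
    base = cohort.baseline()
    train = base[base["group"].isin(["PSP", "CBD"])]
    probs = model.p_positive(train)
    if config.enrichment_cutoff == "auto":
        cp = optimize_cutpoint(
            probs.to_numpy(), (train["group"] == "PSP").to_numpy(),
            n_boot=config.enrichment_n_boot, metric=config.enrichment_metric,
            seed=config.seed + 2,
        )
        cutoff = cp.cutoff
        (out / "cutpoint.json").write_text(json.dumps({
            "cutoff": cp.cutoff, "auc": cp.auc, "sensitivity": cp.sensitivity,
            "specificity": cp.specificity, "ppv": cp.ppv, "npv": cp.npv,
            "n_boot": cp.n_boot, "metric": cp.metric,
        }, indent=1))
        artifacts["cutpoint"] = out / "cutpoint.json"
    else:
        cutoff = float(config.enrichment_cutoff)
    labels = apply_enrichment(cohort, model, cutoff, ad_rules_on=config.ad_rules)
    lf = labels_frame(labels)
    lf.to_csv(out / "labels.csv", index=False)
    artifacts["labels"] = out / "labels.csv"
    enriched = cohort.data["subject_id"].map(lf.set_index("subject_id")["label"])
    cohort = cohort.with_column("enriched_group", enriched)

    # stage 3+4: per-strategy, per-endpoint pilot fits and trial sizes
    designs = DesignInput(effect=config.effect, power=config.power, alpha=config.alpha,
                          attrition=config.attrition, schedule=config.schedule)
    selections = {
        "clinical": cohort.data["phenotype"] == config.clinical_selection_phenotype,
        "enriched": cohort.data["enriched_group"] == config.enriched_selection_label,
    }

    # stage 5: signature search on the enriched selection
    search_cohort = cohort.subset(selections["enriched"])
    results = search_best_signature(
        search_cohort, design=designs, max_size=config.search_max_size,
        p_threshold=config.search_p_threshold,
    )
    ranking_frame(results).to_csv(out / "search.csv", index=False)
    artifacts["search"] = out / "search.csv"
    best = results[0].regions

    endpoints = {
        config.clinical_outcome: (config.clinical_outcome, "none",
                                  ("age_baseline", "sex", "baseline_value")),
        f"{config.mri_outcome}_pct": (config.mri_outcome, "pct_change", ("age_baseline", "sex")),
    }
    rows = []
    fits_json = {}
    for sel_name, mask in selections.items():
        for ep_name, (outcome, transform, covs) in endpoints.items():
            fit, res, ci = _pilot_design(cohort, mask, outcome, transform, designs, covs,
                                         config.jackknife)
            slope, _ = fit.slope()
            rows.append({
                "selection": sel_name, "endpoint": ep_name,
                "n_total": res.n_total, "n_per_arm": res.n_per_arm,
                "slope_per_month": slope,
                "ci_low": None if ci is None else ci.lower,
                "ci_high": None if ci is None else ci.upper,
                "n_subjects": fit.n_subjects,
            })
            fits_json[f"{sel_name}:{ep_name}"] = {
                "slope_per_month": slope, "sigma2_slope": fit.sigma2_b1,
                "sigma2_resid": fit.sigma2_resid, "n_subjects": fit.n_subjects,
                "converged": fit.converged,
            }
        # composite signature endpoint, evaluated within each selection
        sub = cohort.subset(mask)
        from .signature import composite_signature

        sig = composite_signature(sub, best)
        sub = sub.with_column("signature_pct", sig.to_numpy())
        fit, res, ci = _pilot_design(sub, sub.data["signature_pct"].notna(), "signature_pct",
                                     "none", designs, ("age_baseline", "sex"), config.jackknife)
        slope, _ = fit.slope()
        rows.append({
            "selection": sel_name, "endpoint": "signature_pct",
            "n_total": res.n_total, "n_per_arm": res.n_per_arm,
            "slope_per_month": slope,
            "ci_low": None if ci is None else ci.lower,
            "ci_high": None if ci is None else ci.upper,
            "n_subjects": fit.n_subjects,
        })
        fits_json[f"{sel_name}:signature_pct"] = {
            "slope_per_month": slope, "sigma2_slope": fit.sigma2_b1,
            "sigma2_resid": fit.sigma2_resid, "n_subjects": fit.n_subjects,
            "converged": fit.converged,
        }

    report = pd.DataFrame(rows)
    report["signature_regions"] = "+".join(best)
    report.to_csv(out / "report.csv", index=False, float_format="%.6g")
    (out / "fits.json").write_text(json.dumps(fits_json, indent=1))
    config.to_yaml(out / "resolved_config.yaml")
    artifacts.update(report=out / "report.csv", fits=out / "fits.json",
                     config=out / "resolved_config.yaml")
    return RunReport(report=report, best_signature=best, artifacts=artifacts)
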
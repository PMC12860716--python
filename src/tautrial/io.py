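"""Reading and writing cohort tables.

Two dialects are supported:

* long-format delimited text (CSV/TSV) with a JSON sidecar declaring which
  columns are regional measures and of what kind;
* FreeSurfer-style ``aparc.stats`` / ``aseg.stats`` bodies (whitespace
  tables under ``#`` comment headers) plus a visit manifest, from which
  hemisphere-averaged cortical thickness, subcortical/brainstem volumes and
  the estimated total intracranial volume are extracted.

Hemisphere-labelled cortical columns (``lh_*`` / ``rh_*``) are averaged
into a single value per region on ingest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    BRAINSTEM_VOLUME,
    CORTICAL_THICKNESS,
    SUBCORTICAL_VOLUME,
    Cohort,
    CohortValidationError,
    MissingColumnError,
    apply_inclusion_filter,
    validate_cohort_table,
)

logger = logging.getLogger(__name__)

#: aseg/brainstem structure names treated as brainstem rather than subcortical
BRAINSTEM_STRUCTURES = frozenset(
    {"Midbrain", "Pons", "Medulla", "SCP", "Brain-Stem", "Whole_brainstem"}
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".regions.json")


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the visit table (CSV or TSV by suffix) plus the region sidecar."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    cohort.data.to_csv(path, sep=sep, index=False)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"region_catalog": cohort.region_catalog}, indent=1))
    return path


def _average_hemispheres(df: pd.DataFrame, catalog: dict[str, str]) -> tuple[pd.DataFrame, dict[str, str]]:
    lh = {c[3:]: c for c in df.columns if c.startswith("lh_")}
    rh = {c[3:]: c for c in df.columns if c.startswith("rh_")}
    merged = dict(catalog)
    for region in sorted(set(lh) | set(rh)):
        cols = [c for c in (lh.get(region), rh.get(region)) if c is not None]
        df[region] = df[cols].mean(axis=1)
        kinds = {merged.pop(c) for c in cols if c in merged}
        merged[region] = kinds.pop() if kinds else merged.get(region, CORTICAL_THICKNESS)
        df = df.drop(columns=cols)
    return df, merged


def read_cohort(path: str | Path, region_catalog: dict[str, str] | None = None) -> Cohort:
    """Read a long-format cohort table written by :func:`write_cohort`.

    The region catalog is taken from the JSON sidecar unless supplied
    explicitly.  Subjects with a single usable visit are excluded with a
    logged warning; the exclusion count is reported on the returned cohort.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if region_catalog is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            region_catalog = json.loads(sidecar.read_text())["region_catalog"]
        else:
            raise MissingColumnError(
                f"no region sidecar at {sidecar}; pass region_catalog explicitly"
            )
    df, region_catalog = _average_hemispheres(df, dict(region_catalog))
    validate_cohort_table(df)
    df, n_excluded = apply_inclusion_filter(df)
    return Cohort(df, region_catalog, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# FreeSurfer stats dialect
# ---------------------------------------------------------------------------


def parse_aparc_stats(path: str | Path) -> dict[str, float]:
    """Extract ``StructName -> ThickAvg`` from an aparc.stats body."""
    return _parse_stats_table(path, "ThickAvg")


def parse_aseg_stats(path: str | Path) -> tuple[dict[str, float], float | None]:
    """Extract ``StructName -> Volume_mm3`` and eTIV from an aseg.stats body."""
    volumes = _parse_stats_table(path, "Volume_mm3")
    etiv = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# Measure") and "EstimatedTotalIntraCranialVol" in line:
            etiv = float(line.rstrip().rstrip(",").split(",")[-2])
    return volumes, etiv


def _parse_stats_table(path: str | Path, value_col: str) -> dict[str, float]:
    headers: list[str] | None = None
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("# ColHeaders"):
            headers = line.split()[2:]
            continue
        if line.startswith("#") or not line.strip():
            continue
        if headers is None:
            raise CohortValidationError(f"{path}: no '# ColHeaders' line before data rows")
        fields = line.split()
        row = dict(zip(headers, fields))
        if "StructName" not in row or value_col not in row:
            raise CohortValidationError(f"{path}: table lacks StructName/{value_col} columns")
        out[row["StructName"]] = float(row[value_col])
    return out


def read_freesurfer_cohort(manifest_path: str | Path) -> Cohort:
    """Assemble a cohort from per-scan FreeSurfer stats files.

    The manifest is a CSV with one row per scan: mandatory columns
    ``subject_id``, ``time_months`` plus any covariate columns, and file
    columns ``lh_aparc``, ``rh_aparc``, ``aseg`` holding paths relative to
    the manifest.  Cortical thickness is averaged across hemispheres; aseg
    structures in :data:`BRAINSTEM_STRUCTURES` are catalogued as brainstem
    volumes, the rest as subcortical volumes.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "time_months", "lh_aparc", "rh_aparc", "aseg"):
        if col not in manifest.columns:
            raise MissingColumnError(f"manifest lacks column {col!r}")
    base = manifest_path.parent

    rows = []
    catalog: dict[str, str] = {}
    for _, rec in manifest.iterrows():
        lh = parse_aparc_stats(base / rec["lh_aparc"])
        rh = parse_aparc_stats(base / rec["rh_aparc"])
        volumes, etiv = parse_aseg_stats(base / rec["aseg"])
        row = {c: rec[c] for c in manifest.columns if c not in ("lh_aparc", "rh_aparc", "aseg")}
        for region in sorted(set(lh) | set(rh)):
            vals = [v for v in (lh.get(region), rh.get(region)) if v is not None]
            row[region] = float(np.mean(vals))
            catalog[region] = CORTICAL_THICKNESS
        for name, vol in volumes.items():
            row[name] = vol
            catalog[name] = BRAINSTEM_VOLUME if name in BRAINSTEM_STRUCTURES else SUBCORTICAL_VOLUME
        if etiv is not None:
            row["tiv"] = etiv
        rows.append(row)

    df = pd.DataFrame(rows)
    if "group" not in df.columns:
        df["group"] = "unknown"
    validate_cohort_table(df)
    df, n_excluded = apply_inclusion_filter(df)
    return Cohort(df, catalog, n_excluded=n_excluded)
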
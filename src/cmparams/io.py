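"""Readers and writers for the pipeline's on-disk formats.

Long-format measurements and patient tables travel as CSV, treatment
targets and simulation scenarios as YAML, model reports as TSV and run
summaries as JSON.  Dates are ingested as ISO-8601 and converted to
integer day offsets per patient from that patient's first reading --
only day differences ever enter the arithmetic, so the choice of origin
is immaterial.  Units are whatever the targets file declares; no
conversion is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import DEFAULT_TRAJECTORIES, Cohort, OutcomeModel, VisitModel
from .timeline import TargetSpec

#: Arbitrary calendar origin used when *writing* day-offset data as dates.
EPOCH = pd.Timestamp("2000-01-01")

MEASUREMENT_COLUMNS = ("patient_id", "cm_name", "date", "value")


def read_targets(path) -> dict:
    """Target YAML: map cm_name -> {low: ..., high: ...} (either optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"targets file {path}: expected a mapping of CM -> bounds")
    out = {}
    for cm, bounds in raw.items():
        bounds = bounds or {}
        extra = set(bounds) - {"low", "high"}
        if extra:
            raise ValueError(f"targets file {path}: unknown keys {sorted(extra)} for {cm}")
        out[cm] = TargetSpec(cm, low=bounds.get("low"), high=bounds.get("high"))
    return out


def write_targets(targets: Mapping[str, TargetSpec], path) -> None:
    data = {}
    for cm, t in targets.items():
        bounds = {}
        if t.low is not None:
            bounds["low"] = float(t.low)
        if t.high is not None:
            bounds["high"] = float(t.high)
        data[cm] = bounds
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_measurements(path) -> pd.DataFrame:
    """Measurement CSV (patient_id, cm_name, date, value) -> long day-offset frame.

    Malformed rows are reported with their line numbers.  Days are
    offsets from each patient's first reading.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "cm_name": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = dates.isna() | values.isna() | df["patient_id"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:20]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df = df.assign(date=dates, value=values)
    origin = df.groupby("patient_id")["date"].transform("min")
    day = (df["date"] - origin).dt.days.astype(np.int64)
    return pd.DataFrame({
        "patient_id": df["patient_id"],
        "cm_name": df["cm_name"],
        "day": day,
        "value": df["value"],
    })


def read_patients(path, measurements: Optional[pd.DataFrame] = None,
                  raw_dates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Patient CSV with index_date (ISO) and optional covariates/outcome.

    ``raw_dates``, when given, must map patient_id -> first measurement
    date so that ``index_day`` lands on the same per-patient day scale
    as :func:`read_measurements`.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns or "index_date" not in df.columns:
        raise ValueError(f"{path}: needs patient_id and index_date columns")
    idx_dates = pd.to_datetime(df["index_date"], format="ISO8601", errors="coerce")
    if idx_dates.isna().any():
        lines = (df.index[idx_dates.isna()] + 2).tolist()[:20]
        raise ValueError(f"{path}: malformed index_date at lines {lines}")
    if raw_dates is None:
        origin = idx_dates.min()
        first = pd.Series(origin, index=df["patient_id"].values)
    else:
        first = raw_dates.set_index("patient_id")["first_date"]
    offsets = idx_dates.values - first.reindex(df["patient_id"]).values
    df = df.drop(columns=["index_date"])
    df["index_day"] = (offsets / np.timedelta64(1, "D")).astype(np.int64)
    return df


def first_dates(path) -> pd.DataFrame:
    """patient_id -> first measurement date of the raw CSV (for index alignment)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    out = df.assign(date=dates).groupby("patient_id", as_index=False)["date"].min()
    return out.rename(columns={"date": "first_date"})


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a simulated cohort as the CSV/YAML pair the pipeline consumes.

    Day offsets become ISO dates anchored at a fixed calendar origin.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meas = cohort.measurements
    pd.DataFrame({
        "patient_id": meas["patient_id"],
        "cm_name": meas["cm_name"],
        "date": (EPOCH + pd.to_timedelta(meas["day"], unit="D")).dt.strftime("%Y-%m-%d"),
        "value": meas["value"].round(4),
    }).to_csv(out / "measurements.csv", index=False)
    pats = cohort.patients
    tbl = pats.drop(columns=["index_day", "true_lp"]).copy()
    tbl["index_date"] = (
        EPOCH + pd.to_timedelta(pats["index_day"], unit="D")
    ).dt.strftime("%Y-%m-%d")
    tbl["age"] = tbl["age"].round(1)
    tbl.to_csv(out / "patients.csv", index=False)
    write_targets(cohort.targets, out / "targets.yaml")


def write_parameter_table(table: pd.DataFrame, path) -> None:
    """Parameter output CSV: one row per patient, missing cells empty."""
    table.to_csv(path, index=True, float_format="%.10g")


def read_parameter_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_model_report(fit_frame: pd.DataFrame, path) -> None:
    """Model TSV: Parameter / Coefficient / StdErr / pValue / CI95lo / CI95hi."""
    fit_frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def scenario_from_yaml(path) -> dict:
    """Simulation scenario YAML -> keyword arguments for ``simulate_cohort``.

    Recognized keys: ``n_patients``, ``missing_cm_prob``, ``visit``
    (base_rate, abnormal_multiplier, followup_years), ``outcome``
    (intercept, coefficients, references, covariate_coefficients,
    covariate_references) and ``trajectories`` (per-CM overrides of the
    default TrajectoryModel fields).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "n_patients" in raw:
        kwargs["n_patients"] = int(raw["n_patients"])
    if "missing_cm_prob" in raw:
        kwargs["missing_cm_prob"] = float(raw["missing_cm_prob"])
    if "visit" in raw:
        v = raw["visit"]
        if "followup_years" in v:
            v["followup_years"] = tuple(v["followup_years"])
        kwargs["visit_model"] = VisitModel(**v)
    if "outcome" in raw:
        kwargs["outcome_model"] = OutcomeModel(**raw["outcome"])
    if "trajectories" in raw:
        trajs = dict(DEFAULT_TRAJECTORIES)
        from dataclasses import replace

        for cm, overrides in raw["trajectories"].items():
            if "clip" in overrides:
                overrides["clip"] = tuple(overrides["clip"])
            trajs[cm] = replace(trajs[cm], **overrides)
        kwargs["trajectories"] = trajs
    return kwargs
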
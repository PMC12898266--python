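"""Vectorized parameter derivation for long-format measurement tables.

The per-series routines in :mod:`cmparams.engine` are the readable
reference; deriving 13 parameters for hundreds of thousands of
patient x CM series needs group-wise numpy instead.  This module
computes the full parameter table from a long dataframe
(``patient_id``, ``cm_name``, ``day``, ``value``) with ``np.reduceat``
over sorted group blocks, and is tested element-by-element against the
per-series engine on random series.

Missing cells are NaN in the output; integer-valued parameters are kept
as floats so missingness stays explicit.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PARAMETER_NAMES
from .timeline import CM_NAMES, TargetSpec


def _abnormal_mask(values: np.ndarray, target: TargetSpec) -> np.ndarray:
    m = np.zeros(values.shape, dtype=bool)
    if target.low is not None:
        m |= values < target.low
    if target.high is not None:
        m |= values > target.high
    return m


def _excess(values: np.ndarray, target: TargetSpec) -> np.ndarray:
    e = np.zeros(values.shape, dtype=np.float64)
    if target.high is not None:
        e += np.maximum(values - target.high, 0.0)
    if target.low is not None:
        e += np.maximum(target.low - values, 0.0)
    return e


def truncate_frame(measurements: pd.DataFrame, patients: pd.DataFrame,
                   blackout_days: int = 14) -> pd.DataFrame:
    """Keep rows with ``day <= index_day - blackout_days`` per patient.

    ``patients`` must carry ``patient_id`` and ``index_day``; patients
    absent from the table lose all their rows.
    """
    idx = patients.set_index("patient_id")["index_day"]
    cutoff = measurements["patient_id"].map(idx) - blackout_days
    return measurements.loc[measurements["day"] <= cutoff]


def derive_table(
    measurements: pd.DataFrame,
    targets: Mapping[str, TargetSpec],
    patient_ids: Optional[Sequence] = None,
    cms: Iterable[str] = CM_NAMES,
    time_wt_avg_on: str = "auc",
) -> pd.DataFrame:
    """Derive the patients x (13 per CM) parameter table.

    Columns are ``<CM><Parameter>`` in CM-major order; rows are indexed
    by patient id (the union of ids seen in the table, or
    ``patient_ids`` when given, e.g. to include patients with no
    measurements).  Unknown CM names in ``cms`` must have a target.
    """
    if time_wt_avg_on not in ("auc", "abn_auc"):
        raise ValueError(f"unknown time_wt_avg numerator {time_wt_avg_on!r}")
    cms = tuple(cms)
    for cm in cms:
        if cm not in targets:
            raise KeyError(f"no target specified for CM {cm!r}")
    if patient_ids is None:
        patient_ids = np.unique(np.asarray(measurements["patient_id"]))
    index = pd.Index(patient_ids, name="patient_id")
    data = {}
    for cm in cms:
        sub = measurements.loc[measurements["cm_name"] == cm]
        block = _derive_cm_block(sub, targets[cm], index, time_wt_avg_on)
        for p in PARAMETER_NAMES:
            data[f"{cm}{p}"] = block[p]
    return pd.DataFrame(data, index=index)


def _derive_cm_block(sub: pd.DataFrame, target: TargetSpec,
                     index: pd.Index, time_wt_avg_on: str) -> dict:
    nan = np.full(len(index), np.nan)
    cols = {p: nan.copy() for p in PARAMETER_NAMES}
    if len(sub) == 0:
        return cols

    # stable sort by (patient, day); same-day duplicates keep the last entry
    sub = sub.sort_values(["patient_id", "day"], kind="stable")
    sub = sub.drop_duplicates(subset=["patient_id", "day"], keep="last")
    pid = np.asarray(sub["patient_id"])
    day = sub["day"].to_numpy(dtype=np.int64)
    val = sub["value"].to_numpy(dtype=np.float64)
    N = len(val)

    # group boundaries over the sorted block
    new_grp = np.empty(N, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = pid[1:] != pid[:-1]
    starts = np.flatnonzero(new_grp)
    grp = np.cumsum(new_grp) - 1                       # group ordinal per row
    counts = np.diff(np.r_[starts, N])
    last_idx = np.r_[starts[1:], N] - 1
    group_pid = pid[starts]
    row_of = index.get_indexer(group_pid)              # scatter positions
    G = len(starts)

    abn = _abnormal_mask(val, target)
    exc = _excess(val, target)

    # --- per-group sums of per-reading quantities
    num_not = np.add.reduceat(abn.astype(np.int64), starts)
    vsum = np.add.reduceat(val, starts)
    vsumsq = np.add.reduceat(val * val, starts)

    # --- pair quantities: contribution of pair (i, i+1) stored at i,
    # zeroed on the last row of each group so reduceat sums per group
    pair_ok = np.zeros(N, dtype=bool)
    pair_ok[:-1] = grp[:-1] == grp[1:]
    dd = np.zeros(N, dtype=np.float64)
    dd[:-1] = (day[1:] - day[:-1]).astype(np.float64)
    dd[~pair_ok] = 0.0
    vnext = np.zeros(N, dtype=np.float64)
    vnext[:-1] = val[1:]
    enext = np.zeros(N, dtype=np.float64)
    enext[:-1] = exc[1:]
    abnnext = np.zeros(N, dtype=bool)
    abnnext[:-1] = abn[1:]

    auc = np.add.reduceat(np.where(pair_ok, (val + vnext) / 2.0 * dd, 0.0), starts)
    abn_auc = np.add.reduceat(np.where(pair_ok, (exc + enext) / 2.0 * dd, 0.0), starts)
    fu_days = np.add.reduceat(np.where(pair_ok & abn & abnnext, dd, 0.0), starts)
    absdiff = np.add.reduceat(np.where(pair_ok, np.abs(vnext - val), 0.0), starts)

    multi = counts >= 2
    span = (day[last_idx] - day[starts]).astype(np.float64)

    # --- clusters: runs of consecutive abnormal rows within a group
    prev_same_abn = np.zeros(N, dtype=bool)
    prev_same_abn[1:] = (grp[1:] == grp[:-1]) & abn[:-1]
    run_start = abn & ~prev_same_abn
    next_same_abn = np.zeros(N, dtype=bool)
    next_same_abn[:-1] = (grp[1:] == grp[:-1]) & abn[1:]
    run_end = abn & ~next_same_abn
    cs = np.flatnonzero(run_start)
    ce = np.flatnonzero(run_end)
    num_clust = np.add.reduceat(run_start.astype(np.int64), starts)

    cl_count = ce - cs + 1
    cl_dur = (day[ce] - day[cs]).astype(np.float64)
    cl_grp = grp[cs]

    # longest cluster with >= 2 readings, per group
    max_clust = np.full(G, np.nan)
    if len(cs):
        eligible = np.where(cl_count >= 2, cl_dur, -1.0)
        cg_new = np.empty(len(cs), dtype=bool)
        cg_new[0] = True
        cg_new[1:] = cl_grp[1:] != cl_grp[:-1]
        cg_starts = np.flatnonzero(cg_new)
        best = np.maximum.reduceat(eligible, cg_starts)
        tgt = cl_grp[cg_starts]
        max_clust[tgt] = np.where(best >= 0, best, np.nan)

    # open cluster = the run ending on the group's last row
    time_not = np.full(G, np.nan)
    ct_not = np.full(G, np.nan)
    if len(cs):
        open_cl = ce == last_idx[cl_grp]
        time_not[cl_grp[open_cl]] = cl_dur[open_cl]
        ct_not[cl_grp[open_cl]] = cl_count[open_cl]

    # --- dispersion
    mean = vsum / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum(vsumsq - counts * mean * mean, 0.0) / np.where(multi, counts - 1, 1)
        std = np.sqrt(var)
        coeff_var = np.where(multi & (mean != 0.0), std / mean, np.nan)
        mean_val_diff = np.where(multi, absdiff / np.maximum(counts - 1, 1), np.nan)

    # --- trends
    value1 = val[last_idx]
    net_change = value1 - val[starts]
    lag3 = np.full(G, np.nan)
    has4 = counts >= 4
    i4 = last_idx[has4]
    if i4.size:
        lag3_mean = (val[i4 - 3] + val[i4 - 2] + val[i4 - 1]) / 3.0
        with np.errstate(invalid="ignore", divide="ignore"):
            lag3[has4] = np.where(
                lag3_mean != 0.0, (value1[has4] - lag3_mean) / lag3_mean, np.nan
            )

    numerator = auc if time_wt_avg_on == "auc" else abn_auc
    with np.errstate(invalid="ignore", divide="ignore"):
        time_wt_avg = np.where(multi & (span > 0), numerator / np.where(span > 0, span, 1), np.nan)

    valid = row_of >= 0  # patients outside the requested index are dropped

    def scatter(values: np.ndarray) -> np.ndarray:
        dest = np.full(len(index), np.nan)
        dest[row_of[valid]] = values[valid]
        return dest

    cols["Value1"] = scatter(value1)
    cols["FUDaysNotAtGoal"] = scatter(np.where(multi, fu_days, np.nan))
    cols["NumNotAtGoal"] = scatter(num_not.astype(np.float64))
    cols["AbnAUC"] = scatter(np.where(multi, abn_auc, np.nan))
    cols["TimeWtAvg"] = scatter(time_wt_avg)
    cols["TimeNotAtGoal"] = scatter(time_not)
    cols["CtNotAtGoal"] = scatter(ct_not)
    cols["MaxClustDays"] = scatter(max_clust)
    cols["NumClust"] = scatter(num_clust.astype(np.float64))
    cols["CoeffVar"] = scatter(coeff_var)
    cols["MeanValDiff"] = scatter(mean_val_diff)
    cols["NetChange"] = scatter(net_change)
    cols["Lag3Dev"] = scatter(lag3)
    return cols
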
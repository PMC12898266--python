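"""Synthesis of the 13 per-CM parameters from a measurement series.

A patient's complete value set for one CM is summarized into 13 scalar
parameters spanning seven clinical attributes:

==================  =============================================================
attribute           parameters
==================  =============================================================
current control     ``Value1`` -- the most recent value
chronicity          ``FUDaysNotAtGoal`` (days spanned by abnormal->abnormal
                    pairs), ``NumNotAtGoal`` (count of abnormal readings)
disease burden      ``AbnAUC`` (trapezoidal area outside the target, unit*days),
                    ``TimeWtAvg`` (trapezoidal AUC / days of follow-up)
refractoriness      ``TimeNotAtGoal``/``CtNotAtGoal`` (duration and length of the
                    currently open abnormal cluster), ``MaxClustDays`` (longest
                    cluster with >= 2 readings)
relapse             ``NumClust`` (number of abnormal clusters)
lability            ``CoeffVar`` (sample SD / mean), ``MeanValDiff`` (mean
                    absolute successive difference)
temporal trends     ``NetChange`` (last minus first value), ``Lag3Dev``
                    (fractional deviation of the last value from the mean of
                    the 3 preceding ones)
==================  =============================================================

All areas use simple endpoint trapezoids -- no interpolation,
extrapolation or curve fitting -- so the summary is an exact functional
of the recorded readings.  Two computation paths are provided: an
incremental :class:`RunningSummary` updated as each value arrives, and
batch functions recomputing from the full series.  The two are
contractually identical (exact on counts/days, 1e-9 relative on reals)
and are tested against each other.

Missingness is explicit (``None``), never a sentinel:

* a series with no readings yields an all-missing vector;
* span-based parameters (``FUDaysNotAtGoal``, ``AbnAUC``, ``TimeWtAvg``,
  ``CoeffVar``, ``MeanValDiff``) need at least 2 readings;
* ``TimeNotAtGoal``/``CtNotAtGoal`` exist only while the most recent
  reading is abnormal (an open cluster);
* ``MaxClustDays`` needs at least one cluster of >= 2 consecutive
  abnormal readings;
* ``Lag3Dev`` needs 3 readings before the most recent one, and a
  nonzero lagging mean; ``CoeffVar`` needs a nonzero grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .timeline import CMSeries, Reading, TargetSpec, is_abnormal


@dataclass
class Cluster:
    """A maximal run of consecutive abnormal readings.

    Opened by a normal->abnormal transition (or an abnormal first
    reading) and closed by the next normal reading; a run still abnormal
    at the last reading is *open*.  ``duration_days`` counts days from
    the first to the last abnormal reading of the run -- the terminating
    normal reading's day is not included, since the improving interval
    is classified separately.
    """

    start_day: int
    last_abnormal_day: int
    count: int
    open: bool = True

    @property
    def duration_days(self) -> int:
        return self.last_abnormal_day - self.start_day


@dataclass
class ParameterVector:
    """The 13 derived parameters for one patient x CM."""

    value1: Optional[float] = None
    fu_days_not_at_goal: Optional[int] = None
    num_not_at_goal: Optional[int] = None
    abn_auc: Optional[float] = None
    time_wt_avg: Optional[float] = None
    time_not_at_goal: Optional[int] = None
    ct_not_at_goal: Optional[int] = None
    max_clust_days: Optional[int] = None
    num_clust: Optional[int] = None
    coeff_var: Optional[float] = None
    mean_val_diff: Optional[float] = None
    net_change: Optional[float] = None
    lag3_dev: Optional[float] = None

    #: dataclass field name for each public parameter name, attribute order.
    _FIELDS = {
        "Value1": "value1",
        "FUDaysNotAtGoal": "fu_days_not_at_goal",
        "NumNotAtGoal": "num_not_at_goal",
        "AbnAUC": "abn_auc",
        "TimeWtAvg": "time_wt_avg",
        "TimeNotAtGoal": "time_not_at_goal",
        "CtNotAtGoal": "ct_not_at_goal",
        "MaxClustDays": "max_clust_days",
        "NumClust": "num_clust",
        "CoeffVar": "coeff_var",
        "MeanValDiff": "mean_val_diff",
        "NetChange": "net_change",
        "Lag3Dev": "lag3_dev",
    }

    def as_dict(self) -> dict:
        """Parameter name -> value (None for missing), attribute order."""
        return {name: getattr(self, attr) for name, attr in self._FIELDS.items()}


# ---------------------------------------------------------------------------
# batch computations from a full series
# ---------------------------------------------------------------------------

def compute_auc(series: CMSeries) -> Optional[float]:
    """Trapezoidal area under the raw value curve, in unit*days.

    Sum over successive pairs of ``(v_i + v_{i+1})/2 * (d_{i+1} - d_i)``;
    needs at least two readings.
    """
    if len(series) < 2:
        return None
    d, v = series.days, series.values
    return float(np.sum((v[:-1] + v[1:]) / 2.0 * (d[1:] - d[:-1])))


def _excess(values: np.ndarray, target: TargetSpec) -> np.ndarray:
    """Pointwise excursion beyond the target bounds (>= 0)."""
    e = np.zeros_like(values, dtype=np.float64)
    if target.high is not None:
        e += np.maximum(values - target.high, 0.0)
    if target.low is not None:
        e += np.maximum(target.low - values, 0.0)
    return e


def compute_abn_auc(series: CMSeries, target: TargetSpec) -> Optional[float]:
    """Trapezoidal area of the excess curve beyond the target, in unit*days.

    The excess is evaluated at the readings only; threshold-crossing
    points are not interpolated, so a segment crossing the bound
    contributes a half-triangle based on endpoint excesses.
    """
    if len(series) < 2:
        return None
    d = series.days
    e = _excess(series.values, target)
    return float(np.sum((e[:-1] + e[1:]) / 2.0 * (d[1:] - d[:-1])))


def compute_time_wt_avg(series: CMSeries, target: Optional[TargetSpec] = None,
                        on: str = "auc") -> Optional[float]:
    """Time-weighted average: AUC divided by total days of follow-up.

    Robust to the tendency to measure a CM more frequently when it is
    abnormal (the raw mean is not).  ``on="abn_auc"`` divides the
    abnormal-area numerator instead (requires ``target``).
    """
    if len(series) < 2:
        return None
    span = int(series.days[-1] - series.days[0])
    if span <= 0:
        return None
    if on == "auc":
        numerator = compute_auc(series)
    elif on == "abn_auc":
        if target is None:
            raise ValueError("time-weighted average over the abnormal area needs a target")
        numerator = compute_abn_auc(series, target)
    else:
        raise ValueError(f"unknown time_wt_avg numerator {on!r}")
    return numerator / span


def compute_chronicity(series: CMSeries, target: TargetSpec) -> Tuple[int, int]:
    """(days not at goal across successive pairs, count of abnormal readings).

    Only abnormal->abnormal pairs contribute days; worsening and
    improving spans belong to neither at-goal nor not-at-goal time.
    """
    d, v = series.days, series.values
    abn = np.array([is_abnormal(x, target) for x in v], dtype=bool)
    num = int(abn.sum())
    if len(series) < 2:
        return 0, num
    both = abn[:-1] & abn[1:]
    fu_days = int(np.sum((d[1:] - d[:-1])[both]))
    return fu_days, num


def detect_clusters(series: CMSeries, target: TargetSpec) -> List[Cluster]:
    """Maximal runs of consecutive abnormal readings, in order.

    A run starting at the first reading counts as a cluster; a run still
    abnormal at the last reading is returned open.
    """
    out: List[Cluster] = []
    current: Optional[Cluster] = None
    for r in series.readings:
        if is_abnormal(r.value, target):
            if current is None:
                current = Cluster(start_day=r.day, last_abnormal_day=r.day, count=1)
            else:
                current.count += 1
                current.last_abnormal_day = r.day
        else:
            if current is not None:
                current.open = False
                out.append(current)
                current = None
    if current is not None:
        out.append(current)
    return out


def compute_refractoriness(
    clusters: Sequence[Cluster], last_reading_abnormal: bool
) -> Tuple[Optional[int], Optional[int], Optional[int]]:
    """(TimeNotAtGoal, CtNotAtGoal, MaxClustDays) from a cluster list.

    The first two describe the currently open cluster and exist only
    when the most recent reading is abnormal; the third is the longest
    duration over clusters with >= 2 readings, open or closed.
    """
    time_not = ct_not = None
    if last_reading_abnormal:
        if not clusters or not clusters[-1].open:
            raise RuntimeError("last reading abnormal but no open cluster: engine bug")
        time_not = clusters[-1].duration_days
        ct_not = clusters[-1].count
    durations = [c.duration_days for c in clusters if c.count >= 2]
    max_clust = max(durations) if durations else None
    return time_not, ct_not, max_clust


def compute_lability(series: CMSeries) -> Tuple[Optional[float], Optional[float]]:
    """(CoeffVar, MeanValDiff); both need at least two readings.

    CoeffVar is the sample (n-1) standard deviation over the grand mean
    (missing when the mean is zero); MeanValDiff is the average absolute
    difference between consecutive pairs.
    """
    if len(series) < 2:
        return None, None
    v = series.values
    mean = float(np.mean(v))
    coeff_var = None if mean == 0.0 else float(np.std(v, ddof=1)) / mean
    mean_val_diff = float(np.sum(np.abs(np.diff(v)))) / (len(v) - 1)
    return coeff_var, mean_val_diff


def compute_trends(series: CMSeries) -> Tuple[Optional[float], Optional[float]]:
    """(NetChange, Lag3Dev).

    NetChange is the most recent minus the first value (0 for a single
    reading).  Lag3Dev is ``(Value1 - Lag3Mean)/Lag3Mean`` where
    Lag3Mean averages the 3 readings immediately preceding the last;
    it is missing with fewer than 3 lagging values or a zero mean.
    """
    n = len(series)
    if n == 0:
        return None, None
    v = series.values
    net_change = float(v[-1] - v[0])
    if n < 4:
        return net_change, None
    lag3_mean = (v[-4] + v[-3] + v[-2]) / 3.0
    if lag3_mean == 0.0:
        return net_change, None
    return net_change, float((v[-1] - lag3_mean) / lag3_mean)


def batch_derive(series: CMSeries, target: TargetSpec,
                 time_wt_avg_on: str = "auc") -> ParameterVector:
    """Derive all 13 parameters from a full series in one pass.

    The independent batch counterpart of folding :func:`update` over the
    readings and calling :func:`finalize`; the two paths agree exactly on
    integer fields and to 1e-9 relative on reals.
    """
    n = len(series)
    if n == 0:
        return ParameterVector()
    v = series.values
    fu_days, num_not = compute_chronicity(series, target)
    clusters = detect_clusters(series, target)
    last_abn = is_abnormal(float(v[-1]), target)
    time_not, ct_not, max_clust = compute_refractoriness(clusters, last_abn)
    coeff_var, mean_val_diff = compute_lability(series)
    net_change, lag3_dev = compute_trends(series)
    return ParameterVector(
        value1=float(v[-1]),
        fu_days_not_at_goal=fu_days if n >= 2 else None,
        num_not_at_goal=num_not,
        abn_auc=compute_abn_auc(series, target),
        time_wt_avg=compute_time_wt_avg(series, target, on=time_wt_avg_on),
        time_not_at_goal=time_not,
        ct_not_at_goal=ct_not,
        max_clust_days=max_clust,
        num_clust=len(clusters),
        coeff_var=coeff_var,
        mean_val_diff=mean_val_diff,
        net_change=net_change,
        lag3_dev=lag3_dev,
    )


# ---------------------------------------------------------------------------
# incremental running summary
# ---------------------------------------------------------------------------

@dataclass
class RunningSummary:
    """Incremental state from which all 13 parameters can be read at any time.

    Updated whenever a new value arrives (append-only), so a patient's
    status relative to a CM can be assessed at any point in their
    record.  Dispersion uses Welford's online mean/M2 recursion, which
    keeps the incremental path within 1e-9 relative of the batch
    computation without storing the values.
    """

    n: int = 0
    first_day: Optional[int] = None
    first_value: Optional[float] = None
    last_day: Optional[int] = None
    last_value: Optional[float] = None
    mean: float = 0.0
    m2: float = 0.0
    auc: float = 0.0
    abn_auc: float = 0.0
    fu_days_not_at_goal: int = 0
    num_not_at_goal: int = 0
    sum_abs_consec_diff: float = 0.0
    #: the up-to-4 most recent values, oldest first (last is the current value)
    lag_buffer: List[float] = field(default_factory=list)
    clusters_closed: int = 0
    #: longest duration among *closed* clusters with >= 2 readings
    max_closed_clust_days: Optional[int] = None
    current_cluster: Optional[Cluster] = None
    _prev_abnormal: bool = False
    _prev_excess: float = 0.0

    def update(self, reading: Reading, target: TargetSpec) -> "RunningSummary":
        """Fold one more reading into the summary (returns self)."""
        if self.last_day is not None and reading.day < self.last_day:
            raise ValueError("out-of-order append: upstream series must be sorted")
        day, value = reading.day, reading.value
        abn = is_abnormal(value, target)
        excess = float(_excess(np.array([value]), target)[0])

        if self.n == 0:
            self.first_day, self.first_value = day, value
        else:
            dd = day - self.last_day
            self.auc += (self.last_value + value) / 2.0 * dd
            self.abn_auc += (self._prev_excess + excess) / 2.0 * dd
            if self._prev_abnormal and abn:
                self.fu_days_not_at_goal += dd
            self.sum_abs_consec_diff += abs(value - self.last_value)

        self.n += 1
        delta = value - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (value - self.mean)

        if abn:
            self.num_not_at_goal += 1
            if self.current_cluster is None:
                self.current_cluster = Cluster(start_day=day, last_abnormal_day=day, count=1)
            else:
                self.current_cluster.count += 1
                self.current_cluster.last_abnormal_day = day
        elif self.current_cluster is not None:
            closed = self.current_cluster
            closed.open = False
            self.clusters_closed += 1
            if closed.count >= 2:
                dur = closed.duration_days
                if self.max_closed_clust_days is None or dur > self.max_closed_clust_days:
                    self.max_closed_clust_days = dur
            self.current_cluster = None

        self.lag_buffer.append(value)
        if len(self.lag_buffer) > 4:
            del self.lag_buffer[0]
        self.last_day, self.last_value = day, value
        self._prev_abnormal, self._prev_excess = abn, excess
        return self

    @property
    def num_clust(self) -> int:
        return self.clusters_closed + (1 if self.current_cluster is not None else 0)

    @property
    def grand_std(self) -> Optional[float]:
        if self.n < 2:
            return None
        return float(np.sqrt(self.m2 / (self.n - 1)))

    def finalize(self, time_wt_avg_on: str = "auc", target: Optional[TargetSpec] = None
                 ) -> ParameterVector:
        """Read the 13 parameters out of the running summary."""
        if self.n == 0:
            return ParameterVector()
        n = self.n
        span = self.last_day - self.first_day
        if n >= 2 and span > 0:
            numerator = self.auc if time_wt_avg_on == "auc" else self.abn_auc
            time_wt_avg = numerator / span
        else:
            time_wt_avg = None
        coeff_var = None
        if n >= 2 and self.mean != 0.0:
            coeff_var = self.grand_std / self.mean
        time_not = ct_not = None
        if self.current_cluster is not None:
            time_not = self.current_cluster.duration_days
            ct_not = self.current_cluster.count
        max_clust = self.max_closed_clust_days
        if self.current_cluster is not None and self.current_cluster.count >= 2:
            dur = self.current_cluster.duration_days
            max_clust = dur if max_clust is None else max(max_clust, dur)
        lag3_dev = None
        if n >= 4:
            buf = self.lag_buffer
            lag3_mean = (buf[-4] + buf[-3] + buf[-2]) / 3.0
            if lag3_mean != 0.0:
                lag3_dev = (self.last_value - lag3_mean) / lag3_mean
        return ParameterVector(
            value1=self.last_value,
            fu_days_not_at_goal=self.fu_days_not_at_goal if n >= 2 else None,
            num_not_at_goal=self.num_not_at_goal,
            abn_auc=self.abn_auc if n >= 2 else None,
            time_wt_avg=time_wt_avg,
            time_not_at_goal=time_not,
            ct_not_at_goal=ct_not,
            max_clust_days=max_clust,
            num_clust=self.num_clust,
            coeff_var=coeff_var,
            mean_val_diff=self.sum_abs_consec_diff / (n - 1) if n >= 2 else None,
            net_change=self.last_value - self.first_value,
            lag3_dev=lag3_dev,
        )


def update(summary: RunningSummary, reading: Reading, target: TargetSpec) -> RunningSummary:
    """Functional alias for :meth:`RunningSummary.update`."""
    return summary.update(reading, target)


def finalize(summary: RunningSummary, time_wt_avg_on: str = "auc") -> ParameterVector:
    """Functional alias for :meth:`RunningSummary.finalize`."""
    return summary.finalize(time_wt_avg_on=time_wt_avg_on)


def incremental_derive(series: CMSeries, target: TargetSpec,
                       time_wt_avg_on: str = "auc") -> ParameterVector:
    """Fold :func:`update` over a series and finalize (the incremental path)."""
    s = RunningSummary()
    for r in series.readings:
        s.update(r, target)
    return s.finalize(time_wt_avg_on=time_wt_avg_on)
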
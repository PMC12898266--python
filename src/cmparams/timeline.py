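"""Core data model for longitudinal clinical measurements (CMs).

A *clinical measurement* is a vital sign or laboratory analyte tracked
over a patient's record at irregular visit times: systolic/diastolic
blood pressure, oxygen saturation, body mass index, eGFR, serum albumin,
hematocrit, ALT, hemoglobin A1c, HDL and LDL cholesterol.  Everything
downstream works on a per-patient, per-CM series of (day, value) pairs
together with a treatment target that defines which values count as
abnormal.

Conventions adopted here (documented in docs/methods.md):

* values exactly equal to a target bound are **normal** -- abnormality is
  strictly outside the bound;
* time has whole-day resolution; same-day duplicate readings keep the
  last-entered value (a collision is logged);
* the record is truncated at a configurable blackout before the index
  date (default 14 days), so readings taken during a pre-symptomatic
  phase never enter the summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical CM codes, in the order they are reported.
CM_NAMES: Tuple[str, ...] = (
    "SBP", "DBP", "O2Sat", "BMI", "eGFR", "Alb", "HCT", "ALT", "A1c", "HDL", "LDL",
)


@dataclass(frozen=True)
class Reading:
    """One timestamped value of one CM for one patient.

    ``day`` counts whole days since an arbitrary per-record epoch (only
    differences between days ever matter); ``value`` is in the CM's
    native units.
    """

    day: int
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"reading value must be finite, got {self.value!r}")
        if self.day != int(self.day):
            raise ValueError(f"reading day must be a whole number, got {self.day!r}")
        object.__setattr__(self, "day", int(self.day))
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class TargetSpec:
    """Per-CM treatment target: values strictly outside the bounds are abnormal.

    At least one bound must be given.  ``low`` flags values below it
    (e.g. O2Sat < 95), ``high`` flags values above it (e.g. SBP > 140);
    a two-sided target such as hematocrit uses both.
    """

    cm_name: str
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.low is None and self.high is None:
            raise ValueError(f"target for {self.cm_name}: at least one bound required")
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(
                f"target for {self.cm_name}: low bound {self.low} must be < high bound {self.high}"
            )


class IntervalLabel(str, Enum):
    """Classification of the span between two successive readings."""

    AT_GOAL = "at_goal"
    NOT_AT_GOAL = "not_at_goal"
    WORSENING = "worsening"
    IMPROVING = "improving"


@dataclass(frozen=True)
class IntervalClass:
    label: IntervalLabel
    span_days: int


@dataclass(frozen=True)
class CMSeries:
    """An ordered series of readings of one CM for one patient.

    Construct through :meth:`from_pairs`, which sorts by day and
    resolves same-day duplicates by keeping the last-entered value.
    """

    patient_id: object
    cm_name: str
    readings: Tuple[Reading, ...] = ()

    def __post_init__(self) -> None:
        days = [r.day for r in self.readings]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"series {self.patient_id}/{self.cm_name}: readings must be strictly "
                "ascending by day; use CMSeries.from_pairs to ingest raw data"
            )

    @classmethod
    def from_pairs(
        cls, patient_id: object, cm_name: str, pairs: Iterable[Tuple[int, float]]
    ) -> "CMSeries":
        """Build a series from raw (day, value) pairs in entry order.

        Pairs are stably sorted by day; if several share a day, the
        last-entered value wins and the collision is logged.
        """
        items = [Reading(day=d, value=v) for d, v in pairs]
        items.sort(key=lambda r: r.day)  # stable: preserves entry order within a day
        dedup: dict = {}
        for r in items:
            if r.day in dedup:
                logger.warning(
                    "same-day duplicate for %s/%s on day %d: keeping last value %g",
                    patient_id, cm_name, r.day, r.value,
                )
            dedup[r.day] = r
        return cls(patient_id=patient_id, cm_name=cm_name, readings=tuple(dedup.values()))

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def days(self) -> np.ndarray:
        return np.array([r.day for r in self.readings], dtype=np.int64)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.readings], dtype=np.float64)


def is_abnormal(value: float, target: TargetSpec) -> bool:
    """True iff ``value`` lies strictly outside the target bounds."""
    if target.low is not None and value < target.low:
        return True
    if target.high is not None and value > target.high:
        return True
    return False


def classify_interval(prev: Reading, next: Reading, target: TargetSpec) -> IntervalClass:
    """Classify the span between two successive readings.

    Abnormal->abnormal spans count as not at goal, normal->normal as at
    goal, normal->abnormal as worsening and abnormal->normal as
    improving.  Worsening/improving spans belong to neither at-goal nor
    not-at-goal time.
    """
    if next.day < prev.day:
        raise ValueError("readings out of order: upstream series must be sorted")
    a, b = is_abnormal(prev.value, target), is_abnormal(next.value, target)
    if a and b:
        label = IntervalLabel.NOT_AT_GOAL
    elif not a and not b:
        label = IntervalLabel.AT_GOAL
    elif b:
        label = IntervalLabel.WORSENING
    else:
        label = IntervalLabel.IMPROVING
    return IntervalClass(label=label, span_days=next.day - prev.day)


def truncate_at_index(series: CMSeries, index_day: int, blackout_days: int = 14) -> CMSeries:
    """Drop readings within ``blackout_days`` of the index date.

    Keeps readings with ``day <= index_day - blackout_days``; the
    boundary day itself is retained.  The blackout excludes readings
    that may reflect the pre-symptomatic phase of the index illness.
    """
    cutoff = index_day - blackout_days
    kept = tuple(r for r in series.readings if r.day <= cutoff)
    return CMSeries(patient_id=series.patient_id, cm_name=series.cm_name, readings=kept)


def derive_bmi_series(heights: CMSeries, weights: CMSeries) -> CMSeries:
    """Derive BMI readings from height (m) and weight (kg) series.

    Each weight reading yields one BMI reading (weight / height**2)
    using the most recent height on or before the weight's day --
    height is quasi-static, so forward-fill is the standard convention.
    Weights with no prior height, and nonpositive heights or weights,
    are skipped with a logged warning.
    """
    hs = [(r.day, r.value) for r in heights.readings if _positive(r, heights, "height")]
    out = []
    for w in weights.readings:
        if w.value <= 0:
            logger.warning(
                "rejecting nonpositive weight %g on day %d for %s",
                w.value, w.day, weights.patient_id,
            )
            continue
        prior = [h for h in hs if h[0] <= w.day]
        if not prior:
            continue
        height = prior[-1][1]
        out.append((w.day, w.value / height**2))
    return CMSeries.from_pairs(weights.patient_id, "BMI", out)


def _positive(r: Reading, series: CMSeries, what: str) -> bool:
    if r.value <= 0:
        logger.warning(
            "rejecting nonpositive %s %g on day %d for %s",
            what, r.value, r.day, series.patient_id,
        )
        return False
    return True
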
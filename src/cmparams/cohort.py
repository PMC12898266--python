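"""Synthetic EHR cohort generator.

Emulates the longitudinal structure the parameter engine assumes, so the
whole pipeline is testable without patient data:

* per-CM latent trajectories: a patient-level baseline, a slow linear
  drift, and an alternating-renewal *relapse process* of excursions that
  push the latent value toward the abnormal side of the target for a
  random duration;
* irregular visits from an inhomogeneous Poisson process whose rate is
  multiplied while the latent value is abnormal -- the informative
  observation pattern that makes the raw mean a biased severity summary
  and motivates time-weighted averaging;
* per-CM missingness (a patient may simply never have a CM measured);
* a binary 60-day mortality outcome drawn from a logistic model on the
  patient's *derived* parameters (the engine applied to the generated
  series) plus optional covariate effects, so recovery tests are
  well-posed against the engine's own definitions.

Scales are chosen to look like an older, chronically ill primary-care
population (e.g. SBP 125 +/- 12 mmHg between patients, ~5% 60-day
mortality); docs/methods.md discusses which features of real EHR data
the generator does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DEFAULT_TARGETS, PARAMETER_NAMES
from .engine import ParameterVector, batch_derive
from .tabular import derive_table
from .timeline import CM_NAMES, CMSeries, TargetSpec


@dataclass(frozen=True)
class TrajectoryModel:
    """Latent-value model for one CM.

    ``direction`` is the abnormal side excursions push toward: +1 high,
    -1 low, 0 random per excursion (for two-sided targets).  ``clip``
    bounds keep measured values physiologic.  ``visit_rate`` overrides
    the cohort-wide base visit rate for this CM (labs are drawn less
    often than vitals).
    """

    cm_name: str
    mean: float
    between_sd: float
    slope_sd: float          # latent drift SD, units/year
    noise_sd: float          # measurement noise SD, units
    relapse_rate: float      # excursions per year
    excursion_shift: float   # mean magnitude of an excursion, units
    excursion_days: float    # mean excursion duration, days
    direction: int = 1
    clip: Tuple[float, float] = (-np.inf, np.inf)
    visit_rate: Optional[float] = None  # visits/year; None -> VisitModel.base_rate

    def __post_init__(self) -> None:
        for name in ("between_sd", "slope_sd", "noise_sd", "relapse_rate",
                     "excursion_shift", "excursion_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.cm_name}: {name} must be >= 0")


@dataclass(frozen=True)
class VisitModel:
    """Visit process: base rate, abnormality intensification, follow-up length."""

    base_rate: float = 3.0            # visits/year while the CM is normal
    abnormal_multiplier: float = 3.0  # rate multiplier while abnormal (>= 1)
    followup_years: Tuple[float, float] = (3.0, 10.0)  # uniform range

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base visit rate must be > 0")
        if self.abnormal_multiplier < 1:
            raise ValueError("abnormal multiplier must be >= 1")
        lo, hi = self.followup_years
        if not (0 < lo <= hi):
            raise ValueError("degenerate follow-up duration range")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model on derived parameters and covariates.

    The linear predictor is
    ``intercept + sum_j beta_j (x_j - ref_j) + sum_k gamma_k (z_k - ref_k)``
    with ``x_j`` the named ``<CM><Parameter>`` columns and ``z_k`` the
    baseline covariates.  A missing parameter contributes 0 (i.e. sits
    at its reference), which keeps the outcome defined for every patient
    while leaving complete-case coefficient recovery exactly specified.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    references: Mapping[str, float] = field(default_factory=dict)
    covariate_coefficients: Mapping[str, float] = field(default_factory=dict)
    covariate_references: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid_params = {f"{cm}{p}" for cm in CM_NAMES for p in PARAMETER_NAMES}
        for name in self.coefficients:
            if name not in valid_params:
                raise ValueError(f"unknown parameter name in outcome model: {name!r}")
        for name in self.covariate_coefficients:
            if name not in ("age", "charl_2yr", "charl_ever", "elix_2yr", "elix_ever"):
                raise ValueError(f"unknown covariate in outcome model: {name!r}")


#: Default latent trajectory per CM.  Population means/SDs and targets
#: correspond to the units documented in :mod:`cmparams.config`.
DEFAULT_TRAJECTORIES: Dict[str, TrajectoryModel] = {
    "SBP": TrajectoryModel("SBP", 125.0, 12.0, 1.0, 9.0, 0.5, 25.0, 120.0, 1, (70.0, 260.0), 4.0),
    "DBP": TrajectoryModel("DBP", 76.0, 8.0, 0.5, 6.0, 0.4, 15.0, 120.0, 1, (40.0, 140.0), 4.0),
    "O2Sat": TrajectoryModel("O2Sat", 97.0, 1.0, 0.15, 1.0, 0.3, 4.0, 90.0, -1, (70.0, 100.0), 4.0),
    "BMI": TrajectoryModel("BMI", 28.5, 4.5, 0.2, 0.6, 0.2, 4.0, 365.0, 1, (14.0, 60.0), 4.0),
    "eGFR": TrajectoryModel("eGFR", 80.0, 16.0, 1.5, 7.0, 0.3, 25.0, 180.0, -1, (5.0, 150.0), 2.0),
    "Alb": TrajectoryModel("Alb", 4.1, 0.3, 0.02, 0.25, 0.2, 0.8, 120.0, -1, (1.5, 5.5), 2.0),
    "HCT": TrajectoryModel("HCT", 44.0, 3.0, 0.2, 1.5, 0.25, 7.0, 120.0, 0, (20.0, 65.0), 2.0),
    "ALT": TrajectoryModel("ALT", 27.0, 9.0, 0.5, 7.0, 0.4, 25.0, 90.0, 1, (5.0, 300.0), 2.0),
    "A1c": TrajectoryModel("A1c", 6.3, 1.0, 0.08, 0.3, 0.4, 1.5, 200.0, 1, (4.0, 15.0), 2.0),
    "HDL": TrajectoryModel("HDL", 47.0, 11.0, 0.4, 4.0, 0.2, 10.0, 200.0, -1, (10.0, 120.0), 1.5),
    "LDL": TrajectoryModel("LDL", 112.0, 28.0, 1.0, 14.0, 0.3, 40.0, 200.0, 1, (20.0, 300.0), 1.5),
}


def default_outcome_model() -> OutcomeModel:
    """The shipped six-signal scenario.

    Six nonzero parameter coefficients spread over five attributes
    (current control, disease burden twice, relapse, lability, temporal
    trends); magnitudes correspond to roughly a third of a log-odds unit
    per population SD of the parameter, which at cohort scale makes each
    term individually detectable without dominating the others.  The
    intercept puts overall 60-day mortality near 5%.  Covariate effects
    are zero by default so the parameter-only main model is correctly
    specified; scenario configs may switch them on.
    """
    return OutcomeModel(
        intercept=-3.4,
        coefficients={
            "O2SatValue1": -0.20,
            "SBPTimeWtAvg": 0.035,
            "A1cNumClust": 0.22,
            "eGFRTimeWtAvg": -0.022,
            "HCTCoeffVar": 9.0,
            "LDLNetChange": 0.012,
        },
        references={
            "O2SatValue1": 96.6,
            "SBPTimeWtAvg": 129.0,
            "A1cNumClust": 2.0,
            "eGFRTimeWtAvg": 76.0,
            "HCTCoeffVar": 0.06,
            "LDLNetChange": 3.0,
        },
    )


@dataclass
class SyntheticPatient:
    """One simulated patient: covariates, per-CM series, index date, outcome."""

    patient_id: int
    age: float
    charl_2yr: int
    charl_ever: int
    elix_2yr: int
    elix_ever: int
    index_day: int
    series: Dict[str, CMSeries]
    death60: int


@dataclass
class Cohort:
    """A simulated cohort: long measurement table + patient table + truth.

    ``measurements`` has columns patient_id, cm_name, day, value and a
    generator-trace column ``latent_abnormal`` (whether the latent value
    was abnormal at the visit).  ``patients`` carries covariates,
    ``index_day``, ``death60`` and the true linear predictor
    ``true_lp``.  ``parameters`` is the derived design-matrix block the
    outcome was drawn from.  ``excursions`` is the generator's relapse
    log (patient_id, cm_name, start_day, duration_days, magnitude).
    """

    measurements: pd.DataFrame
    patients: pd.DataFrame
    parameters: pd.DataFrame
    excursions: pd.DataFrame
    targets: Mapping[str, TargetSpec]
    outcome_model: OutcomeModel
    visit_model: VisitModel
    trajectories: Mapping[str, TrajectoryModel]

    def patient(self, patient_id: int) -> SyntheticPatient:
        row = self.patients.set_index("patient_id").loc[patient_id]
        series = {}
        sub = self.measurements[self.measurements["patient_id"] == patient_id]
        for cm, block in sub.groupby("cm_name"):
            series[cm] = CMSeries.from_pairs(
                patient_id, cm, list(zip(block["day"], block["value"]))
            )
        return SyntheticPatient(
            patient_id=int(patient_id),
            age=float(row["age"]),
            charl_2yr=int(row["charl_2yr"]),
            charl_ever=int(row["charl_ever"]),
            elix_2yr=int(row["elix_2yr"]),
            elix_ever=int(row["elix_ever"]),
            index_day=int(row["index_day"]),
            series=series,
            death60=int(row["death60"]),
        )

    def iter_patients(self) -> Iterator[SyntheticPatient]:
        for pid in self.patients["patient_id"]:
            yield self.patient(pid)


def oracle_parameters(patient: SyntheticPatient,
                      targets: Mapping[str, TargetSpec] = DEFAULT_TARGETS,
                      ) -> Dict[str, ParameterVector]:
    """Ground-truth parameters for one patient, from the per-series engine.

    Deterministic; this is the independent route the vectorized cohort
    derivation is checked against in tests.
    """
    return {cm: batch_derive(s, targets[cm]) for cm, s in patient.series.items()}


def simulate_cohort(
    n_patients: int,
    trajectories: Optional[Mapping[str, TrajectoryModel]] = None,
    visit_model: Optional[VisitModel] = None,
    outcome_model: Optional[OutcomeModel] = None,
    missing_cm_prob: float = 0.05,
    seed: int = 0,
    targets: Mapping[str, TargetSpec] = DEFAULT_TARGETS,
) -> Cohort:
    """Simulate a cohort of ``n_patients`` with known outcome truth.

    Reproducible given ``seed``.  Each patient's series are sorted, span
    their follow-up and end 14 days before ``index_day``; the outcome is
    Bernoulli(logistic(lp)) with lp built from the *derived* parameters
    of the generated series.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0 <= missing_cm_prob < 1:
        raise ValueError("missing_cm_prob must be in [0, 1)")
    trajectories = dict(trajectories or DEFAULT_TRAJECTORIES)
    visit_model = visit_model or VisitModel()
    outcome_model = outcome_model or default_outcome_model()
    cms = [cm for cm in CM_NAMES if cm in trajectories]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_patients

    lo, hi = visit_model.followup_years
    followup_days = np.floor(rng.uniform(lo * 365.0, hi * 365.0, n)).astype(np.int64)
    followup_days = np.maximum(followup_days, 30)
    index_day = followup_days + 14

    age = np.clip(rng.normal(59.0, 16.0, n), 20.0, 100.0)
    charl_ever = rng.poisson(np.maximum(0.3, (age - 30.0) * 0.06))
    charl_2yr = rng.binomial(charl_ever, 0.5)
    elix_ever = rng.poisson(np.maximum(0.5, (age - 30.0) * 0.09))
    elix_2yr = rng.binomial(elix_ever, 0.5)

    meas_parts: List[pd.DataFrame] = []
    exc_parts: List[pd.DataFrame] = []
    for cm in cms:
        part, exc = _simulate_cm(rng, followup_days, trajectories[cm],
                                 visit_model, targets[cm])
        # per-CM missingness: the patient never has this CM measured
        present = rng.random(n) >= missing_cm_prob
        part = part[present[part["patient_id"].to_numpy()]]
        exc = exc[present[exc["patient_id"].to_numpy()]]
        meas_parts.append(part)
        exc_parts.append(exc)
    measurements = pd.concat(meas_parts, ignore_index=True)
    excursions = pd.concat(exc_parts, ignore_index=True)

    parameters = derive_table(measurements, targets, patient_ids=np.arange(n), cms=cms)

    lp = np.full(n, outcome_model.intercept, dtype=np.float64)
    for name, beta in outcome_model.coefficients.items():
        ref = outcome_model.references.get(name, 0.0)
        x = parameters[name].to_numpy() if name in parameters else np.full(n, np.nan)
        lp += beta * np.nan_to_num(x - ref, nan=0.0)
    covariates = {"age": age, "charl_2yr": charl_2yr, "charl_ever": charl_ever,
                  "elix_2yr": elix_2yr, "elix_ever": elix_ever}
    for name, gamma in outcome_model.covariate_coefficients.items():
        ref = outcome_model.covariate_references.get(name, 0.0)
        lp += gamma * (covariates[name] - ref)
    death60 = rng.binomial(1, expit(lp))

    patients = pd.DataFrame({
        "patient_id": np.arange(n),
        "age": age,
        "charl_2yr": charl_2yr,
        "charl_ever": charl_ever,
        "elix_2yr": elix_2yr,
        "elix_ever": elix_ever,
        "index_day": index_day,
        "death60": death60,
        "true_lp": lp,
    })
    return Cohort(
        measurements=measurements,
        patients=patients,
        parameters=parameters,
        excursions=excursions,
        targets=targets,
        outcome_model=outcome_model,
        visit_model=visit_model,
        trajectories=trajectories,
    )


def _simulate_cm(
    rng: np.random.Generator,
    followup_days: np.ndarray,
    traj: TrajectoryModel,
    visit: VisitModel,
    target: TargetSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one CM for all patients (vectorized); returns (visits, excursions)."""
    n = len(followup_days)
    T = followup_days.astype(np.float64)
    years = T / 365.0
    baseline = rng.normal(traj.mean, traj.between_sd, n)
    slope = rng.normal(0.0, traj.slope_sd, n)

    # alternating-renewal excursion windows (non-overlapping by construction)
    if traj.relapse_rate > 0:
        mean_gap = 365.0 / traj.relapse_rate
        expected = T.max() / (mean_gap + traj.excursion_days)
        kmax = max(3, int(np.ceil(4 + 3 * expected)))
        gaps = rng.exponential(mean_gap, (n, kmax))
        durs = rng.exponential(traj.excursion_days, (n, kmax))
        mags = rng.gamma(2.0, traj.excursion_shift / 2.0, (n, kmax))
        if traj.direction == 0:
            signs = rng.choice([-1.0, 1.0], (n, kmax))
        else:
            signs = np.full((n, kmax), float(traj.direction))
        starts = np.cumsum(gaps, axis=1)
        starts[:, 1:] += np.cumsum(durs, axis=1)[:, :-1]
        live = starts < T[:, None]
        e_pid = np.repeat(np.arange(n), live.sum(axis=1))
        e_start = starts[live]
        e_dur = durs[live]
        e_shift = (mags * signs)[live]
    else:
        e_pid = np.empty(0, dtype=np.int64)
        e_start = e_dur = e_shift = np.empty(0)

    rate = traj.visit_rate if traj.visit_rate is not None else visit.base_rate
    mult = visit.abnormal_multiplier
    lam = rate * mult * years
    n_cand = rng.poisson(lam)
    pid = np.repeat(np.arange(n), n_cand)
    dayf = rng.uniform(0.0, T[pid])
    u_thin = rng.random(len(pid))
    noise = rng.normal(0.0, traj.noise_sd, len(pid))

    # active excursion lookup via keyed searchsorted (windows sorted per patient)
    key_base = T.max() + 2.0
    latent = baseline[pid] + slope[pid] * dayf / 365.0
    if len(e_pid):
        e_key = e_pid * key_base + e_start
        v_key = pid * key_base + dayf
        j = np.searchsorted(e_key, v_key, side="right") - 1
        jc = np.clip(j, 0, None)
        active = (j >= 0) & (e_pid[jc] == pid) & (dayf <= e_start[jc] + e_dur[jc])
        latent = latent + np.where(active, e_shift[jc], 0.0)

    abn = np.zeros(len(pid), dtype=bool)
    if target.low is not None:
        abn |= latent < target.low
    if target.high is not None:
        abn |= latent > target.high
    accept = abn | (u_thin < 1.0 / mult)

    value = np.clip(latent + noise, traj.clip[0], traj.clip[1])
    visits = pd.DataFrame({
        "patient_id": pid[accept],
        "cm_name": traj.cm_name,
        "day": np.floor(dayf[accept]).astype(np.int64),
        "value": value[accept],
        "latent_abnormal": abn[accept],
    })
    excursions = pd.DataFrame({
        "patient_id": e_pid,
        "cm_name": traj.cm_name,
        "start_day": e_start,
        "duration_days": e_dur,
        "magnitude": e_shift,
    })
    return visits, excursions
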
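"""Synthetic cohort generator: determinism, visit intensification, outcome link."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from cmparams import (
    CM_NAMES,
    DEFAULT_TARGETS,
    DEFAULT_TRAJECTORIES,
    OutcomeModel,
    TrajectoryModel,
    VisitModel,
    batch_derive,
    oracle_parameters,
    simulate_cohort,
)
from cmparams.engine import ParameterVector


def _flat_sbp(baseline: float, noise: float = 0.0, relapse: float = 0.0,
              shift: float = 50.0) -> dict:
    """One-CM scenario with a constant latent trajectory at ``baseline``."""
    return {"SBP": TrajectoryModel("SBP", baseline, 0.0, 0.0, noise, relapse,
                                   shift, 120.0, 1, (0.0, 500.0), 4.0)}


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        a = simulate_cohort(100, seed=7)
        b = simulate_cohort(100, seed=7)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.parameters, b.parameters)

    def test_different_seed_differs(self):
        a = simulate_cohort(50, seed=1)
        b = simulate_cohort(50, seed=2)
        assert not a.measurements.equals(b.measurements)


class TestValidation:
    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, seed=1)
        with pytest.raises(ValueError):
            simulate_cohort(10, missing_cm_prob=1.0, seed=1)

    def test_degenerate_followup_rejected(self):
        with pytest.raises(ValueError):
            VisitModel(followup_years=(0.0, 0.0))
        with pytest.raises(ValueError):
            VisitModel(base_rate=0.0)

    def test_unknown_outcome_names_rejected(self):
        with pytest.raises(ValueError):
            OutcomeModel(intercept=0.0, coefficients={"SBPBogus": 1.0})
        with pytest.raises(ValueError):
            OutcomeModel(intercept=0.0, covariate_coefficients={"height": 1.0})


class TestOutcomeLink:
    def test_null_model_death_rate_matches_intercept(self):
        """With all coefficients zero the 60-day death rate is forced by the link."""
        om = OutcomeModel(intercept=float(logit(0.05)))
        c = simulate_cohort(20000, outcome_model=om, seed=11)
        rate = c.patients["death60"].mean()
        # binomial 4-sigma band around 0.05 at n=20,000
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 20000)

    def test_series_end_before_index(self):
        c = simulate_cohort(200, seed=3)
        last = c.measurements.groupby("patient_id")["day"].max()
        idx = c.patients.set_index("patient_id")["index_day"]
        assert (idx.loc[last.index] - last >= 14).all()


class TestVisitIntensification:
    def test_abnormal_latent_triples_visit_rate(self):
        """A latent value pinned on the abnormal side yields ~multiplier times
        the base visit rate of a latent value pinned on the normal side."""
        vm = VisitModel(base_rate=4.0, abnormal_multiplier=3.0, followup_years=(6.0, 6.0))
        abn = simulate_cohort(400, trajectories=_flat_sbp(170.0), visit_model=vm,
                              missing_cm_prob=0.0, seed=5)
        nrm = simulate_cohort(400, trajectories=_flat_sbp(120.0), visit_model=vm,
                              missing_cm_prob=0.0, seed=5)
        per_year_abn = len(abn.measurements) / 400 / 6.0
        per_year_nrm = len(nrm.measurements) / 400 / 6.0
        assert per_year_nrm == pytest.approx(4.0, rel=0.1)
        assert per_year_abn / per_year_nrm == pytest.approx(3.0, rel=0.1)

    def test_latent_abnormal_trace_is_recorded(self):
        c = simulate_cohort(100, seed=9)
        assert set(c.measurements["latent_abnormal"].unique()) <= {True, False}


class TestOracleParameters:
    def test_matches_vectorized_table_and_invariants(self):
        c = simulate_cohort(30, seed=21)
        for patient in c.iter_patients():
            oracle = oracle_parameters(patient, c.targets)
            for cm, pv in oracle.items():
                row = c.parameters.loc[patient.patient_id]
                for name, val in pv.as_dict().items():
                    got = row[f"{cm}{name}"]
                    if val is None:
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(val, rel=1e-9, abs=1e-12)

    def test_no_excursions_no_relapses(self):
        c = simulate_cohort(150, trajectories=_flat_sbp(120.0, noise=0.0),
                            missing_cm_prob=0.0, seed=2)
        assert (c.parameters["SBPNumClust"].dropna() == 0).all()

    def test_num_clust_bounded_by_excursion_log(self):
        """Noise-free, normal-baseline patients relapse only inside generated
        excursion windows, so cluster counts never exceed the excursion log."""
        c = simulate_cohort(
            150, trajectories=_flat_sbp(120.0, noise=0.0, relapse=0.8, shift=60.0),
            missing_cm_prob=0.0, seed=13,
        )
        n_exc = c.excursions.groupby("patient_id").size()
        for pid, row in c.parameters.iterrows():
            if not np.isnan(row["SBPNumClust"]):
                assert row["SBPNumClust"] <= n_exc.get(pid, 0)


class TestMissingness:
    def test_fraction_of_patients_with_any_absent_cm(self):
        p_miss = 0.10
        c = simulate_cohort(4000, missing_cm_prob=p_miss, seed=31)
        present = c.measurements.groupby("patient_id")["cm_name"].nunique()
        present = present.reindex(c.patients["patient_id"], fill_value=0)
        frac_any_missing = (present < len(CM_NAMES)).mean()
        expect = 1 - (1 - p_miss) ** len(CM_NAMES)
        assert frac_any_missing == pytest.approx(expect, abs=0.03)


class TestOversamplingBias:
    def test_raw_mean_biased_toward_abnormal_side(self):
        """With abnormal-state oversampling of a high-side CM, the raw
        per-patient mean typically exceeds the time-weighted average."""
        c = simulate_cohort(1500, seed=41)
        sbp = c.measurements[c.measurements["cm_name"] == "SBP"]
        raw_mean = sbp.groupby("patient_id")["value"].mean()
        twa = c.parameters["SBPTimeWtAvg"].dropna()
        common = raw_mean.index.intersection(twa.index)
        diffs = raw_mean.loc[common] - twa.loc[common]
        assert np.median(diffs) > 0
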
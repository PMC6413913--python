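"""Simulator contracts: protocol schedule, planted structure, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeropower import (
    GenerativeSpec,
    ProtocolSpec,
    simulate_cohort,
    simulate_cpet,
    simulate_wingate,
)
from aeropower.errors import (
    CohortTooSmallError,
    DataValidationError,
    InvalidProtocolError,
    InvalidShapeError,
)
from aeropower.profiles import WingateShape
from aeropower.simulate import CpetModel, make_planted_regression


NOISELESS = CpetModel(noise_vo2=0.0, noise_vco2=0.0, noise_ve=0.0,
                      noise_rf=0.0, noise_hr=0.0)


class TestCpet:
    def test_noiseless_vo2_nondecreasing(self, noiseless_recording):
        vo2 = noiseless_recording.breaths["vo2_ml_min"].to_numpy()
        assert (np.diff(vo2) >= -1e-9).all()

    def test_breath_times_strictly_increasing(self, recording):
        t = recording.breaths["t_s"].to_numpy()
        assert (np.diff(t) > 0).all()

    def test_speed_schedule_increments_one_kmh_per_minute(self, subject):
        rec = simulate_cpet(subject, ProtocolSpec(), seed=5)
        b = rec.breaths[rec.breaths["t_s"] >= rec.warmup_s]
        tt = b["t_s"].to_numpy() - rec.warmup_s
        expected = 7.0 + np.floor(tt / 60.0)
        assert np.array_equal(b["speed_kmh"].to_numpy(), expected)

    def test_noiseless_rer_crosses_trigger_once(self, noiseless_recording):
        b = noiseless_recording.breaths
        rer = (b["vco2_ml_min"] / b["vo2_ml_min"]).to_numpy()
        crossings = np.diff((rer >= 1.0).astype(int))
        assert (crossings == 1).sum() == 1
        assert (crossings == -1).sum() == 0

    def test_terminates_when_modeled_hr_reaches_max(self, noiseless_recording, subject):
        hr = noiseless_recording.breaths["hr_bpm"].to_numpy()
        assert hr[-1] >= subject.hr_max - 1e-6
        assert (hr[:-1] < subject.hr_max).all()

    def test_vo2_approaches_vo2max(self, noiseless_recording, subject):
        vo2 = noiseless_recording.breaths["vo2_ml_min"].to_numpy()
        assert vo2[-1] == pytest.approx(subject.vo2max_true, rel=1e-6)

    def test_grade_increases_after_rer_trigger(self, noiseless_recording):
        b = noiseless_recording.breaths
        rer = b["vco2_ml_min"] / b["vo2_ml_min"]
        pre = b[rer.cummax() < 1.0]
        post = b[rer.cummax() >= 1.0]
        assert (pre["grade_pct"] == 0).all()
        # grade responds from the breath after the trigger latches
        assert (post["grade_pct"].iloc[1:] >= 2.0).all()
        assert (post["grade_pct"].diff().dropna() >= 0).all()

    def test_invalid_protocol_rejected(self):
        with pytest.raises(InvalidProtocolError):
            ProtocolSpec(speed_increment=0.0)
        with pytest.raises(InvalidProtocolError):
            ProtocolSpec(grade_increment_pct=-1.0)

    def test_same_seed_bit_identical_different_seed_differs(self, subject):
        a = simulate_cpet(subject, seed=9)
        b = simulate_cpet(subject, seed=9)
        c = simulate_cpet(subject, seed=10)
        assert a.breaths.equals(b.breaths)
        assert not a.breaths.equals(c.breaths)


class TestWingate:
    def test_flat_curve(self, subject):
        w = simulate_wingate(subject, WingateShape(peak_w=500, end_w=500))
        assert (w.pp, w.mp, w.fatigue) == (500.0, 500.0, 0.0)

    def test_linear_decay_closed_form(self, subject):
        # mean of a linear 800->400 ramp is 600 W; fatigue (800-400)/800 = 50%
        w = simulate_wingate(subject, WingateShape(peak_w=800, end_w=400))
        assert w.pp == pytest.approx(800.0)
        assert w.mp == pytest.approx(600.0)
        assert w.fatigue == pytest.approx(50.0)

    def test_resistance_convention(self, subject):
        w = simulate_wingate(subject, WingateShape(peak_w=700, end_w=350))
        assert w.resistance == 0.075

    def test_curve_spans_30s_and_pp_ge_mp(self, subject):
        w = simulate_wingate(subject, WingateShape(peak_w=900, end_w=500, mid_w=650))
        assert w.power_curve[-1, 0] - w.power_curve[0, 0] == pytest.approx(30.0)
        assert w.pp >= w.mp

    def test_invalid_shapes_rejected(self):
        with pytest.raises(InvalidShapeError):
            WingateShape(peak_w=0.0, end_w=0.0)
        with pytest.raises(InvalidShapeError):
            WingateShape(peak_w=500.0, end_w=600.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           peak=st.floats(min_value=200.0, max_value=1000.0),
           frac=st.floats(min_value=0.2, max_value=1.0))
    def test_fatigue_invariant_to_uniform_scaling(self, subject, scale, peak, frac):
        w1 = simulate_wingate(subject, WingateShape(peak_w=peak, end_w=frac * peak))
        w2 = simulate_wingate(subject, WingateShape(peak_w=scale * peak,
                                                    end_w=scale * frac * peak))
        assert w1.fatigue == pytest.approx(w2.fatigue, abs=1e-9)


class TestCohort:
    def test_reference_sex_mix(self):
        cohort = simulate_cohort(88, seed=1)
        sexes = [p.sex for p in cohort.profiles]
        assert len(sexes) == 88
        assert sexes.count("female") == 36
        assert sexes.count("male") == 52

    def test_too_small_cohort_rejected(self):
        with pytest.raises(CohortTooSmallError):
            simulate_cohort(9, seed=0)

    def test_noiseless_outcome_equals_linear_combination(self):
        gen = GenerativeSpec(
            signal_features=["max VE", "max VO2"],
            coefficients=[100.0, 50.0],
            intercept=600.0,
            noise_sd=0.0,
        )
        cohort = simulate_cohort(12, gen={"pp_w": gen}, seed=3)
        Z = cohort.features_z[["max VE", "max VO2"]].to_numpy()
        expected = 600.0 + Z @ np.array([100.0, 50.0])
        assert np.allclose(cohort.outcomes["pp_w"].to_numpy(), expected, atol=1e-9)

    def test_ols_on_true_design_recovers_coefficients(self):
        # noise set to 5% of the noiseless outcome SD
        gen0 = GenerativeSpec(
            signal_features=["max VE", "max VO2", "max RF"],
            coefficients=[120.0, -60.0, 30.0],
            intercept=640.0,
            noise_sd=0.0,
        )
        cohort = simulate_cohort(200, gen={"pp_w": gen0}, seed=17)
        sd = cohort.outcomes["pp_w"].to_numpy().std(ddof=1)
        gen = GenerativeSpec(
            signal_features=["max VE", "max VO2", "max RF"],
            coefficients=[120.0, -60.0, 30.0],
            intercept=640.0,
            noise_sd=0.05 * sd,
        )
        cohort = simulate_cohort(200, gen={"pp_w": gen}, seed=17)
        Z = cohort.features_z[gen.signal_features].to_numpy()
        D = np.column_stack([np.ones(len(Z)), Z])
        beta, *_ = np.linalg.lstsq(D, cohort.outcomes["pp_w"].to_numpy(), rcond=None)
        assert beta[0] == pytest.approx(640.0, rel=0.10)
        for est, true in zip(beta[1:], [120.0, -60.0, 30.0]):
            assert est == pytest.approx(true, rel=0.10)

    def test_same_seed_bit_identical(self):
        a = simulate_cohort(12, seed=5)
        b = simulate_cohort(12, seed=5)
        assert a.features.equals(b.features)
        assert a.outcomes.equals(b.outcomes)

    def test_truth_records_resolved_noise(self):
        cohort = simulate_cohort(20, seed=2)
        for outcome, truth in cohort.truth.items():
            assert truth["noise_sd"] >= 0
            assert len(truth["signal_features"]) == len(truth["coefficients"])

    def test_unknown_signal_feature_rejected(self):
        gen = GenerativeSpec(signal_features=["no such feature"],
                             coefficients=[1.0], intercept=0.0, noise_sd=0.0)
        with pytest.raises(DataValidationError):
            simulate_cohort(12, gen={"pp_w": gen}, seed=0)


class TestPlantedRegression:
    def test_snr_controls_noise(self):
        X, y, truth = make_planted_regression(500, 6, {"f2": 1.0}, snr=10, seed=1)
        resid_sd = truth["noise_sd"]
        signal_var = np.var(X["f2"].to_numpy())
        assert resid_sd == pytest.approx(np.sqrt(signal_var / 10), rel=0.05)

    def test_noiseless_is_exact(self):
        X, y, truth = make_planted_regression(50, 5, {"f1": 2.0, "f3": -1.0},
                                              noise_sd=0.0, seed=2)
        assert np.allclose(y, 2.0 * X["f1"] - 1.0 * X["f3"], atol=1e-12)
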
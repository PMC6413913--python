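"""Greedy selection, stability voting, consensus fitting, and evaluation."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.base import clone

from aeropower import (
    GreedyStabilityRegressor,
    PredictorEquation,
    adjusted_r2,
    evaluate,
    fit_consensus,
    greedy_select,
    make_planted_regression,
    reference_equations,
    stability_select,
    split_stratified,
)
from aeropower.errors import (
    MissingFeatureError,
    RankDeficiencyError,
    SchemaError,
    UndefinedAdjustmentError,
)
from aeropower.selection import SplitSpec, _spearman


class TestSplit:
    def test_n10_sizes_and_partition(self):
        tr, te, va = split_stratified(10, None, SplitSpec(seed=1))
        assert (len(tr), len(te), len(va)) == (4, 3, 3)
        union = np.concatenate([tr, te, va])
        assert sorted(union.tolist()) == list(range(10))

    def test_default_train_fraction(self):
        tr, te, va = split_stratified(100, None, SplitSpec(seed=3))
        assert len(tr) == 40 and len(te) == 30 and len(va) == 30

    def test_tertile_allocation_is_balanced(self):
        strat = np.repeat([1.0, 2.0, 3.0], 10)
        tr, te, va = split_stratified(30, strat, SplitSpec(seed=2))
        for group, size in ((tr, 4), (te, 3), (va, 3)):
            counts = [int((strat[group] == v).sum()) for v in (1.0, 2.0, 3.0)]
            assert counts == [size, size, size]

    def test_within_stratum_deviation_at_most_one(self):
        rng = np.random.default_rng(8)
        strat = rng.normal(size=40)
        tr, te, va = split_stratified(40, strat, SplitSpec(seed=8))
        qs = np.quantile(strat, [1 / 3, 2 / 3])
        bins = np.searchsorted(qs, strat)
        for s in range(3):
            members = np.nonzero(bins == s)[0]
            for group, frac in ((tr, 0.4), (te, 0.3), (va, 0.3)):
                got = len(np.intersect1d(group, members))
                assert abs(got - frac * len(members)) <= 1.0 + 1e-9


class TestAdjustedR2:
    def test_worked_example(self):
        assert adjusted_r2(0.9, 35, 3) == pytest.approx(0.89032, abs=5e-6)

    def test_perfect_fit_unaffected(self):
        assert adjusted_r2(1.0, 20, 5) == 1.0

    def test_null_model(self):
        assert adjusted_r2(0.0, 12, 0) == 0.0

    def test_undefined_for_saturated_model(self):
        with pytest.raises(UndefinedAdjustmentError):
            adjusted_r2(0.5, 5, 4)


class TestGreedy:
    def test_perfect_single_predictor_selected_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 9)),
                         columns=[f"f{i+1}" for i in range(9)])
        y = X["f7"].to_numpy().copy()
        run, eq = greedy_select(X, y)
        assert run.features[0] == "f7"
        assert run.train_sse_path[0] == pytest.approx(0.0, abs=1e-9)
        assert run.stop_reason == "perfect_fit"

    def test_planted_pair_beats_nuisance_and_matches_best_subset(self):
        X, y, _ = make_planted_regression(
            80, 10, {"f1": 2.0, "f4": -1.5}, noise_sd=0.05, seed=99)
        run, _ = greedy_select(X, y, max_features=2)
        assert set(run.features) == {"f1", "f4"}
        # independent oracle: exhaustive best subset of size 2
        def sse(cols):
            D = np.column_stack([np.ones(len(y)), X.iloc[:, list(cols)]])
            return float(np.linalg.lstsq(D, y, rcond=None)[1][0])
        best = min(itertools.combinations(range(10), 2), key=sse)
        assert {X.columns[i] for i in best} == set(run.features)

    def test_stop_on_adjusted_r2_drop_keeps_pre_drop_model(self, rng):
        # two informative features; remaining candidates are pure noise with a
        # tiny n so the adjustment penalty forces a >2% relative drop
        n = 12
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{i+1}" for i in range(6)])
        y = 2.0 * X["f1"].to_numpy() - 1.0 * X["f2"].to_numpy() \
            + 0.45 * rng.normal(size=n)
        run, eq = greedy_select(X, y)
        if run.stop_reason == "adjusted_r2_drop":
            k = len(run.features)
            assert len(eq.terms) == k
            # the drop criterion compares the would-be next step with the kept one
            assert run.adjusted_r2_path[-1] > 0

    def test_constructed_drop_arithmetic(self):
        # 0.85 < 0.98 * 0.90, so a step from adj 0.90 to 0.85 must stop
        assert 0.85 < 0.98 * 0.90

    def test_monotone_train_sse(self, cohort20):
        y = cohort20.outcomes["pp_w"].to_numpy()
        run, _ = greedy_select(cohort20.features_z, y, max_features=10)
        assert all(b <= a + 1e-9 for a, b in
                   zip(run.train_sse_path, run.train_sse_path[1:]))

    def test_coefficients_match_sklearn(self, cohort20):
        y = cohort20.outcomes["pp_w"].to_numpy()
        run, eq = greedy_select(cohort20.features_z, y, max_features=5)
        lr = LinearRegression().fit(cohort20.features_z[run.features], y)
        assert np.allclose(lr.coef_, eq.coefficients, atol=1e-8)
        assert lr.intercept_ == pytest.approx(eq.intercept, abs=1e-8)

    def test_duplicate_column_skipped_as_collinear(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["f1", "f2", "f3"])
        X["f3"] = X["f1"]  # exact duplicate
        y = X["f1"].to_numpy() + 0.1 * rng.normal(size=30)
        run, _ = greedy_select(X, y, max_features=3)
        assert "f3" not in run.features or "f1" not in run.features

    def test_never_selects_a_feature_twice(self, cohort20):
        y = cohort20.outcomes["mp_w"].to_numpy()
        run, _ = greedy_select(cohort20.features_z, y)
        assert len(run.features) == len(set(run.features))


class TestStability:
    def test_noiseless_single_signal_frequency_one(self):
        X, y, _ = make_planted_regression(40, 6, {"f3": 1.5}, noise_sd=0.0, seed=4)
        res = stability_select(X, y, n_runs=25, seed=0, strata=1)
        assert res.frequencies["f3"] == 1.0
        assert res.consensus[0] == "f3"

    def test_true_features_outrank_correlated_nuisance(self):
        # f1, f2 carry the signal; f3 is correlated with them through the
        # exchangeable design (rho = 0.6) but carries no coefficient
        X, y, _ = make_planted_regression(
            120, 8, {"f1": 1.0, "f2": -1.0}, rho=0.6, snr=20, seed=21)
        res = stability_select(X, y, n_runs=50, seed=1, strata=1,
                               max_features=4)
        f = res.frequencies
        assert f["f1"] > f["f3"] and f["f2"] > f["f3"]

    def test_default_run_count_is_1000(self):
        import inspect

        sig = inspect.signature(stability_select)
        assert sig.parameters["n_runs"].default == 1000


class TestConsensusFit:
    def test_identity_feature(self, rng):
        y = rng.normal(size=30)
        X = pd.DataFrame({"f1": y})
        eq = fit_consensus(X, y, ["f1"])
        assert eq.intercept == pytest.approx(0.0, abs=1e-10)
        assert eq.terms[0][1] == pytest.approx(1.0, abs=1e-10)

    def test_intercept_equals_outcome_mean_for_centered_regressors(self, cohort20):
        y = cohort20.outcomes["pp_w"].to_numpy()
        eq = fit_consensus(cohort20.features_z, y, ["max VE", "max VO2"])
        assert eq.intercept == pytest.approx(float(y.mean()), abs=1e-8)

    def test_noiseless_coefficients_recovered_exactly(self):
        X, y, truth = make_planted_regression(
            60, 8, {"f2": 1.25, "f6": -3.0}, noise_sd=0.0, seed=6)
        eq = fit_consensus(X, y, ["f2", "f6"])
        coefs = dict(eq.terms)
        assert coefs["f2"] == pytest.approx(1.25, abs=1e-8)
        assert coefs["f6"] == pytest.approx(-3.0, abs=1e-8)

    def test_rank_deficiency_names_offender(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["f1", "f2"])
        X["dup"] = X["f1"]
        with pytest.raises(RankDeficiencyError) as err:
            fit_consensus(X, rng.normal(size=20), ["f1", "f2", "dup"])
        assert "dup" in err.value.features


class TestEquation:
    def test_reference_pp_equation_loads_with_6_terms(self):
        eq = reference_equations()["pp_w"]
        assert len(eq.terms) == 6
        assert eq.predict({f: 0.0 for f in eq.features})[0] == pytest.approx(638.4)

    def test_reference_mp_equation_loads_with_4_terms(self):
        eq = reference_equations()["mp_w"]
        assert len(eq.terms) == 4
        assert eq.predict({f: 0.0 for f in eq.features})[0] == pytest.approx(476.8)

    def test_pp_equation_unit_max_ve(self):
        eq = reference_equations()["pp_w"]
        vec = {f: 0.0 for f in eq.features}
        vec["max VE"] = 1.0
        assert eq.predict(vec)[0] == pytest.approx(638.4 + 170.3)

    def test_missing_feature_raises_named_error(self):
        eq = reference_equations()["pp_w"]
        with pytest.raises(MissingFeatureError) as err:
            eq.predict({"max VE": 0.0})
        assert "max RF" in err.value.features

    def test_json_round_trip_bit_exact(self):
        eq = PredictorEquation(
            outcome="mp_w", intercept=1.2345678901234567,
            terms=[("max VE", 0.1), ("max VO2", -2.5e-3)],
            scaler={"max VE": {"mean": 1.0, "sd": 2.0},
                    "max VO2": {"mean": 3.0, "sd": 4.0}},
        )
        back = PredictorEquation.from_json(eq.to_json())
        assert back.intercept == eq.intercept
        assert back.terms == eq.terms
        assert back.scaler == eq.scaler

    def test_unknown_outcome_tag_rejected(self):
        with pytest.raises(SchemaError):
            PredictorEquation(outcome="vo2max", intercept=0.0, terms=[])


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.spearman_r, m.rmse, m.pct_err_mean) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        m = evaluate([100, 200, 300], [110, 190, 330])
        assert m.rmse == pytest.approx(19.1485, abs=5e-5)
        assert m.pct_err_mean == pytest.approx(8.3333, abs=5e-5)
        assert m.spearman_r == pytest.approx(1.0)

    def test_reverse_ranked(self):
        m = evaluate([1, 2, 3, 4], [8, 6, 4, 2])
        assert m.spearman_r == pytest.approx(-1.0)

    def test_constant_predictions_flagged(self):
        m = evaluate([1, 2, 3], [5, 5, 5])
        assert not m.spearman_defined
        assert np.isnan(m.spearman_r)

    def test_spearman_ties_use_average_ranks(self):
        from scipy.stats import spearmanr

        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 5.0])
        assert _spearman(a, b) == pytest.approx(spearmanr(a, b).statistic)


class TestEstimator:
    def test_sklearn_contract(self):
        est = GreedyStabilityRegressor(n_runs=5, random_state=0)
        params = est.get_params()
        assert params["n_runs"] == 5
        clone(est)  # must be cloneable from params alone

    def test_fit_predict_on_planted_signal(self):
        X, y, _ = make_planted_regression(80, 6, {"f2": 2.0}, noise_sd=0.0, seed=3)
        est = GreedyStabilityRegressor(n_runs=10, random_state=0, stratify_on=None)
        est.fit(X, y)
        assert est.selected_features_ == ["f2"]
        assert np.allclose(est.predict(X), y, atol=1e-8)
        assert est.score(X, y) == pytest.approx(1.0)

    def test_equation_carries_scaler_for_raw_features(self, cohort20):
        y = cohort20.outcomes["pp_w"].to_numpy()
        est = GreedyStabilityRegressor(n_runs=8, random_state=1, max_features=4)
        est.fit(cohort20.features, y)
        assert set(est.equation_.scaler) == set(est.selected_features_)
        pred = est.predict(cohort20.features)
        assert np.isfinite(pred).all()
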
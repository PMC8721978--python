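"""OLS fitting, backward elimination, splitting and prediction."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import aquajump as aj
from aquajump.regression import SingularDesignError


def _reference_records(seed, noise_sd=0.07, n_subjects=12):
    return aj.generate_regression_records(n_subjects=n_subjects, seed=seed, noise_sd=noise_sd)


class TestFitLinearModel:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        model = aj.fit_linear_model(2 + 3 * x, pd.DataFrame({"x": x}))
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.coefficients["x"] == pytest.approx(3.0, abs=1e-10)
        assert model.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        design = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        model = aj.fit_linear_model(y, X)
        np.testing.assert_allclose(
            [model.intercept] + [model.coefficients[c] for c in "abc"], beta, atol=1e-8
        )

    def test_adjusted_r2_definition(self, rng):
        n, p = 50, 2
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(0, 1, n)
        model = aj.fit_linear_model(y, X)
        resid = y - (model.intercept + X.to_numpy() @ np.array([model.coefficients["a"], model.coefficients["b"]]))
        r2 = 1 - resid.var() / y.var()
        adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
        assert model.adjusted_r2 == pytest.approx(adj, abs=1e-10)

    def test_constant_predictor_rejected_by_name(self, rng):
        X = pd.DataFrame({"ok": rng.normal(size=20), "flat": np.ones(20)})
        with pytest.raises(SingularDesignError, match="flat"):
            aj.fit_linear_model(rng.normal(size=20), X)

    def test_collinear_design_rejected(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(SingularDesignError, match="rank deficient"):
            aj.fit_linear_model(rng.normal(size=30), X)

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]})
        with pytest.raises(ValueError, match="observations"):
            aj.fit_linear_model(np.array([1.0, 2.0]), X)


class TestBackwardElimination:
    def test_strong_predictors_all_retained(self):
        X, y = _xy(_reference_records(seed=0))
        model = aj.backward_eliminate(y, X)
        assert "c7acc" in model.coefficients
        assert model.elimination_trail == [] or set(model.elimination_trail) <= {"weight", "age"}

    def test_noiseless_reference_data_recovers_equation_exactly(self):
        records = _reference_records(seed=1, noise_sd=0.0)
        X, y = _xy(records)
        model = aj.backward_eliminate(y, X)
        assert set(model.coefficients) == {"c7acc", "pwdh", "age", "weight"}
        assert model.intercept == pytest.approx(-1.712, abs=1e-8)
        for name, ref in aj.REFERENCE_EQUATION.coefficients.items():
            assert model.coefficients[name] == pytest.approx(ref, abs=1e-8)

    def test_coefficient_recovery_within_three_se(self):
        X, y = _xy(_reference_records(seed=2))
        est = aj.BackwardEliminationRegression().fit(X, y)
        assert "c7acc" in est.retained_
        i = list(est.feature_names_in_).index("c7acc")
        assert abs(est.coef_[i] - 0.658) < 3 * est.bse_["c7acc"]

    def test_pure_noise_predictor_usually_removed(self):
        removed = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            records = _reference_records(seed=1000 + seed)
            X, y = _xy(records)
            X = X.assign(noise=rng.normal(size=len(X)))
            model = aj.backward_eliminate(y, X)
            removed += "noise" not in model.coefficients
        # null retention probability is alpha_remove = 0.10
        assert removed / n_seeds > 0.7

    def test_exact_p_tie_removes_later_column(self):
        from aquajump.regression import select_removal_candidate

        pvals = pd.Series({"first": 0.4, "second": 0.4, "third": 0.1})
        assert select_removal_candidate(pvals, ["first", "second", "third"]) == "second"
        # without a tie the unique maximum loses regardless of position
        pvals = pd.Series({"first": 0.4, "second": 0.3})
        assert select_removal_candidate(pvals, ["first", "second"]) == "first"

    def test_all_predictors_removed_leaves_intercept_only_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        # project the noise onto the orthogonal complement of the design so
        # both slopes are numerically zero and their p-values ~1
        design = np.column_stack([np.ones(40), X.to_numpy()])
        e = rng.normal(0, 1e-3, 40)
        y = 2.5 + e - design @ np.linalg.lstsq(design, e, rcond=None)[0]
        with pytest.warns(UserWarning, match="all predictors eliminated"):
            model = aj.backward_eliminate(y, X)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(2.5, abs=0.01)
        assert set(model.elimination_trail) == {"a", "b"}

    def test_final_model_invariant_to_column_order(self):
        records = _reference_records(seed=3)
        X, y = _xy(records)
        m1 = aj.backward_eliminate(y, X)
        m2 = aj.backward_eliminate(y, X[list(reversed(X.columns))])
        assert set(m1.coefficients) == set(m2.coefficients)
        for k in m1.coefficients:
            assert m1.coefficients[k] == pytest.approx(m2.coefficients[k], rel=1e-10)


class TestEstimatorApi:
    def test_sklearn_clone_and_params_roundtrip(self):
        est = aj.BackwardEliminationRegression(alpha_remove=0.05)
        cloned = clone(est)
        assert cloned.get_params() == {"alpha_remove": 0.05, "eliminate": True}
        cloned.set_params(alpha_remove=0.2)
        assert cloned.alpha_remove == 0.2

    def test_predict_matches_manual_linear_combination(self):
        X, y = _xy(_reference_records(seed=4))
        est = aj.BackwardEliminationRegression().fit(X, y)
        manual = est.intercept_ + X.to_numpy() @ est.coef_
        np.testing.assert_allclose(est.predict(X), manual, atol=1e-12)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            aj.BackwardEliminationRegression().predict(pd.DataFrame({"a": [1.0]}))


class TestSplit:
    def test_floor_rule_sizes_at_study_scale(self, rng):
        records = pd.DataFrame({"v": rng.normal(size=1579)})
        split = aj.split_dd_vd(records, seed=0)
        assert (len(split.dd), len(split.vd)) == (1052, 527)

    def test_three_records_floor_rule(self):
        split = aj.split_dd_vd(pd.DataFrame({"v": [1.0, 2.0, 3.0]}), seed=0)
        assert len(split.dd) == 2

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        records = pd.DataFrame({"v": np.arange(101.0)})
        split = aj.split_dd_vd(records, seed=5)
        combined = sorted(split.dd.v.tolist() + split.vd.v.tolist())
        assert combined == records.v.tolist()

    def test_deterministic_under_seed(self, rng):
        records = pd.DataFrame({"v": rng.normal(size=50)})
        s1 = aj.split_dd_vd(records, seed=11)
        s2 = aj.split_dd_vd(records, seed=11)
        pd.testing.assert_frame_equal(s1.dd, s2.dd)

    def test_stratified_split_balances_groups(self):
        records = pd.DataFrame({"subject_id": np.repeat(list("abcd"), 30), "v": np.arange(120.0)})
        split = aj.split_dd_vd(records, seed=2, stratify_by="subject_id")
        assert (split.dd.groupby("subject_id").size() == 20).all()

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            aj.split_dd_vd(pd.DataFrame({"v": np.arange(20.0)}), ratio=1.5)


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self, rng):
        g = pd.DataFrame({"v": rng.normal(size=30)})
        out = aj.compare_groups(g, g.copy(), ["v"])
        assert out.t.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_matches_pooled_variance_oracle(self):
        a = np.array([4.2, 5.1, 6.3, 5.9, 4.8])
        b = np.array([5.0, 6.2, 7.1, 6.0])
        out = aj.compare_groups(pd.DataFrame({"v": a}), pd.DataFrame({"v": b}), ["v"])
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert out.t.iloc[0] == pytest.approx(t, abs=1e-10)
        assert out.p.iloc[0] == pytest.approx(p, abs=1e-10)

    def test_random_split_p_values_are_uniform(self, rng):
        records = pd.DataFrame({"v": rng.normal(size=300)})
        ps = []
        for seed in range(200):
            split = aj.split_dd_vd(records, seed=seed)
            ps.append(aj.compare_groups(split.dd, split.vd, ["v"]).p.iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPredictGrf:
    def test_zero_coefficient_model_returns_intercept(self):
        model = aj.PredictionModel(intercept=0.5, coefficients={})
        assert aj.predict_grf(9.9, 60.0, 30.0, 70.0, model=model) == 0.5

    def test_hand_arithmetic_oracle(self):
        # -1.712 + 0.658*1.5 + 0.016*60 + 0.008*25 + 0.003*55
        assert aj.predict_grf(1.5, 60.0, 25.0, 55.0) == pytest.approx(0.600, abs=1e-12)

    def test_reference_equation_at_validation_means(self):
        value = aj.predict_grf(1.568, 100.0 / 158.2 * 100.0, 23.6, 53.1)
        assert value == pytest.approx(0.679, abs=0.02)

    def test_fractional_pwdh_triggers_unit_warning(self):
        with pytest.warns(UserWarning, match="percent"):
            aj.predict_grf(1.5, 0.632, 25.0, 55.0)

    def test_vectorised_evaluation(self):
        out = aj.predict_grf(np.array([1.5, 1.6]), np.array([60.0, 60.0]), 25.0, 55.0)
        assert out.shape == (2,)
        assert out[1] - out[0] == pytest.approx(0.658 * 0.1)

    def test_model_json_roundtrip(self, tmp_path):
        X, y = _xy(_reference_records(seed=6))
        model = aj.backward_eliminate(y, X)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = aj.PredictionModel.from_json(path)
        assert back == model


def _xy(records: pd.DataFrame):
    return records[["c7acc", "pwdh", "age", "weight"]], records["grf_v_l_bw"].to_numpy()
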
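"""LASSO solver sanity against a normal-equations oracle; MAPE; invariances."""

import numpy as np
import pandas as pd
import pytest

from bootgait import ModelConfig, StrideLassoModel, StrideLassoResults, fit_l1, grade_mape, mape


def ols_oracle(X, y):
    """Independent least-squares oracle: normal equations with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]


def make_design(rng, n=20, p=3, coefs=(1.5, -2.0, 0.7), noise=0.01, offset=20.0):
    X = rng.normal(size=(n, p))
    y = offset + X @ np.asarray(coefs[:p]) + noise * rng.standard_normal(n)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestFit:
    def test_vanishing_penalty_matches_normal_equations(self, rng):
        X, y = make_design(rng)
        config = ModelConfig(penalty_grid=(1e-9,), seed=0)
        res = StrideLassoModel(y, X).fit(config)
        _, beta = ols_oracle(X.to_numpy(), y)
        # model coefficients are in standardized units: map back
        raw = (res.coefficients / res.scaler_sds).to_numpy()
        np.testing.assert_allclose(raw, beta, atol=1e-4)
        intercept, _ = ols_oracle(X.to_numpy(), y)
        fitted = intercept + X.to_numpy() @ beta
        np.testing.assert_allclose(res.predict(X), fitted, atol=1e-4)

    def test_huge_penalty_gives_intercept_only_model(self, rng):
        X, y = make_design(rng)
        res = StrideLassoModel(y, X).fit(ModelConfig(penalty_grid=(1e9,), seed=0))
        assert res.nnz == 0
        np.testing.assert_allclose(res.predict(X), np.full(len(y), y.mean()), rtol=1e-9)

    def test_planted_sparse_support_recovery(self, rng):
        n, p_noise = 200, 10
        X = rng.normal(size=(n, 2 + p_noise))
        y = 50.0 + 3.0 * X[:, 0] - 2.0 * X[:, 1] + 1e-8 * rng.standard_normal(n)
        frame = pd.DataFrame(X, columns=["f1", "f2"] + [f"noise{i}" for i in range(p_noise)])
        res = StrideLassoModel(y, frame).fit(ModelConfig(seed=0))
        support = set(res.coefficients[res.coefficients.abs() > 1e-4].index)
        assert support == {"f1", "f2"}
        raw = res.coefficients / res.scaler_sds
        assert raw["f1"] == pytest.approx(3.0, rel=0.05)
        assert raw["f2"] == pytest.approx(-2.0, rel=0.05)

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError):
            StrideLassoModel(np.ones(10), np.random.default_rng(0).normal(size=(10, 2)))

    def test_fewer_rows_than_folds_rejected(self, rng):
        X, y = make_design(rng, n=4)
        with pytest.raises(ValueError, match="inner_cv_folds"):
            StrideLassoModel(y, X).fit(ModelConfig(inner_cv_folds=5))

    def test_zero_variance_feature_gets_zero_coefficient(self, rng):
        X, y = make_design(rng, n=40)
        X["flat"] = 7.0
        res = StrideLassoModel(y, X).fit(ModelConfig(seed=0))
        assert res.coefficients["flat"] == 0.0
        assert np.isfinite(res.predict(X)).all()

    def test_monotone_sparsity_along_penalty_path(self, rng):
        X, y = make_design(rng, n=60, p=3, noise=0.5)
        grid = np.logspace(-4, 1, 12)
        nnzs = [StrideLassoModel(y, X).fit(ModelConfig(penalty_grid=(a,), seed=0)).nnz for a in grid]
        assert nnzs == sorted(nnzs, reverse=True)

    def test_deterministic_given_seed(self, tiny_dataset):
        sub = tiny_dataset[tiny_dataset.kept]
        a = fit_l1(sub, "at_peak_bw", ModelConfig(seed=3))
        b = fit_l1(sub, "at_peak_bw", ModelConfig(seed=3))
        pd.testing.assert_series_equal(a.coefficients, b.coefficients)
        assert a.selected_penalty == b.selected_penalty


class TestPredict:
    def test_exact_interpolation_of_exact_fit(self, rng):
        X, y = make_design(rng, n=30, noise=0.0)
        res = StrideLassoModel(y, X).fit(ModelConfig(penalty_grid=(1e-10,), seed=0))
        np.testing.assert_allclose(res.predict(X), y, atol=1e-6)

    def test_column_permutation_invariant(self, rng):
        X, y = make_design(rng, n=30)
        res = StrideLassoModel(y, X).fit(ModelConfig(seed=0))
        shuffled = X[["f2", "f0", "f1"]]
        np.testing.assert_array_equal(res.predict(X), res.predict(shuffled))

    def test_missing_feature_column_named_in_error(self, rng):
        X, y = make_design(rng, n=30)
        res = StrideLassoModel(y, X).fit(ModelConfig(seed=0))
        with pytest.raises(KeyError, match="f2"):
            res.predict(X[["f0", "f1"]])

    def test_affine_feature_rescaling_leaves_predictions_unchanged(self, rng):
        X, y = make_design(rng, n=50)
        res_a = StrideLassoModel(y, X).fit(ModelConfig(seed=1))
        X2 = X.copy()
        X2["f1"] = X2["f1"] * 1000.0 + 5.0
        res_b = StrideLassoModel(y, X2).fit(ModelConfig(seed=1))
        np.testing.assert_allclose(res_a.predict(X), res_b.predict(X2), atol=1e-6)


class TestMape:
    def test_perfect_prediction_is_zero(self):
        assert mape([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_forced_arithmetic(self):
        assert mape([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0, 0.0], [1.0, 1.0])

    @pytest.mark.parametrize(
        "value, grade",
        [(9.5, "excellent"), (15.0, "acceptable"), (25.0, "unacceptable")],
    )
    def test_agreement_grading_thresholds(self, value, grade):
        assert grade_mape(value) == grade


class TestPersistence:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = make_design(rng, n=30)
        res = StrideLassoModel(y, X).fit(ModelConfig(seed=0))
        res.to_json(tmp_path / "model.json")
        back = StrideLassoResults.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.predict(X), res.predict(X), atol=1e-12)

    def test_summary_mentions_selected_penalty_and_grade(self, rng):
        X, y = make_design(rng, n=30)
        res = StrideLassoModel(y, X).fit(ModelConfig(seed=0))
        text = res.summary()
        assert "Selected penalty" in text and "Grade" in text
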
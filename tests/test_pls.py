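"""PLS1/OLS fitting and grouped cross-validation."""

import numpy as np
import pytest

from chlorospec import (
    ChlorophyllPLS,
    choose_n_lv,
    fit_linear,
    fit_pls1,
    kfold_cv,
    r2_score,
    rmse,
)
from chlorospec.exceptions import FitError, ParameterError, ShapeError
from chlorospec.pls import grouped_folds
from chlorospec.synthetic import generate_dataset, noise_free_config
from chlorospec.spectra import WavelengthGrid


class TestFitPLS1:
    def test_single_predictor_equals_simple_regression(self, rng):
        x = rng.normal(size=40)
        y = 3.0 + 1.7 * x + rng.normal(scale=0.1, size=40)
        m = fit_pls1(x[:, None], y, n_lv=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.coefficients[0] == pytest.approx(slope, rel=1e-10)
        assert m.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_full_rank_pls_equals_ols_predictions(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        m = fit_pls1(X, y, n_lv=5)
        # normal-equations oracle
        A = np.column_stack([np.ones(60), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(m.predict(X), A @ beta, atol=1e-8)

    def test_global_scaling_equivariance(self, rng):
        X = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        m1 = fit_pls1(X, y, n_lv=3)
        m2 = fit_pls1(4.0 * X, y, n_lv=3)
        np.testing.assert_allclose(m2.predict(4.0 * X), m1.predict(X), atol=1e-9)
        np.testing.assert_allclose(m2.coefficients, m1.coefficients / 4.0, atol=1e-12)

    def test_prediction_at_training_mean_is_y_mean(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        m = fit_pls1(X, y, n_lv=2)
        assert m.predict(X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(45, 12))
        y = rng.normal(size=45)
        for n_lv in (1, 3, 6):
            ours = fit_pls1(X, y, n_lv)
            ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_excess_components_reduced_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.warns(UserWarning):
            m = fit_pls1(X, y, n_lv=9)
        assert m.n_lv <= 3

    def test_shape_mismatch_on_predict(self, rng):
        m = fit_pls1(rng.normal(size=(20, 4)), rng.normal(size=20), 2)
        with pytest.raises(ShapeError):
            m.predict(rng.normal(size=(5, 3)))


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.linspace(-1, 1, 30)
        m = fit_linear(x[:, None], 1.0 + 2.0 * x)
        assert m.intercept == pytest.approx(1.0)
        assert m.coefficients[0] == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        m = fit_linear(X, y)
        A = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], rel=1e-9)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-9)

    def test_duplicate_column_is_fit_error(self, rng):
        x = rng.normal(size=40)
        with pytest.raises(FitError):
            fit_linear(np.column_stack([x, x]), rng.normal(size=40))


class TestChooseNLV:
    def test_low_rank_signal_selects_few_components(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=(120, 2))
        loadings = rng.normal(size=(2, 30))
        X = scores @ loadings + rng.normal(scale=0.01, size=(120, 30))
        y = scores @ [2.0, -1.0] + rng.normal(scale=0.01, size=120)
        assert choose_n_lv(X, y, seed=0) <= 3

    def test_pure_noise_selects_single_component(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(80, 15))
        y = rng.normal(size=80)
        assert choose_n_lv(X, y, seed=0) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(60, 10))
        y = X[:, 0] + rng.normal(scale=0.5, size=60)
        picks = {choose_n_lv(X, y, seed=5) for _ in range(3)}
        assert len(picks) == 1


class TestGroupedFolds:
    def test_groups_never_split_across_folds(self, tiny_spectra):
        groups = tiny_spectra.records["seedling_id"].to_numpy()
        folds = grouped_folds(groups, 5, seed=0,
                              strata=tiny_spectra.records["treatment"])
        for g in np.unique(groups):
            assert len(set(folds[groups == g])) == 1

    def test_folds_partition_all_samples(self, tiny_spectra):
        groups = tiny_spectra.records["seedling_id"].to_numpy()
        folds = grouped_folds(groups, 5, seed=0)
        assert set(folds) == set(range(5))

    def test_more_folds_than_groups_rejected(self):
        with pytest.raises(ParameterError):
            grouped_folds(np.array(["a", "a", "b"]), 3, seed=0)


class _MeanRecipe:
    """Constant-mean baseline; predicts the training mean everywhere."""

    def __init__(self):
        self.mean = None

    def clone(self):
        return _MeanRecipe()

    def fit(self, s):
        self.mean = s.chlorophyll.mean()

    def predict(self, s):
        return np.full(s.n_leaves, self.mean)


class _SpyRecipe(_MeanRecipe):
    """Records every row identity passed to fit, to audit leakage."""

    seen = []

    def clone(self):
        return _SpyRecipe()

    def fit(self, s):
        super().fit(s)
        _SpyRecipe.seen.append(set(zip(s.records["seedling_id"],
                                       s.records["pair_position"],
                                       s.records["leaf_side"])))


class TestKFoldCV:
    def test_noise_free_linear_signal_is_recovered(self):
        cfg = noise_free_config(n_seedlings_per_treatment=5, seed=9)
        s, _ = generate_dataset(cfg, WavelengthGrid.regular(350, 2500, 5))
        model = ChlorophyllPLS(s, strategy="ca", transform="log(1/R)", seed=0)
        cv = kfold_cv(model._make_recipe(), s, k=5, seed=0)
        assert cv.r2_cv >= 0.97

    def test_permuted_response_has_no_skill(self, tiny_spectra):
        rng = np.random.default_rng(31)
        shuffled = tiny_spectra.records.copy()
        shuffled["chlorophyll"] = rng.permutation(shuffled["chlorophyll"].to_numpy())
        from chlorospec import SpectraSet

        s = SpectraSet(tiny_spectra.grid, tiny_spectra.reflectance, shuffled, "R")
        model = ChlorophyllPLS(s, strategy="ca", transform="log(1/R)", seed=0)
        cv = kfold_cv(model._make_recipe(), s, k=5, seed=0)
        assert cv.r2_cv <= 0.1

    def test_constant_model_rmse_matches_response_sd(self, tiny_spectra):
        cv = kfold_cv(_MeanRecipe(), tiny_spectra, k=5, seed=0)
        sd = tiny_spectra.chlorophyll.std()
        assert cv.rmse_cv == pytest.approx(sd, rel=0.05)
        assert cv.r2_cv <= 0.05

    def test_fit_never_sees_validation_rows(self, tiny_spectra):
        _SpyRecipe.seen = []
        cv = kfold_cv(_SpyRecipe(), tiny_spectra, k=5, seed=0)
        keys = list(zip(tiny_spectra.records["seedling_id"],
                        tiny_spectra.records["pair_position"],
                        tiny_spectra.records["leaf_side"]))
        for f, trained in enumerate(_SpyRecipe.seen):
            held_out = {k for k, fold in zip(keys, cv.fold_assignments) if fold == f}
            assert trained.isdisjoint(held_out)

    def test_metrics_definitions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([1.1, 1.9, 3.2, 3.8])
        assert r2_score(y, p) == pytest.approx(1 - 0.1 / 5.0)
        assert rmse(y, p) == pytest.approx(np.sqrt(0.025))
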
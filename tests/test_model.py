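"""Model/Results surface, strategy comparison and the published equation."""

from fractions import Fraction

import numpy as np
import pytest

from chlorospec import (
    AccuracyReport,
    ChlorophyllPLS,
    ModelRunSpec,
    PublishedModel,
    compare_water_effect,
    evaluate_published_model,
    holdout_split,
    run_strategy,
    select_optimal,
    shortlist_transforms,
)
from chlorospec.exceptions import ComparabilityError, GridError, ParameterError
from chlorospec.compare import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT
from chlorospec.spectra import WavelengthGrid
from chlorospec.synthetic import generate_dataset, noise_free_config

PRIME = "′"


def report(strategy="CA-PLS", transform="R", r2_cv=0.7, rmse_cv=3.0,
           r2_p=0.7, rmse_p=3.0, per_position=None, cv_seed=0):
    per_position = per_position or {
        1: {"r2_p": 0.6, "rmse_p": 3.5, "n": 40, "low_n": False},
        2: {"r2_p": 0.8, "rmse_p": 2.5, "n": 30, "low_n": False},
    }
    return AccuracyReport(strategy, transform, r2_cv, rmse_cv, r2_p, rmse_p,
                          per_position, cv_k=5, cv_seed=cv_seed, split_seed=0,
                          n_train=300, n_test=90)


class TestHoldoutSplit:
    def test_disjoint_and_stratified(self, tiny_spectra):
        train, test = holdout_split(tiny_spectra, 0.25, seed=0)
        tr = set(train.records["seedling_id"])
        te = set(test.records["seedling_id"])
        assert tr.isdisjoint(te)
        assert tr | te == set(tiny_spectra.records["seedling_id"])
        # every treatment reaches the test set, hence every leaf position
        assert set(test.records["treatment"]) == {"T1", "T2", "T3", "T4"}
        assert set(test.records["pair_position"]) == {1, 2, 3, 4}


class TestChlorophyllPLS:
    def test_caw_results_expose_ten_bands_four_from_windows(self, tiny_spectra):
        res = ChlorophyllPLS(tiny_spectra, strategy="caw",
                             transform="log(1/R)", seed=3).fit()
        sel = res.band_selection
        assert len(sel) == 10
        assert len(sel.window_bands) == 4
        assert res.accuracy.per_position  # stratified split covers positions

    def test_log_family_transforms_give_identical_accuracy(self, tiny_spectra):
        metrics = []
        for name in ("logR", "log(1/R)", f"log{chr(0x221A)}R"):
            res = ChlorophyllPLS(tiny_spectra, strategy="ab",
                                 transform=name, seed=3).fit()
            metrics.append((res.accuracy.r2_cv, res.accuracy.rmse_cv))
        for m in metrics[1:]:
            assert m[0] == pytest.approx(metrics[0][0], abs=1e-8)
            assert m[1] == pytest.approx(metrics[0][1], abs=1e-8)

    def test_raw_spectrum_differs_from_log_family(self, tiny_spectra):
        raw = ChlorophyllPLS(tiny_spectra, strategy="ab", transform="R",
                             seed=3).fit()
        log = ChlorophyllPLS(tiny_spectra, strategy="ab", transform="logR",
                             seed=3).fit()
        assert raw.accuracy.r2_cv != pytest.approx(log.accuracy.r2_cv, abs=1e-8)

    def test_single_index_model_nearly_exact_without_noise(self):
        cfg = noise_free_config(n_seedlings_per_treatment=5, seed=5)
        s, _ = generate_dataset(cfg, WavelengthGrid.regular(350, 2500, 5))
        rep = run_strategy(ModelRunSpec(strategy="vi_l",
                                        index_names=("GNDVI",), seed=5), s)
        assert rep.r2_p >= 0.95  # GNDVI is monotone but mildly nonlinear in C,
        # so a linear fit on noise-free data tops out just below 1

    def test_from_dataframe_round_trip(self, tiny_spectra):
        model = ChlorophyllPLS.from_dataframe(tiny_spectra.to_frame(),
                                              strategy="ca",
                                              transform="log(1/R)", seed=1)
        assert model.spectra.n_leaves == tiny_spectra.n_leaves

    def test_summary_mentions_key_metrics(self, tiny_spectra):
        res = ChlorophyllPLS(tiny_spectra, strategy="ca",
                             transform="log(1/R)", seed=1).fit()
        text = res.summary()
        assert "R2_CV" in text and "RMSE_P" in text and "position" in text


class TestShortlist:
    def test_baseline_always_qualifies(self):
        results = {"R": report(r2_cv=0.8), "SNV": report(r2_cv=0.5)}
        assert shortlist_transforms(results) == ["R"]

    def test_ties_with_baseline_included(self):
        results = {"R": report(r2_cv=0.8), "MSC": report(r2_cv=0.8),
                   "SNV": report(r2_cv=0.81)}
        short = shortlist_transforms(results)
        assert short == ["SNV", "MSC", "R"] or short == ["SNV", "R", "MSC"]
        assert set(short) == {"SNV", "MSC", "R"}

    def test_missing_baseline_rejected(self):
        with pytest.raises(ParameterError):
            shortlist_transforms({"SNV": report()})

    def test_log_family_enters_or_leaves_together(self, tiny_spectra):
        names = ["R", "logR", "log(1/R)", f"log{chr(0x221A)}R"]
        results = {}
        for name in names:
            res = ChlorophyllPLS(tiny_spectra, strategy="ca", transform=name,
                                 seed=3).fit()
            results[name] = res.accuracy
        short = shortlist_transforms(results)
        log_in = [n in short for n in names[1:]]
        assert all(log_in) or not any(log_in)


class TestSelectOptimal:
    def test_dominating_strategy_ranks_first(self):
        reports = {
            ("CA(W)-PLS", "log(1/R)"): report(
                per_position={1: {"r2_p": 0.8, "rmse_p": 2.0, "n": 40, "low_n": False},
                              2: {"r2_p": 0.82, "rmse_p": 1.9, "n": 40, "low_n": False}}),
            ("AB-PLS", "R" + PRIME): report(
                per_position={1: {"r2_p": 0.6, "rmse_p": 3.0, "n": 40, "low_n": False},
                              2: {"r2_p": 0.9, "rmse_p": 1.5, "n": 40, "low_n": False}}),
        }
        decision = select_optimal(reports)
        assert decision["ranking"][0] == "CA(W)-PLS"
        assert decision["trace"][0]["rank"] == 1

    def test_position1_tie_broken_by_uniformity_range(self):
        tight = {1: {"r2_p": 0.7, "rmse_p": 2.0, "n": 40, "low_n": False},
                 2: {"r2_p": 0.72, "rmse_p": 1.9, "n": 40, "low_n": False}}
        wide = {1: {"r2_p": 0.7 + 1e-8, "rmse_p": 2.0, "n": 40, "low_n": False},
                2: {"r2_p": 0.95, "rmse_p": 1.2, "n": 40, "low_n": False}}
        reports = {("CA(W)-PLS", "log(1/R)"): report(per_position=tight),
                   ("AB-PLS", "R"): report(per_position=wide)}
        assert select_optimal(reports)["ranking"][0] == "CA(W)-PLS"

    def test_best_transform_chosen_by_cv_within_strategy(self):
        reports = {
            ("CA-PLS", "R"): report(r2_cv=0.6),
            ("CA-PLS", "R" + PRIME): report(transform="R" + PRIME, r2_cv=0.7),
        }
        trace = select_optimal(reports)["trace"]
        assert trace[0]["transform"] == "R" + PRIME

    def test_missing_position1_rejected(self):
        bad = report(per_position={2: {"r2_p": 0.8, "rmse_p": 2.0, "n": 30,
                                       "low_n": False}})
        with pytest.raises(ParameterError):
            select_optimal({("CA-PLS", "R"): bad})


class TestCompareWaterEffect:
    def test_identical_reports_give_zero_deltas(self):
        a = report()
        deltas = compare_water_effect(a, a)
        assert all(v == 0 for v in deltas.values())

    def test_reported_improvement_percentages(self):
        # r2 0.7300 -> 0.8094 and rmse 3.6133 -> 2.9085
        ca = report(r2_cv=0.7300, rmse_cv=3.6133)
        caw = report(r2_cv=0.8094, rmse_cv=2.9085)
        deltas = compare_water_effect(ca, caw)
        assert deltas["r2_cv_pct"] == pytest.approx(10.88, abs=0.005)
        assert deltas["rmse_cv_pct"] == pytest.approx(-19.51, abs=0.005)

    def test_mismatched_folds_rejected(self):
        with pytest.raises(ComparabilityError):
            compare_water_effect(report(cv_seed=0), report(cv_seed=1))


class TestPublishedModel:
    def test_zero_input_returns_intercept(self):
        m = PublishedModel()
        assert m.predict_values(np.zeros(10))[0] == pytest.approx(2.1754)

    def test_all_ones_returns_intercept_plus_coefficient_sum(self):
        # independent exact-rational summation oracle
        total = sum(Fraction(str(c)) for c in PUBLISHED_COEFFICIENTS)
        expected = float(Fraction(str(PUBLISHED_INTERCEPT)) + total)
        m = PublishedModel()
        assert m.predict_values(np.ones(10))[0] == pytest.approx(expected, abs=1e-10)

    def test_random_input_matches_dot_product_oracle(self, rng):
        x = rng.normal(size=10)
        m = PublishedModel()
        oracle = PUBLISHED_INTERCEPT + sum(
            c * v for c, v in zip(PUBLISHED_COEFFICIENTS, x))
        assert m.predict_values(x)[0] == pytest.approx(oracle, abs=1e-10)

    def test_evaluation_on_spectra_matches_manual_transform(self, study_spectra):
        from chlorospec import apply_transform

        sub = study_spectra.subset(np.arange(5))
        m = PublishedModel()
        got = evaluate_published_model(m, sub)
        t = apply_transform("log(1/R)", sub)
        X = np.column_stack([t.band(b) for b in m.bands])
        np.testing.assert_allclose(got, m.predict_values(X))

    def test_raw_reflectance_interpretation_available(self, study_spectra):
        sub = study_spectra.subset(np.arange(3))
        m = PublishedModel(input_transform=None)
        X = np.column_stack([sub.band(b) for b in m.bands])
        np.testing.assert_allclose(evaluate_published_model(m, sub),
                                   m.predict_values(X))

    def test_missing_band_is_grid_error(self, study_spectra):
        trimmed = study_spectra.subset(np.arange(3)).trim(400, 1200)
        with pytest.raises(GridError):
            evaluate_published_model(PublishedModel(), trimmed)

    def test_wrong_width_rejected(self):
        with pytest.raises(ParameterError):
            PublishedModel().predict_values(np.zeros(9))
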
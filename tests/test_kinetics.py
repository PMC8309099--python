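"""Release-model fitting, scoring, selection and mechanism classification."""

import numpy as np
import pytest

from dissofit import (
    KineticFitResult,
    Mechanism,
    ReleaseModel,
    analyze_profile,
    classify_mechanism,
    compute_mpe,
    fit_first_order,
    fit_higuchi,
    fit_korsmeyer_peppas,
    fit_zero_order,
    select_best_model,
    truncate_to_60,
)
from dissofit.exceptions import AnalysisError, InsufficientDataError, ModelSkipped
from dissofit.simulate import two_stage_schedule


def result(model, r2, mpe, n=None):
    return KineticFitResult(
        model=ReleaseModel(model), rate_constant=1.0, intercept=0.0,
        r_squared=r2, mpe=mpe, n_points_used=10, exponent_n=n,
    )


class TestTruncation:
    def test_keeps_points_up_to_60(self, profile_factory):
        p = profile_factory([1, 2, 3, 4, 5], [10, 30, 55, 70, 95])
        out = truncate_to_60(p)
        np.testing.assert_array_equal(out.release, [10, 30, 55])
        assert p.n_points == 5  # original untouched

    def test_identity_when_all_below_60(self, profile_factory):
        p = profile_factory([1, 2, 3], [10, 30, 55])
        np.testing.assert_array_equal(truncate_to_60(p).release, p.release)

    def test_empty_when_all_above_60(self, profile_factory):
        p = profile_factory([1, 2], [65, 80])
        assert truncate_to_60(p).n_points == 0


class TestExactFits:
    def test_zero_order_on_linear_data(self, profile_factory):
        t = np.array([0.0, 15, 30, 60])
        fit = fit_zero_order(profile_factory(t, 1.5 * t))
        assert fit.rate_constant == pytest.approx(1.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.mpe == pytest.approx(0.0, abs=1e-12)

    def test_first_order_on_exact_exponential(self, profile_factory):
        t = np.arange(15.0, 200.0, 15.0)
        q = 100 * (1 - 10 ** (-0.01 * t))
        fit = fit_first_order(profile_factory(t, q))
        assert fit.transformed_slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.rate_constant == pytest.approx(0.01 * np.log(10), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_first_order_drops_complete_release_points(self, profile_factory):
        p = profile_factory([1, 2, 3], [99.9, 99.99, 100.0])
        with pytest.raises(InsufficientDataError):
            fit_first_order(p)

    def test_higuchi_on_sqrt_data(self, profile_factory):
        fit = fit_higuchi(profile_factory([1, 4, 9], [20, 40, 60]))
        assert fit.rate_constant == pytest.approx(20.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_korsmeyer_peppas_recovers_exponent_and_k(self, profile_factory):
        t = np.array([10.0, 20, 40, 80])
        q = 10 * t**0.941 / 100  # scaled to stay below 60%
        fit = fit_korsmeyer_peppas(profile_factory(t, q))
        assert fit.exponent_n == pytest.approx(0.941, abs=1e-12)
        assert fit.rate_constant == pytest.approx(0.1, abs=1e-12)

    def test_nested_higuchi_gives_exponent_half(self, profile_factory):
        t = np.array([1.0, 4, 9, 16])
        fit = fit_korsmeyer_peppas(profile_factory(t, 10 * np.sqrt(t)))
        assert fit.exponent_n == pytest.approx(0.5, abs=1e-12)

    def test_nested_zero_order_gives_exponent_one(self, profile_factory):
        t = np.array([5.0, 10, 20, 40])
        fit = fit_korsmeyer_peppas(profile_factory(t, 1.2 * t))
        assert fit.exponent_n == pytest.approx(1.0, abs=1e-12)


class TestDegenerateAndSkips:
    def test_constant_release_is_degenerate(self, profile_factory):
        with pytest.raises(ModelSkipped, match="degenerate"):
            fit_zero_order(profile_factory([1, 2, 3, 4], [50, 50, 50, 50]))

    def test_fast_release_skips_higuchi(self, profile_factory):
        with pytest.raises(ModelSkipped, match="fast drug release"):
            fit_higuchi(profile_factory([15, 30, 45], [55, 90, 99]))

    def test_too_few_points_rejected(self, profile_factory):
        with pytest.raises(InsufficientDataError):
            fit_zero_order(profile_factory([1, 2], [10, 20]))

    def test_kp_excludes_time_and_release_zeros(self, profile_factory):
        p = profile_factory([0, 10, 20, 40], [0, 10, 17, 28])
        fit = fit_korsmeyer_peppas(p)
        assert fit.n_points_used == 3

    def test_r2_invariant_to_predictor_rescaling(self, profile_factory):
        rng = np.random.default_rng(3)
        t = np.arange(10.0, 130.0, 10.0)
        q = 0.4 * t + rng.normal(0, 2, len(t))
        f1 = fit_zero_order(profile_factory(t, q))
        f2 = fit_zero_order(profile_factory(3 * t + 7, q))
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)


class TestMpe:
    def test_identical_is_zero(self):
        assert compute_mpe([10, 20], [10, 20]) == 0.0

    @pytest.mark.parametrize(
        "obs,pred,expected",
        [([50], [55], 10.0), ([25, 50], [30, 45], 15.0)],
    )
    def test_hand_computed(self, obs, pred, expected):
        assert compute_mpe(obs, pred) == pytest.approx(expected)

    def test_zero_observations_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero observed"):
            value = compute_mpe([0, 50], [5, 55])
        assert value == pytest.approx(10.0)

    def test_all_zero_observations_rejected(self):
        with pytest.raises(AnalysisError):
            compute_mpe([0, 0], [1, 2])


class TestSelection:
    def test_highest_r_squared_wins(self):
        fits = [
            result("zero_order", 0.998, 4.74),
            result("first_order", 0.976, 22.65),
            result("higuchi", 0.971, 20.63),
            result("korsmeyer_peppas", 0.994, 5.07, n=1.327),
        ]
        assert select_best_model(fits) is ReleaseModel.ZERO_ORDER

    def test_sustained_matrix_scores_pick_higuchi(self):
        fits = [
            result("zero_order", 0.838, 43.18),
            result("first_order", 0.905, 37.43),
            result("higuchi", 0.953, 17.72),
            result("korsmeyer_peppas", 0.923, 19.48, n=0.941),
        ]
        assert select_best_model(fits) is ReleaseModel.HIGUCHI

    def test_exact_tie_broken_by_parsimony(self):
        fits = [
            result("korsmeyer_peppas", 1.0, 0.0, n=1.0),
            result("zero_order", 1.0, 0.0),
        ]
        assert select_best_model(fits) is ReleaseModel.ZERO_ORDER

    def test_near_tie_broken_by_mpe(self):
        fits = [
            result("zero_order", 0.9999990, 8.0),
            result("higuchi", 0.9999995, 2.0),
        ]
        assert select_best_model(fits) is ReleaseModel.HIGUCHI

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            select_best_model([])


class TestMechanism:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (0.30, Mechanism.FICKIAN),
            (0.449, Mechanism.FICKIAN),
            (0.45, Mechanism.ANOMALOUS),
            (0.88, Mechanism.ANOMALOUS),
            (0.89, Mechanism.CASE_II),
            (0.941, Mechanism.CASE_II),
            (1.0, Mechanism.CASE_II),
            (1.030, Mechanism.SUPER_CASE_II),
            (1.327, Mechanism.SUPER_CASE_II),
        ],
    )
    def test_exponent_bands(self, n, expected):
        assert classify_mechanism(n) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_mechanism(float("inf"))


class TestAnalyzeProfile:
    def test_fast_release_fits_only_zero_and_first(self, profile_factory, schedule):
        # complete release by the second sample: the power-law validity
        # window (<= 60% released) contains a single point
        q = np.clip(np.array([50.0] + [100.0] * (len(schedule) - 1)), 0, 100)
        q[1:] = np.linspace(99, 100, len(schedule) - 1)
        report = analyze_profile(profile_factory(schedule, q, fid="fast"))
        assert set(report.fits) <= {ReleaseModel.ZERO_ORDER, ReleaseModel.FIRST_ORDER}
        assert ReleaseModel.HIGUCHI in report.skipped_models
        assert "fast drug release" in report.skipped_models[ReleaseModel.HIGUCHI]
        assert report.mechanism is Mechanism.NOT_APPLICABLE

    def test_sustained_profile_fits_all_four(self, profile_factory, schedule):
        q = 2.2 * np.sqrt(schedule)
        report = analyze_profile(profile_factory(schedule, q, fid="slow"))
        assert len(report.fits) == 4
        assert report.best_model is ReleaseModel.HIGUCHI
        # square-root kinetics imply n = 0.5, inside the anomalous band
        assert report.mechanism is Mechanism.ANOMALOUS

    def test_all_models_skipped_is_an_error(self, profile_factory):
        with pytest.raises(AnalysisError):
            analyze_profile(profile_factory([1, 2, 3], [50, 50, 50]))

    def test_deterministic_for_fixed_profile(self, profile_factory, schedule):
        q = np.clip(100 * (1 - np.exp(-0.0035 * schedule)), 0, 100)
        p = profile_factory(schedule, q, fid="S")
        r1, r2 = analyze_profile(p), analyze_profile(p)
        assert r1.best_model == r2.best_model
        assert {m: f.r_squared for m, f in r1.fits.items()} == {
            m: f.r_squared for m, f in r2.fits.items()
        }
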
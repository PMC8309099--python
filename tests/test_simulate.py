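"""Synthetic dissolution experiments and powder measurement fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dissofit import (
    SimulationSpec,
    model_curve,
    simulate_powder_measurements,
    simulate_profile,
    simulate_two_stage_profile,
    two_stage_schedule,
)
from dissofit.qc import carr_index


class TestSchedule:
    def test_two_stage_grid_shape(self):
        t = two_stage_schedule()
        assert len(t) == 19
        assert t[0] == 15.0 and t[-1] == 1440.0
        assert np.all(np.diff(t) > 0)
        assert np.max(np.diff(t)) <= 120.0

    def test_gastric_points_every_15_minutes(self):
        t = two_stage_schedule()
        np.testing.assert_array_equal(t[t <= 120], np.arange(15.0, 121.0, 15.0))


class TestSimulateProfile:
    def test_noise_free_higuchi_is_exact(self):
        spec = SimulationSpec(
            model="higuchi", params={"k": 20}, schedule=[1, 4, 9], noise_sd=0
        )
        (p,) = simulate_profile(spec)
        np.testing.assert_array_equal(p.release, [20, 40, 60])

    def test_same_seed_reproduces(self, schedule):
        spec = SimulationSpec(
            model="zero_order", params={"k": 0.05}, schedule=schedule,
            noise_sd=1.0, n_replicates=3, seed=11,
        )
        a, b = simulate_profile(spec), simulate_profile(spec)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.release, pb.release)

    def test_adding_replicates_preserves_earlier_streams(self, schedule):
        base = dict(model="higuchi", params={"k": 2.2}, schedule=schedule,
                    noise_sd=1.0, seed=5)
        two = simulate_profile(SimulationSpec(n_replicates=2, **base))
        three = simulate_profile(SimulationSpec(n_replicates=3, **base))
        for pa, pb in zip(two, three):
            np.testing.assert_array_equal(pa.release, pb.release)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_projection_is_nondecreasing(self, seed):
        spec = SimulationSpec(
            model="first_order", params={"k": 0.003},
            schedule=two_stage_schedule(), noise_sd=2.0, monotone=True, seed=seed,
        )
        (p,) = simulate_profile(spec)
        assert np.all(np.diff(p.release) >= 0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_noised_values_stay_physical(self, seed):
        spec = SimulationSpec(
            model="zero_order", params={"k": 0.08},
            schedule=two_stage_schedule(), noise_sd=1.5, seed=seed,
        )
        (p,) = simulate_profile(spec)
        assert np.all(p.release >= 0)
        assert np.all(p.release <= spec.cap + 5 * spec.noise_sd)

    def test_cap_bounds_the_clean_curve(self, schedule):
        spec = SimulationSpec(
            model="korsmeyer_peppas", params={"k": 1.5, "n": 0.75},
            schedule=schedule, noise_sd=0,
        )
        (p,) = simulate_profile(spec)
        assert p.release.max() == pytest.approx(100.0)

    def test_replicate_mean_tracks_clean_curve(self, schedule):
        spec = SimulationSpec(
            model="higuchi", params={"k": 2.2}, schedule=schedule,
            noise_sd=1.0, n_replicates=200, seed=1,
        )
        profiles = simulate_profile(spec)
        mean = np.mean([p.release for p in profiles], axis=0)
        clean = 2.2 * np.sqrt(schedule)
        se = 1.0 / np.sqrt(200)
        assert np.max(np.abs(mean - clean)) <= 3 * se

    def test_stage_annotations_follow_schedule(self, schedule):
        spec = SimulationSpec(model="higuchi", params={"k": 2.2},
                              schedule=schedule, noise_sd=0)
        (p,) = simulate_profile(spec)
        assert p.ph_at(60) == 1.2
        assert p.ph_at(240) == 7.4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="higuchi", params={}, schedule=[1, 2]),
            dict(model="korsmeyer_peppas", params={"k": 1}, schedule=[1, 2]),
            dict(model="higuchi", params={"k": 1}, schedule=[2, 1]),
            dict(model="higuchi", params={"k": 1}, schedule=[1, 2], noise_sd=-1),
            dict(model="higuchi", params={"k": 1}, schedule=[1, 2], cap=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSpec(**kwargs)


class TestTwoStage:
    @pytest.mark.parametrize(
        "model,params",
        [
            ("zero_order", {"k": 0.07}),
            ("first_order", {"k": 0.0035}),
            ("higuchi", {"k": 2.2}),
            ("korsmeyer_peppas", {"k": 1.5, "n": 0.75}),
        ],
    )
    def test_identical_stages_reproduce_single_stage(self, schedule, model, params):
        spec = SimulationSpec(model=model, params=params, schedule=schedule, noise_sd=0)
        (single,) = simulate_profile(spec)
        (double,) = simulate_two_stage_profile(spec, spec, changeover=120.0)
        np.testing.assert_allclose(double.release, single.release, atol=1e-9)

    def test_zero_rate_second_stage_plateaus(self, schedule):
        s1 = SimulationSpec(model="zero_order", params={"k": 0.3},
                            schedule=schedule, noise_sd=0)
        s2 = SimulationSpec(model="zero_order", params={"k": 0.0},
                            schedule=schedule, noise_sd=0)
        (p,) = simulate_two_stage_profile(s1, s2, changeover=120.0)
        after = schedule > 120
        np.testing.assert_array_equal(p.release[after], 36.0)

    def test_higuchi_continuation_is_continuous_at_changeover(self):
        sched = np.array([15.0, 60.0, 120.0, 120.0 + 1e-8, 240.0])
        s1 = SimulationSpec(model="zero_order", params={"k": 0.2},
                            schedule=sched, noise_sd=0)
        s2 = SimulationSpec(model="higuchi", params={"k": 3.0},
                            schedule=sched, noise_sd=0)
        for continuation in ("carryover", "additive"):
            (p,) = simulate_two_stage_profile(
                s1, s2, changeover=120.0, continuation=continuation
            )
            assert p.release[3] == pytest.approx(p.release[2], abs=1e-3)

    def test_changeover_must_be_on_schedule(self, schedule):
        spec = SimulationSpec(model="higuchi", params={"k": 2},
                              schedule=schedule, noise_sd=0)
        with pytest.raises(ValueError, match="schedule"):
            simulate_two_stage_profile(spec, spec, changeover=100.0)


class TestPowderMeasurements:
    def test_zero_noise_returns_exact_inputs(self):
        table = simulate_powder_measurements(0.42, 0.50, 2.0, 4.0, noise_cv=0.0)
        assert len(table) == 3
        assert (table["bulk_density"] == 0.42).all()
        assert (table["tapped_density"] == 0.50).all()

    def test_noise_free_carr_index_downstream(self):
        table = simulate_powder_measurements(0.42, 0.50, 2.0, 4.0, noise_cv=0.0)
        ci = carr_index(table["bulk_density"][0], table["tapped_density"][0])
        assert ci == pytest.approx(16.0)

    def test_seed_determinism_and_tapped_floor(self):
        a = simulate_powder_measurements(0.42, 0.44, 2, 4, noise_cv=0.2,
                                         n_replicates=5, seed=9)
        b = simulate_powder_measurements(0.42, 0.44, 2, 4, noise_cv=0.2,
                                         n_replicates=5, seed=9)
        assert a.equals(b)
        assert (a["tapped_density"] >= a["bulk_density"]).all()

    def test_inverted_densities_rejected(self):
        with pytest.raises(ValueError):
            simulate_powder_measurements(0.50, 0.42, 2, 4)


def test_model_curve_forms():
    t = np.array([4.0, 16.0])
    np.testing.assert_allclose(model_curve("zero_order", t, {"k": 2}), [8, 32])
    np.testing.assert_allclose(model_curve("higuchi", t, {"k": 10}), [20, 40])
    np.testing.assert_allclose(
        model_curve("korsmeyer_peppas", t, {"k": 3, "n": 0.5}), [6, 12]
    )
    np.testing.assert_allclose(
        model_curve("first_order", t, {"k": 0.1}),
        100 * (1 - np.exp(-0.1 * t)),
    )
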
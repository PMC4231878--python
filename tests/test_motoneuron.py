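"""Recruitment curves, point-process ISI draws, and spike-train generation."""

import numpy as np
import pytest

from lifesim import (
    ConfigurationError,
    FiringCurve,
    MotoneuronSpec,
    PointProcessSpec,
    TimeGrid,
    ValidationError,
    draw_isi,
    firing_rate,
    generate_spike_times,
    rate_slope,
    sample_pool,
)

# The two pool-wide rate curves of the overlap sweep: S units cover the
# lower half of the intent range, FF units the upper half.
S_CURVE = FiringCurve(x_thr=0.0, x_sat=0.5, f_thr=5.0, f_sat=18.0)
FF_CURVE = FiringCurve(x_thr=0.5, x_sat=1.0, f_thr=18.0, f_sat=35.0)


def _spec(curve=S_CURVE, kind="identity", **kw):
    return MotoneuronSpec(
        curve=curve,
        process=PointProcessSpec(kind=kind, **kw),
        template_id="u0",
        fiber_type="S",
        spike_duration=0.004,
        spike_amplitude=50.0,
    )


class TestFiringCurve:
    def test_silent_below_and_at_threshold(self):
        assert firing_rate(FF_CURVE, 0.4999) == 0.0
        # a unit is recruited strictly above its threshold
        assert firing_rate(FF_CURVE, 0.5) == 0.0

    def test_linear_branch_matches_hand_evaluation(self):
        # 5 Hz at threshold rising with slope 26 Hz/unit over [0, 0.5]
        assert firing_rate(S_CURVE, 0.25) == pytest.approx(5 + 26 * 0.25)

    def test_saturation_rate_at_and_above_x_sat(self):
        assert firing_rate(S_CURVE, 0.5) == 18.0
        assert firing_rate(S_CURVE, 0.9) == 18.0

    def test_slopes_of_the_sweep_curves(self):
        assert rate_slope(S_CURVE) == pytest.approx(26.0)
        assert rate_slope(FF_CURVE) == pytest.approx(34.0)

    def test_flat_curve_has_zero_slope(self):
        flat = FiringCurve(x_thr=0.1, x_sat=0.9, f_thr=10.0, f_sat=10.0)
        assert rate_slope(flat) == 0.0

    def test_rate_is_nondecreasing_in_activation(self):
        x = np.linspace(0, 1, 1001)
        f = firing_rate(FF_CURVE, x)
        assert np.all(np.diff(f) >= 0)
        assert set(np.unique(f[f > 0])) <= set(f[f >= FF_CURVE.f_thr])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(x_thr=0.5, x_sat=0.5, f_thr=5.0, f_sat=18.0),
            dict(x_thr=0.6, x_sat=0.5, f_thr=5.0, f_sat=18.0),
            dict(x_thr=0.0, x_sat=0.5, f_thr=0.0, f_sat=18.0),
            dict(x_thr=0.0, x_sat=0.5, f_thr=20.0, f_sat=18.0),
            dict(x_thr=0.0, x_sat=1.5, f_thr=5.0, f_sat=18.0),
        ],
    )
    def test_invalid_curves_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FiringCurve(**kwargs)


class TestDrawIsi:
    def test_identity_process_is_exact(self, rng):
        spec = PointProcessSpec(kind="identity")
        assert draw_isi(spec, 0.1, rng) == 0.1

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ValidationError):
            draw_isi(PointProcessSpec(kind="poisson"), 0.0, rng)

    def test_floor_clips_stochastic_draws(self, rng):
        spec = PointProcessSpec(kind="poisson")
        draws = draw_isi(spec, 0.0005, rng, size=1000)
        assert draws.min() >= 0.001

    def test_gamma_concentrates_as_dispersion_vanishes(self, rng):
        spec = PointProcessSpec(kind="gamma", dispersion=1e-5)
        draws = draw_isi(spec, 0.05, rng, size=1000)
        assert np.all(np.abs(draws - 0.05) < 1e-3)

    def test_gamma_moment_parameterization(self, rng):
        spec = PointProcessSpec(kind="gamma", dispersion=0.01)
        draws = draw_isi(spec, 0.05, rng, size=50_000)
        assert draws.mean() == pytest.approx(0.05, rel=0.01)
        assert draws.std() == pytest.approx(0.01, rel=0.05)

    def test_uniform_draws_stay_in_window(self, rng):
        spec = PointProcessSpec(kind="uniform", width=0.02)
        draws = draw_isi(spec, 0.05, rng, size=5000)
        assert draws.min() >= 0.04 - 1e-12
        assert draws.max() <= 0.06 + 1e-12

    def test_poisson_moments_match_exponential(self, rng):
        spec = PointProcessSpec(kind="poisson")
        draws = draw_isi(spec, 0.05, rng, size=100_000)
        assert draws.mean() == pytest.approx(0.05, rel=0.02)
        assert draws.std() / draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_dispersion_required_where_meaningful(self):
        with pytest.raises(ValidationError):
            PointProcessSpec(kind="gamma")
        with pytest.raises(ConfigurationError):
            PointProcessSpec(kind="weibull")


class TestGenerateSpikeTimes:
    def test_subthreshold_activation_yields_empty_train(self, grid, rng):
        act = np.full(grid.n_samples, 0.3)  # below FF threshold of 0.5
        train = generate_spike_times(_spec(curve=FF_CURVE), act, grid, rng)
        assert train.n_events == 0

    def test_identity_process_gives_regular_train(self, grid, rng):
        # constant activation at 5 Hz + slope*... -> pick x giving exactly 10 Hz
        curve = FiringCurve(x_thr=0.0, x_sat=1.0, f_thr=10.0, f_sat=10.0)
        act = np.ones(grid.n_samples)
        train = generate_spike_times(_spec(curve=curve), act, grid, rng)
        assert train.n_events == 10
        np.testing.assert_allclose(np.diff(train.event_times), 0.1, atol=1e-9)
        # first event one full interval after onset
        assert train.event_times[0] == pytest.approx(0.1)

    def test_first_event_follows_recruitment_onset(self, grid, rng):
        act = np.zeros(grid.n_samples)
        act[grid.n_samples // 2 :] = 1.0
        curve = FiringCurve(x_thr=0.5, x_sat=0.9, f_thr=50.0, f_sat=60.0)
        train = generate_spike_times(_spec(curve=curve), act, grid, rng)
        assert train.n_events > 0
        assert train.event_times[0] >= 0.5

    def test_poisson_event_count_matches_rate(self, rng):
        long_grid = TimeGrid(sampling_rate=2000.0, duration=200.0)
        curve = FiringCurve(x_thr=0.0, x_sat=1.0, f_thr=20.0, f_sat=20.0)
        act = np.ones(long_grid.n_samples)
        train = generate_spike_times(
            _spec(curve=curve, kind="poisson"), act, long_grid, rng
        )
        assert abs(train.n_events - 4000) < 3 * np.sqrt(4000)

    def test_events_sorted_within_bounds_for_varying_drive(self, grid, rng):
        act = np.abs(np.sin(2 * np.pi * grid.times))
        train = generate_spike_times(_spec(kind="poisson"), act, grid, rng)
        diffs = np.diff(train.event_times)
        assert np.all(diffs > 0)
        assert train.event_times[0] >= 0 and train.event_times[-1] <= grid.duration

    def test_mean_isi_converges_to_inverse_rate(self, rng):
        # constant 18 Hz drive, gamma timing: sample mean ISI within 3 SE
        long_grid = TimeGrid(sampling_rate=2000.0, duration=600.0)
        curve = FiringCurve(x_thr=0.0, x_sat=1.0, f_thr=18.0, f_sat=18.0)
        act = np.ones(long_grid.n_samples)
        train = generate_spike_times(
            _spec(curve=curve, kind="gamma", dispersion=0.005), act, long_grid, rng
        )
        isis = np.diff(train.event_times)
        assert isis.size > 10_000
        se = isis.std(ddof=1) / np.sqrt(isis.size)
        assert abs(isis.mean() - 1 / 18.0) < 3 * se


RUN1_S = {
    "duration": (0.004, 0.006),
    "amplitude": (45.0, 65.0),
    "f_thr": (1.0, 5.0),
    "f_sat": (16.0, 18.0),
    "x_thr": (0.0, 0.10),
    "x_sat": (0.40, 0.50),
}
RUN1_FF = {
    "duration": (0.002, 0.004),
    "amplitude": (95.0, 105.0),
    "f_thr": (12.0, 19.0),
    "f_sat": (25.0, 30.0),
    "x_thr": (0.35, 0.65),
    "x_sat": (0.80, 1.00),
}


class TestSamplePool:
    def test_all_draws_inside_their_ranges(self, rng):
        pool = sample_pool(RUN1_S, 6, "S", rng)
        assert len(pool) == 6
        for unit in pool:
            assert 0.004 <= unit.spike_duration <= 0.006
            assert 45 <= unit.spike_amplitude <= 65
            assert 1 <= unit.curve.f_thr <= 5
            assert 16 <= unit.curve.f_sat <= 18
            assert 0 <= unit.curve.x_thr <= 0.10
            assert 0.40 <= unit.curve.x_sat <= 0.50
            assert unit.fiber_type == "S"

    def test_sequential_recruitment_of_fiber_types(self, rng):
        s_pool = sample_pool(RUN1_S, 6, "S", rng)
        ff_pool = sample_pool(RUN1_FF, 6, "FF", rng)
        assert max(u.curve.x_thr for u in s_pool) < min(
            u.curve.x_thr for u in ff_pool
        )

    def test_degenerate_ranges_are_deterministic(self, rng):
        ranges = {k: (v, v) for k, v in
                  dict(duration=0.004, amplitude=50.0, f_thr=5.0, f_sat=18.0,
                       x_thr=0.1, x_sat=0.5).items()}
        unit, = sample_pool(ranges, 1, "S", rng)
        assert unit.curve.x_thr == 0.1 and unit.curve.f_sat == 18.0

    def test_zero_count_rejected(self, rng):
        with pytest.raises(ValidationError):
            sample_pool(RUN1_S, 0, "S", rng)

    def test_unsatisfiable_thresholds_rejected(self, rng):
        bad = dict(RUN1_S, x_thr=(0.9, 0.95), x_sat=(0.1, 0.2))
        with pytest.raises(ConfigurationError):
            sample_pool(bad, 1, "S", rng)

    def test_missing_range_rejected(self, rng):
        bad = {k: v for k, v in RUN1_S.items() if k != "f_sat"}
        with pytest.raises(ConfigurationError):
            sample_pool(bad, 1, "S", rng)
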
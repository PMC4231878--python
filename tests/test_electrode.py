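"""Mixing matrices H = CB, SNR calibration, noise synthesis, and record()."""

import numpy as np
import pytest

from lifesim import (
    AxonSignals,
    NoiseSpec,
    SpikeTrain,
    TimeGrid,
    ValidationError,
    compose_mapping,
    generate_gaussian_noise,
    generate_powerlaw_noise,
    make_morphology,
    noise_sigma_from_snr,
    record,
    render_pool,
    scale_template,
    virtual_signals,
)


class TestComposeMapping:
    def test_identity_crosstalk_leaves_b_unchanged(self):
        B = np.array([[0.5, 1.0], [1.0, 0.0]])
        mapping = compose_mapping(B)
        np.testing.assert_array_equal(mapping.H, B)

    def test_single_electrode_row(self):
        mapping = compose_mapping([[0.5, 1.0]], [[1.0]])
        np.testing.assert_array_equal(mapping.H, [[0.5, 1.0]])

    def test_hand_computed_crosstalk_product(self):
        # two one-hot virtual electrodes mixed by a symmetric crosstalk matrix
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        mapping = compose_mapping(B, C)
        np.testing.assert_array_equal(mapping.H, [[1.0, 0.5], [0.5, 1.0]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compose_mapping(np.ones((2, 3)), np.ones((3, 3)))

    def test_negative_gains_rejected(self):
        with pytest.raises(ValidationError):
            compose_mapping([[-0.1, 1.0]])


def _axons(grid, rows):
    return AxonSignals(grid, np.atleast_2d(rows))


class TestVirtualSignals:
    def test_one_hot_row_selects_one_axon(self, grid, rng):
        y = rng.standard_normal((3, grid.n_samples))
        v = virtual_signals(_axons(grid, y), compose_mapping([[0.0, 1.0, 0.0]]))
        np.testing.assert_array_equal(v[0], y[1])

    def test_zero_row_is_silent(self, grid, rng):
        y = rng.standard_normal((2, grid.n_samples))
        v = virtual_signals(_axons(grid, y), compose_mapping([[0.0, 0.0]]))
        assert np.all(v == 0)

    def test_weighted_sum_matches_accumulation_oracle(self, grid, rng):
        y = rng.standard_normal((6, grid.n_samples))
        weights = np.linspace(0.5, 1.0, 6)
        v = virtual_signals(_axons(grid, y), compose_mapping([weights]))
        oracle = np.zeros(grid.n_samples)
        for w, row in zip(weights, y):
            oracle += w * row
        np.testing.assert_allclose(v[0], oracle, atol=1e-12)

    def test_axon_count_mismatch_rejected(self, grid, rng):
        y = rng.standard_normal((2, grid.n_samples))
        with pytest.raises(ValidationError):
            virtual_signals(_axons(grid, y), compose_mapping([[1.0, 1.0, 1.0]]))


class TestNoiseSigma:
    def test_unit_span_arithmetic(self, rng):
        # scale an arbitrary trace so its 99.9-0.1 percentile span is 9:
        # with SNR 3 the noise SD must be exactly 1
        trace = rng.standard_normal(200_000)
        span = np.percentile(trace, 99.9) - np.percentile(trace, 0.1)
        trace *= 9.0 / span
        assert noise_sigma_from_snr(trace, 3.0) == pytest.approx(1.0, abs=1e-12)

    def test_sigma_vanishes_at_infinite_snr(self, rng):
        trace = rng.standard_normal(10_000)
        assert noise_sigma_from_snr(trace, 1e9) < 1e-8

    def test_uniform_trace_span(self, rng):
        # uniform on [0, 1]: the 99.9-0.1 percentile span is 0.998
        trace = rng.uniform(0, 1, 1_000_000)
        assert noise_sigma_from_snr(trace, 3.0) == pytest.approx(
            0.998 / 9.0, rel=1e-2
        )

    def test_constant_trace_rejected(self):
        with pytest.raises(ValidationError):
            noise_sigma_from_snr(np.ones(1000), 3.0)


class TestNoiseGeneration:
    def test_powerlaw_amplitude_is_output_sd(self, grid, rng):
        spec = NoiseSpec(model="powerlaw", beta=1.0, amplitude=2.5)
        trace = generate_powerlaw_noise(spec, grid, rng)
        assert trace.std() == pytest.approx(2.5)
        assert trace.size == grid.n_samples

    def test_powerlaw_is_seed_deterministic(self, grid):
        spec = NoiseSpec(model="powerlaw", beta=2.0, amplitude=1.0)
        a = generate_powerlaw_noise(spec, grid, np.random.default_rng(7))
        b = generate_powerlaw_noise(spec, grid, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_gaussian_noise_realizes_requested_snr(self, rng):
        grid = TimeGrid(20_000.0, 10.0)
        pure = np.sin(2 * np.pi * 500 * grid.times) * 50
        spec = NoiseSpec(model="gaussian_snr", snr=3.0, band=(80.0, 4000.0))
        noise = generate_gaussian_noise(spec, pure, grid, rng)
        measured = (
            np.percentile(pure, 99.9) - np.percentile(pure, 0.1)
        ) / (3 * noise.std())
        assert measured == pytest.approx(3.0, rel=0.05)

    def test_band_outside_nyquist_rejected(self, grid, rng):
        spec = NoiseSpec(model="gaussian_snr", snr=3.0, band=(80.0, 4000.0))
        bad = NoiseSpec(model="gaussian_snr", snr=3.0, band=(80.0, 40_000.0))
        pure = np.sin(2 * np.pi * 500 * grid.times)
        generate_gaussian_noise(spec, pure, grid, rng)  # fine
        with pytest.raises(ValidationError):
            generate_gaussian_noise(bad, pure, grid, rng)


def _pool_recording_inputs(grid, rng, n_axons=3, n_events=20):
    morph = make_morphology("gaussian", 1)
    templates, trains = [], []
    for i in range(n_axons):
        templates.append(scale_template(morph, 50.0 + 10 * i, 0.003, grid, f"t{i}"))
        times = np.sort(rng.uniform(0, grid.duration * 0.98, n_events))
        times = times[np.diff(np.concatenate([[-1.0], times])) > 1e-3]
        trains.append(SpikeTrain(times, f"t{i}", grid))
    return trains, templates, render_pool(trains, templates, grid)


class TestRecord:
    def test_noise_free_one_hot_equals_axon_trace(self, grid, rng):
        trains, templates, axons = _pool_recording_inputs(grid, rng)
        mapping = compose_mapping([[0.0, 1.0, 0.0]])
        rec = record(axons, mapping, NoiseSpec(model="none"), rng)
        np.testing.assert_array_equal(rec.values[0], axons.values[1])

    def test_silent_pool_records_pure_noise(self, grid, rng):
        axons = AxonSignals(grid, np.zeros((2, grid.n_samples)))
        mapping = compose_mapping([[1.0, 1.0]])
        rec = record(axons, mapping, NoiseSpec(model="powerlaw", beta=0.0, amplitude=1.0), 5)
        np.testing.assert_array_equal(rec.values, rec.noise)
        assert rec.noise.std() > 0

    def test_superposition_matches_event_accumulation_oracle(self, grid, rng):
        trains, templates, axons = _pool_recording_inputs(grid, rng, n_axons=5)
        H = rng.uniform(0.3, 1.0, (2, 5))
        mapping = compose_mapping(H)
        rec = record(axons, mapping, NoiseSpec(model="none"), rng)
        oracle = np.zeros((2, grid.n_samples))
        for e in range(2):
            for i, (train, tmpl) in enumerate(zip(trains, templates)):
                for tau in train.event_times:
                    start = grid.index_of(tau)
                    stop = min(start + tmpl.samples.size, grid.n_samples)
                    oracle[e, start:stop] += H[e, i] * tmpl.samples[: stop - start]
        np.testing.assert_allclose(rec.values, oracle, rtol=1e-12, atol=1e-9)

    def test_scaling_one_gain_scales_one_contribution(self, grid, rng):
        _, _, axons = _pool_recording_inputs(grid, rng, n_axons=2)
        base = record(
            axons, compose_mapping([[1.0, 0.0]]), NoiseSpec(model="none"), rng
        )
        scaled = record(
            axons, compose_mapping([[0.25, 0.0]]), NoiseSpec(model="none"), rng
        )
        np.testing.assert_allclose(scaled.values, 0.25 * base.values, atol=1e-12)

    def test_independent_noise_across_electrodes(self, rng):
        grid = TimeGrid(20_000.0, 2.0)
        axons = AxonSignals(grid, np.zeros((1, grid.n_samples)))
        mapping = compose_mapping([[1.0], [1.0]])
        rec = record(
            axons, mapping, NoiseSpec(model="powerlaw", beta=0.0, amplitude=1.0), 3
        )
        r = np.corrcoef(rec.noise[0], rec.noise[1])[0, 1]
        assert abs(r) < 0.05

    def test_shared_noise_mode_duplicates_the_trace(self, grid, rng):
        axons = AxonSignals(grid, np.zeros((1, grid.n_samples)))
        mapping = compose_mapping([[1.0], [1.0]])
        spec = NoiseSpec(
            model="powerlaw", beta=0.0, amplitude=1.0, shared_across_electrodes=True
        )
        rec = record(axons, mapping, spec, 3)
        np.testing.assert_array_equal(rec.noise[0], rec.noise[1])

    def test_file_noise_is_read_and_resampled(self, grid, rng, tmp_path):
        path = tmp_path / "noise.txt"
        values = np.sin(np.linspace(0, 20 * np.pi, 2000))
        path.write_text("sampling_rate=2000\n" + "\n".join(f"{v:.6f}" for v in values))
        axons = AxonSignals(grid, np.zeros((1, grid.n_samples)))
        rec = record(
            axons,
            compose_mapping([[1.0]]),
            NoiseSpec(model="file", path=str(path)),
            rng,
        )
        assert rec.noise[0].std() > 0.1
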
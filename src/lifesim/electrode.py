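"""Electrode mixing and additive noise.

The signal on each of ``l`` electrodes is a weighted sum of the axon
traces plus noise,

    z(t) = H y(t) + W(t),      H = C B,

where ``B`` (l x m) maps axons of a motor pool onto *virtual electrodes*
``v(t) = B y(t)`` — the crosstalk-free pool signals — and ``C`` (l x l)
mixes virtual electrodes into physical ones (crosstalk between motor
pools).  Gains near 1 represent close, unencapsulated fibers; distance,
drift and encapsulation are modeled as static attenuation (smaller gains).
For an intrafascicular electrode recording from a single pool, ``C`` is the
identity and ``H == B``.

Two noise generators are provided: power-law (1/f^beta) noise synthesized
spectrally, and band-limited Gaussian noise calibrated to a target SNR via
the percentile-span convention

    sigma_noise = (Q_99.9 - Q_0.1) / (3 SNR),

with the percentiles taken on the noise-free composite trace of each
electrode (per electrode, so an "average across electrodes" SNR target is
met automatically).  A noise time series can also be supplied from a file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import TimeGrid
from .errors import ConfigurationError, ValidationError
from .motoneuron import SpikeTrain
from .templates import AxonSignals

NOISE_MODELS = ("powerlaw", "gaussian_snr", "file", "none")


@dataclass
class ElectrodeMapping:
    """Mixing matrices: ``B`` (pool -> virtual electrodes), ``C`` (crosstalk),
    and the derived ``H = C B``."""

    B: np.ndarray
    C: np.ndarray
    H: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        l, m = self.B.shape
        if self.C.shape != (l, l):
            raise ValidationError(
                f"C must be {l} x {l} to match B with {l} rows; got {self.C.shape}"
            )
        for name, mat in (("B", self.B), ("C", self.C)):
            if not np.all(np.isfinite(mat)) or mat.min() < 0:
                raise ValidationError(f"{name} entries must be finite and >= 0")
        self.H = self.C @ self.B

    @property
    def n_electrodes(self) -> int:
        return self.B.shape[0]

    @property
    def n_axons(self) -> int:
        return self.B.shape[1]


def compose_mapping(B, C=None) -> ElectrodeMapping:
    """Build an :class:`ElectrodeMapping`; ``C`` defaults to the identity
    (negligible crosstalk), in which case ``H == B``."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if C is None:
        C = np.eye(B.shape[0])
    return ElectrodeMapping(B=B, C=C)


def virtual_signals(axons: AxonSignals, mapping: ElectrodeMapping) -> np.ndarray:
    """Pure pool signals ``v(t) = B y(t)`` (l x n_samples)."""
    if mapping.n_axons != axons.n_axons:
        raise ValidationError(
            f"B has {mapping.n_axons} columns but {axons.n_axons} axon traces given"
        )
    return mapping.B @ axons.values


def noise_sigma_from_snr(pure_electrode_trace: np.ndarray, snr: float) -> float:
    """Noise standard deviation for a target SNR.

    ``sigma = (Q_99.9 - Q_0.1) / (3 snr)`` with the percentiles computed
    empirically on the noise-free electrode trace.
    """
    if snr <= 0:
        raise ValidationError("snr must be positive")
    trace = np.asarray(pure_electrode_trace, dtype=float)
    q_hi, q_lo = np.percentile(trace, [99.9, 0.1])
    span = q_hi - q_lo
    if span <= 0:
        raise ValidationError(
            "percentile span of the pure trace is zero; SNR scaling undefined "
            "on a constant trace"
        )
    return float(span / (3.0 * snr))


@dataclass
class NoiseSpec:
    """Additive noise settings.

    model : {"powerlaw", "gaussian_snr", "file", "none"}
    beta : float
        Spectral exponent of 1/f^beta noise (powerlaw), >= 0.
    amplitude : float
        Output standard deviation of power-law noise, recording units.
    snr : float
        Target SNR (gaussian_snr), > 0, percentile-span convention.
    band : (low, high) Hz
        Passband of the Gaussian noise, within (0, Nyquist).
    shared_across_electrodes : bool
        If True all electrodes receive the same base noise realization
        (scaled per electrode for gaussian_snr); default independent.
    path : str
        Source file for model "file" (single column, rate header).
    """

    model: str = "gaussian_snr"
    beta: float = 0.0
    amplitude: float = 1.0
    snr: float = 3.0
    band: tuple[float, float] = (80.0, 4000.0)
    shared_across_electrodes: bool = False
    path: str | None = None

    def __post_init__(self) -> None:
        if self.model not in NOISE_MODELS:
            raise ConfigurationError(
                f"unknown noise model {self.model!r}; expected one of {NOISE_MODELS}"
            )
        if self.model == "powerlaw" and self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if self.model == "gaussian_snr":
            if self.snr <= 0:
                raise ValidationError("snr must be positive")
            low, high = self.band
            if not 0 < low < high:
                raise ValidationError("band must satisfy 0 < low < high")
        if self.model == "file" and not self.path:
            raise ConfigurationError("file noise model requires a path")


def generate_powerlaw_noise(
    spec: NoiseSpec, grid: TimeGrid, rng: np.random.Generator
) -> np.ndarray:
    """Synthesize 1/f^beta noise with standard deviation ``spec.amplitude``.

    White Gaussian noise is shaped in the frequency domain by
    ``|f|^(-beta/2)`` with the DC bin zeroed; using the real FFT keeps the
    spectrum Hermitian so the output is exactly real.  ``beta = 0`` reduces
    to (zero-mean) white noise.
    """
    n = grid.n_samples
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / grid.sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spec.beta / 2.0)
    out = np.fft.irfft(spectrum * shaping, n)
    sd = out.std()
    if sd == 0 or spec.amplitude == 0:
        return np.zeros(n)
    return out * (spec.amplitude / sd)


def _bandlimited_white(
    band: tuple[float, float], grid: TimeGrid, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited with a zero-phase filter."""
    low, high = band
    nyquist = grid.sampling_rate / 2.0
    if not 0 < low < high < nyquist:
        raise ValidationError(
            f"band {band} must lie within (0, {nyquist}) Hz"
        )
    white = rng.standard_normal(grid.n_samples)
    sos = butter(2, [low, high], btype="bandpass", output="sos", fs=grid.sampling_rate)
    shaped = sosfiltfilt(sos, white)
    return shaped / shaped.std()


def generate_gaussian_noise(
    spec: NoiseSpec,
    pure_trace: np.ndarray,
    grid: TimeGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise whose standard deviation realizes the
    requested SNR against ``pure_trace`` (exactly, by rescaling after
    filtering)."""
    sigma = noise_sigma_from_snr(pure_trace, spec.snr)
    return _bandlimited_white(spec.band, grid, rng) * sigma


def load_noise_file(path, grid: TimeGrid) -> np.ndarray:
    """Read a single-column noise trace with a ``sampling_rate=<Hz>`` header
    line and linearly interpolate it onto the grid."""
    with open(path) as fh:
        header = fh.readline().strip()
        if "=" not in header:
            raise ConfigurationError(
                "noise file must start with a 'sampling_rate=<Hz>' line"
            )
        rate = float(header.split("=", 1)[1])
        values = np.loadtxt(fh)
    src_t = np.arange(values.size) / rate
    return np.interp(grid.times, src_t, values)


@dataclass
class Recording:
    """Multi-electrode composite recording with full ground truth.

    ``values == pure + noise`` exactly, where ``pure = H y(t)``.  The
    contributing spike trains and mapping are retained so any downstream
    metric can be computed against known truth.
    """

    grid: TimeGrid
    values: np.ndarray
    pure: np.ndarray
    noise: np.ndarray
    mapping: ElectrodeMapping
    spike_trains: list[SpikeTrain] | None = None
    channel_labels: list[str] | None = None

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]


def record(
    axons: AxonSignals,
    mapping: ElectrodeMapping,
    noise: NoiseSpec,
    rng,
) -> Recording:
    """Assemble ``z(t) = H y(t) + W(t)``.

    ``rng`` may be a :class:`numpy.random.Generator` (noise streams drawn
    sequentially), an integer seed, or a :class:`numpy.random.SeedSequence`;
    with a seed/sequence each electrode gets an independent child stream, so
    adding an electrode never perturbs the noise of existing ones.
    """
    if mapping.n_axons != axons.n_axons:
        raise ValidationError(
            f"H has {mapping.n_axons} columns but {axons.n_axons} axon traces given"
        )
    pure = mapping.H @ axons.values
    l = mapping.n_electrodes
    if isinstance(rng, (int, np.integer)):
        rng = np.random.SeedSequence(int(rng))
    if isinstance(rng, np.random.SeedSequence):
        streams = [np.random.default_rng(child) for child in rng.spawn(l)]
    else:
        streams = [rng] * l

    noise_rows = np.zeros_like(pure)
    if noise.model == "none":
        pass
    elif noise.model == "file":
        trace = load_noise_file(noise.path, axons.grid)
        noise_rows = np.tile(trace, (l, 1))
    elif noise.model == "powerlaw":
        if noise.shared_across_electrodes:
            base = generate_powerlaw_noise(noise, axons.grid, streams[0])
            noise_rows = np.tile(base, (l, 1))
        else:
            for e in range(l):
                noise_rows[e] = generate_powerlaw_noise(noise, axons.grid, streams[e])
    else:  # gaussian_snr
        if noise.shared_across_electrodes:
            base = _bandlimited_white(noise.band, axons.grid, streams[0])
            for e in range(l):
                noise_rows[e] = base * noise_sigma_from_snr(pure[e], noise.snr)
        else:
            for e in range(l):
                noise_rows[e] = generate_gaussian_noise(
                    noise, pure[e], axons.grid, streams[e]
                )
    return Recording(
        grid=axons.grid,
        values=pure + noise_rows,
        pure=pure,
        noise=noise_rows,
        mapping=mapping,
    )
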
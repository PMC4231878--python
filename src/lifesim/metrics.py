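"""Analysis metrics for simulated recordings.

Covers the quantities used to characterize simulated data sets: percent
spike overlap and composite firing rate (collision statistics that stress
spike-detection-based decoders), band-pass filtering and Welch spectral
summaries, a moving-average intent decoder, and quiescent-phase amplitude
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt, welch

from .core import TimeGrid
from .errors import ValidationError
from .motoneuron import SpikeTrain


@dataclass
class OverlapResult:
    """Overlap statistics for one electrode at one steady intent level."""

    electrode_id: str
    intent_level: float
    percent_overlap: float
    composite_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_overlap <= 100.0:
            raise ValidationError("percent_overlap must lie in [0, 100]")
        if self.composite_rate < 0:
            raise ValidationError("composite_rate must be >= 0")


@dataclass
class SpectralSummary:
    """Welch-method summary of one trace over an analysis band."""

    total_power: float
    mean_frequency: float
    frequencies: np.ndarray
    psd: np.ndarray


def _occupancy(
    train: SpikeTrain, duration: float, grid: TimeGrid
) -> np.ndarray:
    """Boolean mask of samples where this axon's spike is present.

    A spike occupies the half-open window [event, event + duration), so
    back-to-back spikes never double-count a boundary sample.
    """
    n = grid.n_samples
    starts = np.round(train.event_times * grid.sampling_rate).astype(int)
    span = max(1, int(round(duration * grid.sampling_rate)))
    edges = np.zeros(n + 1, dtype=np.int64)
    np.add.at(edges, np.clip(starts, 0, n), 1)
    np.add.at(edges, np.clip(starts + span, 0, n), -1)
    return np.cumsum(edges[:-1]) > 0


def percent_overlap(
    trains: Sequence[SpikeTrain],
    durations: float | Sequence[float],
    grid: TimeGrid,
) -> float:
    """Percent of recording time with spikes present on >= 2 axons.

    ``durations`` gives each axon's template duration in seconds (a scalar
    applies to every axon).  Overlap is counted between *different* axons;
    a single train can never overlap with itself.
    """
    if len(trains) < 1:
        raise ValidationError("at least one train required")
    if np.isscalar(durations):
        durations = [float(durations)] * len(trains)
    if len(durations) != len(trains):
        raise ValidationError("one duration per train required")
    counts = np.zeros(grid.n_samples, dtype=np.int64)
    for train, dur in zip(trains, durations):
        counts += _occupancy(train, dur, grid)
    return float(np.mean(counts >= 2) * 100.0)


def composite_rate(trains: Sequence[SpikeTrain], window: float) -> float:
    """Total spike count across all axons divided by the window (seconds)."""
    if window <= 0:
        raise ValidationError("window must be positive")
    return float(sum(tr.n_events for tr in trains) / window)


def bandpass(
    trace: np.ndarray,
    low: float,
    high: float,
    grid: TimeGrid,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    ``order`` is the analog prototype order of the band-pass design (poles
    of a single pass); the filter is applied forward-backward so spike
    timing is unaffected and DC is rejected.
    """
    nyquist = grid.sampling_rate / 2.0
    if not 0 < low < high < nyquist:
        raise ValidationError(
            f"band ({low}, {high}) must satisfy 0 < low < high < {nyquist}"
        )
    if order < 2 or order % 2:
        raise ValidationError("order must be an even integer >= 2")
    sos = butter(
        order // 2, [low, high], btype="bandpass", output="sos", fs=grid.sampling_rate
    )
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def spectral_summary(
    trace: np.ndarray,
    grid: TimeGrid,
    band: tuple[float, float] | None = None,
    window_seconds: float = 0.5,
) -> SpectralSummary:
    """Welch PSD (0.5 s windows, 50% overlap) with band-limited summaries.

    ``total_power`` integrates the one-sided PSD over the analysis band
    (full band by default, so it estimates the trace variance); the mean
    frequency is the power-weighted mean over the same band.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_seconds * grid.sampling_rate))
    if trace.size < nperseg:
        raise ValidationError(
            f"trace of {trace.size} samples is shorter than one "
            f"{window_seconds} s window"
        )
    freqs, psd = welch(
        trace, fs=grid.sampling_rate, nperseg=nperseg, noverlap=nperseg // 2
    )
    if band is None:
        band = (0.0, grid.sampling_rate / 2.0)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        raise ValidationError("analysis band contains fewer than 2 PSD bins")
    f_b, p_b = freqs[mask], psd[mask]
    total = float(np.trapezoid(p_b, f_b))
    mean_f = float(np.trapezoid(f_b * p_b, f_b) / np.trapezoid(p_b, f_b))
    return SpectralSummary(
        total_power=total, mean_frequency=mean_f, frequencies=freqs, psd=psd
    )


def moving_average_decode(
    trace: np.ndarray,
    window: float,
    grid: TimeGrid,
    rectify: str = "square",
    normalize: bool = True,
) -> np.ndarray:
    """Moving-average intent decoder.

    The trace is rectified (squared by default, absolute value optionally),
    low-pass filtered with a boxcar of ``window`` seconds (edge samples use
    nearest-value padding so a constant input decodes to the same constant),
    and min-max normalized to [0, 1] over the trial.
    """
    k = int(round(window * grid.sampling_rate))
    if k < 2:
        raise ValidationError("window must span at least 2 samples")
    trace = np.asarray(trace, dtype=float)
    if rectify == "square":
        r = trace**2
    elif rectify == "abs":
        r = np.abs(trace)
    else:
        raise ValidationError("rectify must be 'square' or 'abs'")
    smoothed = uniform_filter1d(r, size=k, mode="nearest")
    if not normalize:
        return smoothed
    lo, hi = smoothed.min(), smoothed.max()
    if hi == lo:
        return np.zeros_like(smoothed)
    return (smoothed - lo) / (hi - lo)


def quiescent_normalize(trace: np.ndarray, quiescent_segment) -> np.ndarray:
    """Scale a trace by the standard deviation of its quiescent phase.

    ``quiescent_segment`` is a slice or an ``(start, stop)`` sample-index
    pair covering >= 100 samples of null motor intent.  After one
    application the quiescent standard deviation is exactly 1, so the
    operation is idempotent.
    """
    trace = np.asarray(trace, dtype=float)
    if isinstance(quiescent_segment, slice):
        segment = trace[quiescent_segment]
    else:
        start, stop = quiescent_segment
        segment = trace[int(start) : int(stop)]
    if segment.size < 100:
        raise ValidationError("quiescent segment must cover >= 100 samples")
    sd = segment.std()
    if sd == 0:
        raise ValidationError("quiescent segment has zero variance")
    return trace / sd
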
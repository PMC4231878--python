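"""Spike morphologies, templates, and axon-signal rendering.

An extracellular spike is modeled phenomenologically: a normalized
*morphology* (unit peak amplitude, support normalized to (0, 1)) is produced
by differentiating a Gaussian or Gamma kernel, then scaled in duration
(resampled onto the simulation grid) and amplitude into a *template*
``psi_i``.  Every template is constrained to the two properties of a
physical extracellular waveform: zero integral,

    sum_k psi_i[k] = 0   (to floating tolerance),

and finite energy ``sum_k psi_i[k]^2 < inf``.  Electrode geometry, tissue
filtering and fiber caliber are all folded into the template shape — there
is no biophysical forward model here by design.

The axon voltage trace is the superposition of template copies placed at
the spike event times (nearest-sample alignment; at 20 kHz the <= 25 us
placement jitter is far below the 2–6 ms template durations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gamma as gamma_dist

from .core import TimeGrid
from .errors import ValidationError
from .motoneuron import SpikeTrain

MORPHOLOGY_CLASSES = (
    "symmetric_1peak",
    "symmetric_2peak",
    "asymmetric_1peak",
    "custom",
)

#: Default kernel shape parameters (on the normalized (0, 1) support).
DEFAULT_SHAPE_PARAMS = {
    "gaussian": {"center": 0.5, "width": 0.1},
    "gamma": {"shape": 3.0, "scale": 0.08},
}


@dataclass
class SpikeMorphology:
    """Unit-normalized spike waveform on a normalized (0, 1) support.

    ``samples`` has max |value| == 1, zero discrete integral, and values in
    (-1, 1].  ``source`` records how it was synthesized.
    """

    samples: np.ndarray
    morphology_class: str = "custom"
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = self.samples.size
        if n < 2:
            raise ValidationError("morphology requires >= 2 samples")
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            raise ValidationError("morphology is identically zero")
        if abs(peak - 1.0) > 1e-9:
            raise ValidationError("morphology must be peak-normalized to 1")
        if abs(self.samples.sum()) > 1e-9 * n:
            raise ValidationError("morphology must have zero discrete integral")
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise ValidationError(
                f"unknown morphology class {self.morphology_class!r}"
            )

    @property
    def support(self) -> np.ndarray:
        """Normalized sample positions, midpoints of (0, 1) bins."""
        n = self.samples.size
        return (np.arange(n) + 0.5) / n


def _normalize(w: np.ndarray) -> np.ndarray:
    """Zero-mean then peak-normalize; the order guarantees both properties."""
    w = w - w.mean()
    peak = np.max(np.abs(w))
    if peak == 0 or not np.isfinite(peak):
        raise ValidationError("waveform is numerically degenerate (all zero)")
    return w / peak


def _classify(w: np.ndarray) -> str:
    """Assign a morphology class by peak/trough count and mirror symmetry."""
    peaks, _ = find_peaks(w, height=0.15)
    troughs, _ = find_peaks(-w, height=0.15)
    rev = w[::-1]
    symmetric = min(np.max(np.abs(w - rev)), np.max(np.abs(w + rev))) < 0.05
    n_p, n_t = len(peaks), len(troughs)
    if symmetric and n_p == 1 and n_t == 1:
        return "symmetric_1peak"
    if symmetric and n_p == 2 and n_t == 2:
        return "symmetric_2peak"
    if not symmetric and n_p == 1 and n_t == 1:
        return "asymmetric_1peak"
    return "custom"


def make_morphology(
    kernel: str = "gaussian",
    derivative_order: int = 1,
    shape_params: Mapping[str, float] | None = None,
    n_points: int = 256,
) -> SpikeMorphology:
    """Synthesize a normalized morphology by differentiating a kernel.

    Parameters
    ----------
    kernel : {"gaussian", "gamma"}
        A centered Gaussian bump yields mirror-symmetric wavelets (first
        derivative: one peak/one trough; third: two of each); the skewed
        Gamma density yields asymmetric wavelets.
    derivative_order : int
        Number of differentiations, >= 1.
    shape_params : mapping, optional
        Gaussian: ``center``, ``width`` (sigma) on the (0, 1) support.
        Gamma: ``shape``, ``scale``.
    n_points : int
        Samples on the normalized support, >= 16.
    """
    if derivative_order < 1:
        raise ValidationError("derivative_order must be >= 1")
    if n_points < 16:
        raise ValidationError("n_points must be >= 16")
    params = dict(DEFAULT_SHAPE_PARAMS.get(kernel, {}))
    if shape_params:
        params.update(shape_params)
    s = (np.arange(n_points) + 0.5) / n_points
    if kernel == "gaussian":
        center, width = params["center"], params["width"]
        if width <= 0:
            raise ValidationError("gaussian width must be positive")
        base = np.exp(-0.5 * ((s - center) / width) ** 2)
    elif kernel == "gamma":
        base = gamma_dist.pdf(s, a=params["shape"], scale=params["scale"])
    else:
        raise ValidationError(f"unknown kernel {kernel!r}")
    w = base
    ds = 1.0 / n_points
    for _ in range(derivative_order):
        w = np.gradient(w, ds)
    w = _normalize(w)
    return SpikeMorphology(
        samples=w,
        morphology_class=_classify(w),
        source={
            "kernel": kernel,
            "derivative_order": int(derivative_order),
            "shape_params": params,
        },
    )


@dataclass
class SpikeTemplate:
    """A morphology scaled to physical duration and amplitude on a grid.

    ``samples`` holds ``round(duration * sampling_rate)`` values whose peak
    |value| equals ``amplitude`` (arbitrary recording units) and whose sum
    is zero to floating tolerance.
    """

    template_id: str
    morphology: SpikeMorphology
    amplitude: float
    duration: float
    samples: np.ndarray

    @property
    def energy(self) -> float:
        """Discrete waveform energy, sum of squared samples."""
        return float(np.sum(self.samples**2))


def scale_template(
    morphology: SpikeMorphology,
    amplitude: float,
    duration: float,
    grid: TimeGrid,
    template_id: str = "",
) -> SpikeTemplate:
    """Resample a morphology to ``duration`` seconds at the grid rate and
    rescale its peak to ``amplitude``.

    The resampled waveform is re-zero-meaned before peak scaling so the
    zero-integral property holds on the simulation grid, not just on the
    normalized support.
    """
    if amplitude <= 0:
        raise ValidationError("amplitude must be positive")
    n_t = int(round(duration * grid.sampling_rate))
    if n_t < 2:
        raise ValidationError(
            f"duration {duration} s is below 2 samples at "
            f"{grid.sampling_rate} Hz"
        )
    target_s = (np.arange(n_t) + 0.5) / n_t
    resampled = np.interp(target_s, morphology.support, morphology.samples)
    resampled = resampled - resampled.mean()
    peak = np.max(np.abs(resampled))
    if peak == 0:
        raise ValidationError("resampled template is degenerate")
    samples = resampled * (amplitude / peak)
    return SpikeTemplate(
        template_id=template_id,
        morphology=morphology,
        amplitude=float(amplitude),
        duration=float(duration),
        samples=samples,
    )


@dataclass
class AxonSignals:
    """Per-axon extracellular traces ``y(t)`` (m x n_samples, recording units)."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.n_samples:
            raise ValidationError("signal length must equal grid.n_samples")

    @property
    def n_axons(self) -> int:
        return self.values.shape[0]


def render_axon_signal(
    train: SpikeTrain, template: SpikeTemplate, grid: TimeGrid
) -> np.ndarray:
    """Superpose template copies at the train's event times.

    Each copy starts at the nearest grid sample to its event time and is
    truncated at the recording boundary.  Superposition is purely additive:
    coincident events sum constructively (one double-amplitude spike).
    """
    out = np.zeros(grid.n_samples)
    tmpl = template.samples
    n = grid.n_samples
    for tau in train.event_times:
        start = int(round(tau * grid.sampling_rate))
        if start >= n:
            continue
        stop = min(start + tmpl.size, n)
        out[start:stop] += tmpl[: stop - start]
    return out


def render_pool(
    trains: Sequence[SpikeTrain],
    templates: Sequence[SpikeTemplate],
    grid: TimeGrid,
) -> AxonSignals:
    """Render every axon of a pool; row i is axon i's trace."""
    if len(trains) != len(templates):
        raise ValidationError("one template per train required")
    if not trains:
        raise ValidationError("at least one train required")
    values = np.vstack(
        [render_axon_signal(tr, tm, grid) for tr, tm in zip(trains, templates)]
    )
    return AxonSignals(grid, values)
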
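"""Motoneuron recruitment, rate coding, and point-process spike timing.

Each motoneuron carries a piecewise-linear input/output curve with a
recruitment threshold and saturation,

    f(x) = 0                           for x <= x_thr,
    f(x) = f_thr + kappa_f (x - x_thr) for x_thr < x < x_sat,
    f(x) = f_sat                       for x >= x_sat,

with slope ``kappa_f = (f_sat - f_thr) / (x_sat - x_thr)``.  A unit is
recruited strictly above its threshold, so a pool whose thresholds are
staggered by fiber type reproduces orderly (size-principle) recruitment:
small S units first, FF units only at high drive.

Spike timing is realized sequentially: from the current time the rate
``f(x(t))`` fixes the mean interspike interval ``xi = 1/f`` and one of five
point processes draws the next interval (identity = regular train, Poisson =
exponential ISI, truncated Gaussian, Gamma, or uniform jitter).  The rate is
frozen at the time of the previous event — a standard approximation for
slowly varying drive — and the first event falls one drawn interval after
recruitment onset.  All stochastic intervals are floored at 1 ms (clipped,
not resampled, so the mean interval is essentially unbiased) to keep one
axon from overlapping itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import TimeGrid
from .errors import ConfigurationError, ValidationError

#: Minimum interspike interval in seconds applied to stochastic draws.
DEFAULT_ISI_FLOOR = 1e-3

POINT_PROCESS_KINDS = ("identity", "poisson", "truncated_gaussian", "gamma", "uniform")

FIBER_TYPES = ("S", "FR", "FF")


@dataclass(frozen=True)
class FiringCurve:
    """Piecewise-linear activation-to-rate curve.

    Parameters
    ----------
    x_thr, x_sat : float
        Recruitment threshold and saturation activation, ``0 <= x_thr <
        x_sat <= 1`` (unitless normalized activation).
    f_thr, f_sat : float
        Firing rate at recruitment and at saturation, Hz, ``0 < f_thr <=
        f_sat``.
    """

    x_thr: float
    x_sat: float
    f_thr: float
    f_sat: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_thr < self.x_sat <= 1.0):
            raise ValidationError(
                f"require 0 <= x_thr < x_sat <= 1; got x_thr={self.x_thr}, "
                f"x_sat={self.x_sat}"
            )
        if not (0.0 < self.f_thr <= self.f_sat):
            raise ValidationError(
                f"require 0 < f_thr <= f_sat; got f_thr={self.f_thr}, "
                f"f_sat={self.f_sat}"
            )

    @property
    def slope(self) -> float:
        """Rate gain ``kappa_f`` in Hz per unit activation."""
        return (self.f_sat - self.f_thr) / (self.x_sat - self.x_thr)


def rate_slope(curve: FiringCurve) -> float:
    """Slope of the input/output curve, ``(f_sat - f_thr)/(x_sat - x_thr)``."""
    return curve.slope


def firing_rate(curve: FiringCurve, x):
    """Mean instantaneous firing rate, Hz, for activation ``x``.

    Vectorized over ``x``.  The result is 0 at or below threshold (a unit
    is recruited strictly above ``x_thr``), ``f_sat`` at or above
    saturation, and linear in between, so the attained rates form
    ``{0} ∪ (f_thr, f_sat]``.
    """
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValidationError("activation must be finite")
    mid = curve.f_thr + curve.slope * (x_arr - curve.x_thr)
    out = np.where(
        x_arr <= curve.x_thr, 0.0, np.where(x_arr >= curve.x_sat, curve.f_sat, mid)
    )
    if np.isscalar(x) or getattr(x, "ndim", 1) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PointProcessSpec:
    """Which ISI distribution times the spikes, and its spread.

    ``dispersion`` is the ISI standard deviation sigma in seconds
    (truncated_gaussian and gamma); ``width`` is the full width w in seconds
    of the uniform jitter window.  The mean ISI is supplied at draw time.
    """

    kind: str = "poisson"
    dispersion: float | None = None
    width: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in POINT_PROCESS_KINDS:
            raise ConfigurationError(
                f"unknown point process {self.kind!r}; "
                f"expected one of {POINT_PROCESS_KINDS}"
            )
        if self.kind in ("truncated_gaussian", "gamma"):
            if self.dispersion is None or self.dispersion <= 0:
                raise ValidationError(f"{self.kind} requires dispersion > 0")
        if self.kind == "uniform":
            if self.width is None or self.width < 0:
                raise ValidationError("uniform requires width >= 0")


def draw_isi(
    spec: PointProcessSpec,
    mean_isi: float,
    rng: np.random.Generator,
    size: int | None = None,
    isi_floor: float = DEFAULT_ISI_FLOOR,
):
    """Draw interspike interval(s) with the given mean.

    Returns a float when ``size`` is None, else an array of ``size`` draws.
    Stochastic draws are clipped to ``isi_floor``; the identity process is
    exempt (it is exact by construction for rates <= 1/floor).
    """
    mean_isi = float(mean_isi)
    if mean_isi <= 0:
        raise ValidationError("mean_isi must be positive")
    n = 1 if size is None else int(size)
    if spec.kind == "identity":
        out = np.full(n, mean_isi)
    elif spec.kind == "poisson":
        out = rng.exponential(mean_isi, size=n)
    elif spec.kind == "truncated_gaussian":
        out = rng.normal(mean_isi, spec.dispersion, size=n)
    elif spec.kind == "gamma":
        # mean xi, sd sigma  ->  shape (xi/sigma)^2, scale sigma^2/xi
        shape = (mean_isi / spec.dispersion) ** 2
        scale = spec.dispersion**2 / mean_isi
        out = rng.gamma(shape, scale, size=n)
    else:  # uniform
        half = spec.width / 2.0
        out = rng.uniform(mean_isi - half, mean_isi + half, size=n)
    if spec.kind != "identity":
        out = np.maximum(out, isi_floor)
    if size is None:
        return float(out[0])
    return out


@dataclass
class MotoneuronSpec:
    """Full description of one motoneuron.

    ``template_id`` names the spike template rendered for this axon;
    ``spike_duration`` (s) and ``spike_amplitude`` (recording units) are the
    template scaling parameters carried alongside so a pool table is
    self-contained.
    """

    curve: FiringCurve
    process: PointProcessSpec
    template_id: str
    fiber_type: str = "S"
    spike_duration: float | None = None
    spike_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.fiber_type not in FIBER_TYPES:
            raise ValidationError(
                f"fiber_type must be one of {FIBER_TYPES}; got {self.fiber_type!r}"
            )


@dataclass
class SpikeTrain:
    """Sorted spike event times (seconds) of one axon within [0, T]."""

    event_times: np.ndarray
    motoneuron_id: str
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size:
            if np.any(np.diff(self.event_times) <= 0):
                raise ValidationError("event times must be strictly increasing")
            if self.event_times[0] < 0 or self.event_times[-1] > self.grid.duration:
                raise ValidationError("event times must lie within [0, T]")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


def generate_spike_times(
    mn: MotoneuronSpec,
    activation_row: np.ndarray,
    grid: TimeGrid,
    rng: np.random.Generator,
    isi_floor: float = DEFAULT_ISI_FLOOR,
) -> SpikeTrain:
    """Realize one spike train from an activation time series.

    Sequential-ISI construction: starting at t = 0, silent stretches
    (f = 0) are skipped to the next recruited sample; from a recruited time
    the rate is evaluated, an interval with mean 1/f is drawn, and the next
    event is placed one interval later.  Events beyond T are discarded.
    """
    activation_row = np.asarray(activation_row, dtype=float)
    if activation_row.size != grid.n_samples:
        raise ValidationError("activation_row length must equal grid.n_samples")
    f = firing_rate(mn.curve, activation_row)
    active_idx = np.flatnonzero(f > 0)
    if active_idx.size == 0:
        return SpikeTrain(np.empty(0), mn.template_id, grid)

    fs = grid.sampling_rate
    n = grid.n_samples
    events: list[float] = []
    t = 0.0
    while True:
        i = min(int(round(t * fs)), n - 1)
        if f[i] <= 0:
            pos = np.searchsorted(active_idx, i)
            if pos >= active_idx.size:
                break
            i = int(active_idx[pos])
            t = i / fs
        isi = draw_isi(mn.process, 1.0 / f[i], rng, isi_floor=isi_floor)
        t = t + isi
        if t > grid.duration:
            break
        events.append(t)
    return SpikeTrain(np.asarray(events), mn.template_id, grid)


_RANGE_KEYS = ("duration", "amplitude", "f_thr", "f_sat", "x_thr", "x_sat")


def sample_pool(
    ranges: Mapping[str, Sequence[float]],
    count: int,
    fiber_type: str,
    rng: np.random.Generator,
    process: PointProcessSpec | None = None,
    id_prefix: str | None = None,
    max_redraws: int = 100,
) -> list[MotoneuronSpec]:
    """Draw a pool of motoneurons, each parameter uniform within its range.

    ``ranges`` maps each of ``duration`` (s), ``amplitude`` (recording
    units), ``f_thr``, ``f_sat`` (Hz), ``x_thr``, ``x_sat`` (unitless) to a
    ``(low, high)`` pair.  Draws violating the firing-curve invariants
    (``x_thr < x_sat``, ``f_thr <= f_sat``) are redrawn pairwise up to
    ``max_redraws`` times, which preserves the marginal uniformity of valid
    configurations; persistent violation raises :class:`ConfigurationError`.
    """
    if count < 1:
        raise ValidationError("count must be >= 1")
    for key in _RANGE_KEYS:
        if key not in ranges:
            raise ConfigurationError(f"missing range for {key!r}")
        low, high = ranges[key]
        if low > high:
            raise ConfigurationError(f"range for {key!r} has low > high")
    if process is None:
        process = PointProcessSpec(kind="poisson")
    prefix = id_prefix if id_prefix is not None else fiber_type

    def _uniform(key: str) -> float:
        low, high = ranges[key]
        return float(rng.uniform(low, high))

    specs = []
    for k in range(count):
        x_thr, x_sat = _uniform("x_thr"), _uniform("x_sat")
        for _ in range(max_redraws):
            if x_thr < x_sat:
                break
            x_thr, x_sat = _uniform("x_thr"), _uniform("x_sat")
        else:
            raise ConfigurationError(
                "could not satisfy x_thr < x_sat from the given ranges"
            )
        f_thr, f_sat = _uniform("f_thr"), _uniform("f_sat")
        for _ in range(max_redraws):
            if f_thr <= f_sat:
                break
            f_thr, f_sat = _uniform("f_thr"), _uniform("f_sat")
        else:
            raise ConfigurationError(
                "could not satisfy f_thr <= f_sat from the given ranges"
            )
        specs.append(
            MotoneuronSpec(
                curve=FiringCurve(x_thr=x_thr, x_sat=x_sat, f_thr=f_thr, f_sat=f_sat),
                process=process,
                template_id=f"{prefix}{k:02d}",
                fiber_type=fiber_type,
                spike_duration=_uniform("duration"),
                spike_amplitude=_uniform("amplitude"),
            )
        )
    return specs
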
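"""Time grids, motor-intent waveforms, and the intent-to-activation map.

Motor intent is modeled as an ``n``-dimensional command signal ``u(t)`` whose
components are unitless efforts normalized to [0, 1] (1 = maximum intended
effort), one component per controlled degree of freedom (DOF).  A gain matrix
``G`` (``m x n``, ``m >= n``) distributes the intent components over the ``m``
motoneurons of the simulated pools,

    x(t) = G u(t),

where ``x(t)`` is the vector of motoneuron activation states — normalized
surrogates for the membrane potential at the spike-initiation zone.  Uniform
entries within a row of ``G`` give every motoneuron in a pool an identical
drive; unequal entries model uneven synaptic input.

All components of a simulation run share a single uniform :class:`TimeGrid`.
The default sampling rate is 20 kHz, which satisfies Nyquist for
extracellular spike waveforms (roughly 100 Hz – 10 kHz bandwidth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Default sampling rate in samples/second.
DEFAULT_SAMPLING_RATE = 20_000.0

WAVEFORM_KINDS = (
    "constant",
    "ramp",
    "ramp_and_hold",
    "square",
    "sinusoid",
    "piecewise",
    "file",
)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid over the simulation interval [0, T].

    Parameters
    ----------
    sampling_rate : float
        Samples per second.
    duration : float
        Length T of the simulated interval, in seconds.
    """

    sampling_rate: float = DEFAULT_SAMPLING_RATE
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t_k = k / sampling_rate``."""
        return np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Nearest-sample index of time ``t`` (may equal ``n_samples`` at T)."""
        return int(round(t * self.sampling_rate))


@dataclass
class IntentTrajectory:
    """A single-DOF intent trace on a grid; values lie in [0, 1]."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.grid.n_samples:
            raise ValidationError(
                "trajectory length must equal grid.n_samples "
                f"({self.values.size} != {self.grid.n_samples})"
            )


@dataclass
class MotorIntent:
    """Multi-DOF normalized intent trajectories ``u(t)`` on a shared grid.

    ``values`` is an ``n x n_samples`` array with every entry in [0, 1];
    row ``i`` is the trajectory for DOF ``dof_labels[i]``.
    """

    grid: TimeGrid
    values: np.ndarray
    dof_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValidationError("MotorIntent requires at least one DOF")
        if self.values.shape[1] != self.grid.n_samples:
            raise ValidationError("intent length must equal grid.n_samples")
        if len(self.dof_labels) != self.values.shape[0]:
            raise ValidationError("one label per DOF required")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValidationError("intent values must lie in [0, 1]")

    @property
    def n_dof(self) -> int:
        return self.values.shape[0]


@dataclass
class IntentMapping:
    """Intent-to-motoneuron gain matrix ``G`` (``m x n``, ``m >= n``)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        m, n = self.matrix.shape
        if m < n:
            raise ValidationError(
                f"G must have at least as many rows (motoneurons) as columns "
                f"(DOFs); got {m} x {n}"
            )
        if not np.all(np.isfinite(self.matrix)) or self.matrix.min() < 0:
            raise ValidationError("G entries must be finite and >= 0")

    @property
    def n_motoneurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dof(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ActivationState:
    """Motoneuron activation ``x(t)``; 1 = maximum activation."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("activation values must be finite")
        if self.values.shape[1] != self.grid.n_samples:
            raise ValidationError("activation length must equal grid.n_samples")


def _check_amplitude(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1]; got {value}")
    return value


def generate_intent(waveform_spec: Mapping, grid: TimeGrid) -> IntentTrajectory:
    """Generate one single-DOF intent trajectory from a structured spec.

    Parameters
    ----------
    waveform_spec : mapping
        ``{"kind": <one of constant | ramp | ramp_and_hold | square |
        sinusoid | piecewise | file>, ...parameters}``.  Amplitude-like
        parameters must lie in [0, 1]; the output is clipped to [0, 1].
    grid : TimeGrid

    Returns
    -------
    IntentTrajectory

    Notes
    -----
    The default ramp endpoints are the first and last *samples* of the grid,
    so a full-scale ramp attains exactly 0 at t = 0 and exactly 1 at the
    final sample.
    """
    spec = dict(waveform_spec)
    try:
        kind = spec.pop("kind")
    except KeyError:
        raise ConfigurationError("waveform spec requires a 'kind' entry") from None
    if kind not in WAVEFORM_KINDS:
        raise ConfigurationError(
            f"unknown waveform kind {kind!r}; expected one of {WAVEFORM_KINDS}"
        )
    t = grid.times
    t_last = t[-1] if t.size else 0.0

    if kind == "constant":
        value = _check_amplitude(spec.pop("value", 0.0), "value")
        u = np.full(grid.n_samples, value)
    elif kind == "ramp":
        start = _check_amplitude(spec.pop("start", 0.0), "start")
        end = _check_amplitude(spec.pop("end", 1.0), "end")
        t0 = float(spec.pop("t_start", 0.0))
        t1 = float(spec.pop("t_end", t_last))
        if t1 <= t0:
            raise ValidationError("ramp requires t_end > t_start")
        u = np.interp(t, [t0, t1], [start, end])
    elif kind == "ramp_and_hold":
        amp = _check_amplitude(spec.pop("amplitude", 1.0), "amplitude")
        rise = float(spec.pop("rise_time", 1.0))
        t0 = float(spec.pop("t_start", 0.0))
        hold_until = float(spec.pop("hold_until", t_last))
        fall = float(spec.pop("fall_time", 0.0))
        if rise <= 0:
            raise ValidationError("rise_time must be positive")
        knots_t = [t0, t0 + rise, hold_until]
        knots_u = [0.0, amp, amp]
        if fall > 0:
            knots_t.append(hold_until + fall)
            knots_u.append(0.0)
        u = np.interp(t, knots_t, knots_u)
    elif kind == "square":
        amp = _check_amplitude(spec.pop("amplitude", 1.0), "amplitude")
        base = _check_amplitude(spec.pop("baseline", 0.0), "baseline")
        period = float(spec.pop("period"))
        duty = float(spec.pop("duty", 0.5))
        t0 = float(spec.pop("t_start", 0.0))
        t1 = float(spec.pop("t_end", grid.duration))
        if period <= 0 or not 0 < duty < 1:
            raise ValidationError("square requires period > 0 and 0 < duty < 1")
        phase = (t - t0) % period
        u = np.where(
            (t >= t0) & (t < t1) & (phase < duty * period), amp, base
        )
    elif kind == "sinusoid":
        amp = _check_amplitude(spec.pop("amplitude", 0.5), "amplitude")
        offset = _check_amplitude(spec.pop("offset", 0.5), "offset")
        freq = float(spec.pop("frequency"))
        phase = float(spec.pop("phase", 0.0))
        u = offset + amp * np.sin(2.0 * np.pi * freq * t + phase)
    elif kind == "piecewise":
        knots_t = np.asarray(spec.pop("times"), dtype=float)
        knots_u = np.asarray(spec.pop("values"), dtype=float)
        if knots_t.size != knots_u.size or knots_t.size < 2:
            raise ValidationError("piecewise requires matching times/values, >= 2 knots")
        if knots_u.min() < 0 or knots_u.max() > 1:
            raise ValidationError("piecewise values must lie in [0, 1]")
        u = np.interp(t, knots_t, knots_u)
    else:  # file
        u = _read_intent_file(
            spec.pop("path"),
            grid,
            column=spec.pop("column", None),
            sampling_rate=spec.pop("sampling_rate", None),
        )
    return IntentTrajectory(grid, np.clip(u, 0.0, 1.0))


def _read_intent_file(
    path,
    grid: TimeGrid,
    column: str | int | None = None,
    sampling_rate: float | None = None,
) -> np.ndarray:
    """Read one DOF from a delimited text file (header row of DOF labels).

    The file is assumed uniformly sampled at ``sampling_rate`` (grid rate if
    omitted) starting at t = 0 and is linearly interpolated onto the grid.
    """
    import pandas as pd

    table = pd.read_csv(path, sep=None, engine="python")
    if table.shape[1] < 1:
        raise ConfigurationError(f"intent file {path} has no columns")
    if column is None:
        series = table.iloc[:, 0]
    elif isinstance(column, int):
        series = table.iloc[:, column]
    else:
        if column not in table.columns:
            raise ConfigurationError(
                f"intent file {path} has no column {column!r}"
            )
        series = table[column]
    values = np.asarray(series, dtype=float)
    rate = float(sampling_rate) if sampling_rate else grid.sampling_rate
    src_t = np.arange(values.size) / rate
    return np.interp(grid.times, src_t, values)


def assemble_multi_dof(
    trajectories: Sequence[IntentTrajectory],
    labels: Sequence[str] | None = None,
) -> MotorIntent:
    """Stack single-DOF trajectories (shared grid) into a :class:`MotorIntent`."""
    if not trajectories:
        raise ValidationError("at least one trajectory required")
    grid = trajectories[0].grid
    for traj in trajectories[1:]:
        if traj.grid != grid:
            raise ValidationError("all trajectories must share one grid")
    if labels is None:
        labels = [f"dof{i}" for i in range(len(trajectories))]
    values = np.vstack([traj.values for traj in trajectories])
    return MotorIntent(grid, values, list(labels))


def map_intent_to_activation(
    intent: MotorIntent, mapping: IntentMapping
) -> ActivationState:
    """Apply ``x(t) = G u(t)`` per time sample.

    Activation above 1 (possible when G row sums exceed 1) is clipped to the
    normalized maximum with a logged warning; the firing-rate curves are
    defined on [0, 1].
    """
    if mapping.n_dof != intent.n_dof:
        raise ValidationError(
            f"G has {mapping.n_dof} columns but intent has {intent.n_dof} DOFs"
        )
    x = mapping.matrix @ intent.values
    over = x > 1.0
    if over.any():
        logger.warning(
            "activation exceeded 1 on %d samples; clipping to 1", int(over.sum())
        )
        x = np.minimum(x, 1.0)
    return ActivationState(intent.grid, x)


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG stream for (master seed, integer key path).

    Streams with distinct key paths are statistically independent, so adding
    electrodes (which consume noise streams) never perturbs spike trains
    (which consume per-motoneuron streams).
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    )
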
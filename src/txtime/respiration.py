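"""Synthetic respiratory signal and amplitude-based gate schedules.

The default breathing surrogate is a three-component sinusoidal model of a
regular breathing trace,

    Sig(x) = [sin(x) + sin(2x + 0.7*pi) + sin(2x + pi) - 5.4] / 2,

evaluated at the normalized phase ``x = 2*pi*t / T_R`` for respiratory period
``T_R``.  The absolute offset is irrelevant to gating, which is purely
threshold-based: the beam is permitted while the signal is at or below an
amplitude threshold (end-exhale gating, the clinical norm for liver; the
sense is configurable).  The threshold is usually specified indirectly as a
gating duty cycle — the fraction of each period the gate is open — and
converted by :func:`threshold_for_duty`.

The signal function is injectable via :class:`RespiratoryModel` so an
alternative surrogate (or an alternative reading of the formula above)
changes one line; everything downstream only consumes gate intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "GateError",
    "default_signal",
    "RespiratoryModel",
    "GateConfig",
    "GateSchedule",
    "breathing_signal",
    "threshold_for_duty",
    "gate_intervals",
]

#: grid density (samples per period) for threshold search and crossing bracketing
_GRID = 20000


class GateError(ValueError):
    """Gate configuration that can never open the beam, or an inconsistent schedule."""


def default_signal(x):
    """Three-component sinusoidal breathing surrogate at normalized phase x (rad)."""
    return (np.sin(x) + np.sin(2 * x + 0.7 * np.pi) + np.sin(2 * x + np.pi) - 5.4) / 2.0


@dataclass(frozen=True)
class RespiratoryModel:
    """Periodic breathing surrogate: period T_R in s plus a 2*pi-periodic signal."""

    period: float = 4.0
    signal: Callable[[float], float] = field(default=default_signal)

    def __post_init__(self) -> None:
        if not (self.period > 0):
            raise GateError(f"respiratory period must be > 0, got {self.period!r}")


def breathing_signal(t, model: RespiratoryModel):
    """Evaluate the surrogate amplitude at time t (s); accepts arrays."""
    x = 2.0 * np.pi * np.asarray(t) / model.period
    return model.signal(x)


@dataclass(frozen=True)
class GateConfig:
    """Amplitude gating setup.

    Either a ``duty`` fraction in (0, 1] (threshold derived per period) or an
    explicit amplitude ``threshold``.  ``beam_on_below=True`` (default) opens
    the gate while the signal is <= threshold.
    """

    mode: str = "duty_cycle"  # or "threshold"
    duty: float | None = 0.3
    threshold: float | None = None
    beam_on_below: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("duty_cycle", "threshold"):
            raise GateError(f"mode must be 'duty_cycle' or 'threshold', got {self.mode!r}")
        if self.mode == "duty_cycle":
            if self.duty is None or not (0 < self.duty <= 1):
                raise GateError(f"duty must be in (0, 1], got {self.duty!r}")
        elif self.threshold is None:
            raise GateError("threshold mode requires a threshold amplitude")


@dataclass(frozen=True)
class GateSchedule:
    """Beam-permitted windows of a periodic gate.

    ``base_intervals`` are the on-windows within one period ``[0, T_R)``
    (half-open, non-wrapping pieces; a window crossing the period seam is
    split and re-merged when tiling).  ``intervals`` concretize the pattern
    over ``[0, horizon)``.  :meth:`windows` yields the unbounded tiled stream,
    optionally phase-shifted, for the delivery simulator.
    """

    period: float
    base_intervals: tuple[tuple[float, float], ...]
    horizon: float
    intervals: tuple[tuple[float, float], ...]
    duty_achieved: float

    def windows(self, offset: float = 0.0) -> Iterator[tuple[float, float]]:
        """Infinite stream of on-windows in simulation time.

        Simulation time ``t`` corresponds to respiratory time ``t + offset``;
        windows are therefore shifted left by ``offset``, clipped at 0, and
        windows contiguous across the period seam are merged.
        """
        yield from _tile(self.base_intervals, self.period, offset)

    def is_on(self, t: float) -> bool:
        """Gate state at respiratory time t (half-open [start, end) windows)."""
        tm = t % self.period
        return any(s <= tm < e for s, e in self.base_intervals)


def _tile(
    base: tuple[tuple[float, float], ...], period: float, offset: float = 0.0
) -> Iterator[tuple[float, float]]:
    """Tile one-period on-windows periodically, shifted left by ``offset``.

    Windows contiguous across the period seam are merged; output is clipped
    to t >= 0 in simulation time.
    """
    if not base:
        return
    if len(base) == 1 and base[0][0] <= 0.0 and base[0][1] >= period:
        yield (0.0, math.inf)  # always-on gate
        return
    pending: tuple[float, float] | None = None
    k = math.floor(offset / period) - 1
    while True:
        for s, e in base:
            ws, we = s + k * period - offset, e + k * period - offset
            if we <= 0:
                continue
            ws = max(ws, 0.0)
            if pending is not None:
                if ws - pending[1] <= 1e-12:  # contiguous across seam
                    pending = (pending[0], we)
                    continue
                yield pending
            pending = (ws, we)
        k += 1


def threshold_for_duty(model: RespiratoryModel, duty: float) -> float:
    """Amplitude threshold tau such that Sig <= tau for ``duty`` of each period.

    Bisection on tau against the occupancy fraction measured on a dense
    (>= 10^4 samples/period) grid; the recovered duty is within ~1/_GRID of
    the request.  ``duty = 1`` returns the sampled per-period maximum.
    """
    if not (0 < duty <= 1):
        raise GateError(f"duty must be in (0, 1], got {duty!r}")
    x = np.linspace(0.0, 2 * np.pi, _GRID, endpoint=False)
    s = np.asarray(model.signal(x), dtype=float)
    lo, hi = float(s.min()), float(s.max())
    if duty >= 1.0:
        # margin covers the sampled maximum's grid error: gate is always open
        return hi + 1e-6
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(s <= mid))
        if frac < duty:
            lo = mid
        else:
            hi = mid
    return hi


def _refine_crossing(f: Callable[[float], float], a: float, b: float) -> float:
    """Bisection root of sign-changing f on [a, b] to 1e-9 s."""
    fa = f(a)
    for _ in range(64):
        m = 0.5 * (a + b)
        fm = f(m)
        if (fa <= 0) == (fm <= 0):
            a, fa = m, fm
        else:
            b = m
        if b - a < 1e-9:
            break
    return 0.5 * (a + b)


def gate_intervals(model: RespiratoryModel, config: GateConfig, horizon: float) -> GateSchedule:
    """Beam-permitted intervals of ``[0, horizon)`` under amplitude gating.

    The on-region of one period is located on a dense grid and its boundaries
    refined by bisection (sub-microsecond), then tiled exactly periodically
    over the horizon.  Raises :class:`GateError` if the gate never opens.
    """
    if not (horizon > 0):
        raise GateError(f"horizon must be > 0, got {horizon!r}")
    if config.mode == "duty_cycle":
        tau = threshold_for_duty(model, config.duty)
        if config.duty >= 1.0:
            full = ((0.0, horizon),)
            return GateSchedule(
                period=model.period,
                base_intervals=((0.0, model.period),),
                horizon=horizon,
                intervals=full,
                duty_achieved=1.0,
            )
    else:
        tau = config.threshold

    T = model.period
    sign = 1.0 if config.beam_on_below else -1.0

    def margin(t: float):
        # >= 0 while the beam is permitted
        return sign * (tau - breathing_signal(t, model))

    t = np.linspace(0.0, T, _GRID + 1)
    m = np.asarray(margin(t), dtype=float)
    on = m >= 0
    if not on.any():
        raise GateError("gate never opens: threshold outside the signal's range")
    if on.all():
        base: list[tuple[float, float]] = [(0.0, T)]
    else:
        # boundaries where the on-indicator flips, refined by bisection
        flips = np.nonzero(np.diff(on.astype(np.int8)))[0]
        edges = [float(_refine_crossing(margin, float(t[i]), float(t[i + 1]))) for i in flips]
        base = []
        if on[0]:
            # on-region includes t=0: first edge closes it
            base.append((0.0, edges[0]))
            edges = edges[1:]
        for i in range(0, len(edges) - 1, 2):
            base.append((edges[i], edges[i + 1]))
        if len(edges) % 2 == 1:
            # on-region runs into the seam (wraps to the piece at t=0)
            base.append((edges[-1], T))

    duty_achieved = sum(e - s for s, e in base) / T
    sched = GateSchedule(
        period=T,
        base_intervals=tuple(base),
        horizon=horizon,
        intervals=(),
        duty_achieved=duty_achieved,
    )
    # concretize [0, horizon) from the unbounded stream
    concrete: list[tuple[float, float]] = []
    for ws, we in sched.windows():
        if ws >= horizon:
            break
        concrete.append((ws, min(we, horizon)))
    object.__setattr__(sched, "intervals", tuple(concrete))
    return sched
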
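"""Event-driven simulation of layer-by-layer delivery under respiratory gating.

Delivery proceeds one energy layer at a time.  The beam may only be on while
the gate is open; a layer's remaining beam-on time is treated as continuously
divisible, so the beam pauses instantly at a gate-off edge and resumes at the
next gate-on (segment granularity, sub-millisecond, is far below gating
timescales).  When a layer completes, an energy switch of fixed duration
``t_ls`` starts immediately and runs regardless of gate state — switching is
mutually exclusive with beam-on but not with gating, which is exactly what
lets a well-synchronized plan hide switches inside gate-off periods.  The
next layer then starts at the first instant that is both post-switch and
gate-on.

Every simulated timeline satisfies the exact decomposition

    t_total = t_bot + t_ls * (n_layers - 1) + t_dead,      t_dead >= 0,

where ``t_bot`` is cumulative beam-on time, the middle term is total
switching time (no switch after the final layer), and ``t_dead`` absorbs all
gating-induced waiting, including the part of a switch that spills past a
gate-on window.

:func:`oracle_simulate` re-implements the identical rules by brute-force
time stepping and exists purely as an independent cross-check of the
event-driven engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .dr_engine import DynamicRange, field_bot
from .plan_model import MachineSpec, TreatmentPlan
from .respiration import GateConfig, GateSchedule, RespiratoryModel, gate_intervals

__all__ = [
    "DeliveryError",
    "Event",
    "DeliveryTimeline",
    "SimConfig",
    "simulate_field",
    "oracle_simulate",
    "simulate_plan",
]

_EPS = 1e-12


class DeliveryError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """One contiguous timeline state: beam_on, layer_switch or idle."""

    start: float
    end: float
    kind: str  # "beam_on" | "layer_switch" | "idle"
    layer_index: int | None = None


@dataclass(frozen=True)
class DeliveryTimeline:
    """Event log of one field's delivery plus its time decomposition."""

    events: tuple[Event, ...]
    t_total: float
    t_bot: float
    t_ls_total: float
    t_dead: float

    def per_layer_beam_time(self, n_layers: int) -> list[float]:
        out = [0.0] * n_layers
        for ev in self.events:
            if ev.kind == "beam_on":
                out[ev.layer_index] += ev.end - ev.start
        return out


@dataclass(frozen=True)
class SimConfig:
    """Simulation conventions.

    start_phase : s offset into the respiratory cycle at simulation start
        (0 <= start_phase < T_R; validated against the schedule's period).
    clock_origin : "simulation_start" (default) or "first_beam_on".
    interruptible : if False, a layer is only started inside a gate window
        long enough to finish it in one piece (whole-layer deferral); the
        default models instant pause/resume at gate edges.
    """

    start_phase: float = 0.0
    clock_origin: str = "simulation_start"
    interruptible: bool = True

    def __post_init__(self) -> None:
        if self.start_phase < 0:
            raise DeliveryError(f"start_phase must be >= 0, got {self.start_phase!r}")
        if self.clock_origin not in ("simulation_start", "first_beam_on"):
            raise DeliveryError(f"unknown clock_origin {self.clock_origin!r}")


def _finalize(
    events: list[Event], n_layers: int, t_ls: float, config: SimConfig
) -> DeliveryTimeline:
    if config.clock_origin == "first_beam_on":
        t0 = next(ev.start for ev in events if ev.kind == "beam_on")
        events = [
            Event(ev.start - t0, ev.end - t0, ev.kind, ev.layer_index)
            for ev in events
            if ev.end > t0
        ]
    t_total = events[-1].end
    t_bot = sum(ev.end - ev.start for ev in events if ev.kind == "beam_on")
    t_ls_total = t_ls * (n_layers - 1)
    t_dead = t_total - t_bot - t_ls_total
    if t_dead < -1e-9:
        raise DeliveryError(f"negative dead time {t_dead} — inconsistent timeline")
    return DeliveryTimeline(
        events=tuple(events),
        t_total=t_total,
        t_bot=t_bot,
        t_ls_total=t_ls_total,
        t_dead=max(t_dead, 0.0),
    )


def simulate_field(
    per_layer_bot: Sequence[float],
    gates: GateSchedule,
    machine: MachineSpec,
    config: SimConfig = SimConfig(),
) -> DeliveryTimeline:
    """Event-driven delivery of one field's per-layer beam-on times.

    Windows are half-open ``[on, off)``: the beam may start at an instant t
    only if t lies strictly before the window end, so a switch finishing
    exactly at gate-off waits for the next window.
    """
    if len(per_layer_bot) == 0:
        raise DeliveryError("per_layer_bot is empty")
    if any(not (b > 0) for b in per_layer_bot):
        raise DeliveryError("every per-layer beam-on time must be > 0")
    if config.start_phase >= gates.period:
        raise DeliveryError(
            f"start_phase {config.start_phase} must be < respiratory period {gates.period}"
        )

    win = gates.windows(offset=config.start_phase)
    try:
        ws, we = next(win)
    except StopIteration:
        raise DeliveryError("gate never opens") from None
    max_window = max(e - s for s, e in gates.base_intervals)

    events: list[Event] = []
    t = 0.0

    def advance_to(target: float, kind: str = "idle") -> None:
        nonlocal t
        if target > t + _EPS:
            events.append(Event(t, target, kind))
            t = target

    n = len(per_layer_bot)
    for i, bot in enumerate(per_layer_bot):
        r = float(bot)
        if not config.interruptible and r > max_window + _EPS and not math.isinf(we):
            raise DeliveryError(
                f"layer {i} beam-on time {r} s exceeds the longest gate window "
                f"({max_window} s); uninterruptible delivery is impossible"
            )
        while r > _EPS:
            # advance to a window containing usable beam time after t
            while we <= t + _EPS:
                ws, we = next(win)
            start = max(t, ws)
            if not config.interruptible and we - start < r - _EPS:
                # window too short to finish the layer in one piece: skip it
                ws, we = next(win)
                continue
            advance_to(start)
            d = min(r, we - t)
            events.append(Event(t, t + d, "beam_on", i))
            t += d
            r -= d
            if r <= _EPS:
                r = 0.0
        if i < n - 1 and machine.t_ls > 0:
            events.append(Event(t, t + machine.t_ls, "layer_switch", i))
            t += machine.t_ls

    return _finalize(events, n, machine.t_ls, config)


def oracle_simulate(
    per_layer_bot: Sequence[float],
    gates: GateSchedule,
    machine: MachineSpec,
    config: SimConfig = SimConfig(),
    dt: float = 1e-3,
) -> DeliveryTimeline:
    """Brute-force time-stepping simulator with the same delivery semantics.

    Steps the clock by ``dt`` and applies the rules state-by-state; agrees
    with :func:`simulate_field` on t_total and t_dead to within ~2*dt.  Only
    supports the default interruptible mode.  Independent verification code:
    deliberately shares no machinery with the event-driven engine.
    """
    if dt <= 0:
        raise DeliveryError(f"dt must be > 0, got {dt!r}")
    if len(per_layer_bot) == 0:
        raise DeliveryError("per_layer_bot is empty")
    if any(not (b > 0) for b in per_layer_bot):
        raise DeliveryError("every per-layer beam-on time must be > 0")
    if not gates.base_intervals:
        raise DeliveryError("gate never opens")

    # gate-state boundaries within one period, for clipping steps so no step
    # straddles an on/off edge (otherwise edge quantization drifts the clock)
    edges = sorted({0.0, gates.period, *(b for se in gates.base_intervals for b in se)})

    def fold(t: float) -> float:
        # phase-fold into [0, period), snapping float fuzz onto the exact edge
        # so the half-open [on, off) convention is applied at the boundary itself
        tm = (t + config.start_phase) % gates.period
        for e in edges:
            if abs(tm - e) < 1e-9:
                return e % gates.period
        return tm

    def gate_on(t: float) -> bool:
        tm = fold(t)
        return any(s <= tm < e for s, e in gates.base_intervals)

    def time_to_edge(t: float) -> float:
        tm = fold(t)
        for e in edges:
            if e > tm + 1e-9:
                return e - tm
        # within 1e-9 of the period seam: wrap to the first edge past it
        # (the state is uniform on [0, first positive edge))
        nxt = edges[1] if len(edges) > 1 else gates.period
        return (gates.period - tm) + nxt

    events: list[Event] = []

    def record(t0: float, t1: float, kind: str, layer: int | None = None) -> None:
        if events and events[-1].kind == kind and events[-1].layer_index == layer:
            events[-1] = Event(events[-1].start, t1, kind, layer)
        else:
            events.append(Event(t0, t1, kind, layer))

    t = 0.0
    layer = 0
    residual = float(per_layer_bot[0])
    switch_left = 0.0
    max_steps = int(1e8)
    for _ in range(max_steps):
        if switch_left > _EPS:
            step = min(dt, switch_left)
            record(t, t + step, "layer_switch", layer - 1)
            switch_left -= step
        elif gate_on(t):
            step = min(dt, residual, time_to_edge(t))
            record(t, t + step, "beam_on", layer)
            residual -= step
        else:
            step = min(dt, time_to_edge(t))
            record(t, t + step, "idle")
        t += step
        if residual <= _EPS and switch_left <= _EPS:
            layer += 1
            if layer >= len(per_layer_bot):
                break
            residual = float(per_layer_bot[layer])
            switch_left = machine.t_ls
    else:
        raise DeliveryError("oracle exceeded step budget")

    return _finalize(events, len(per_layer_bot), machine.t_ls, config)


def simulate_plan(
    plan: TreatmentPlan,
    dr: DynamicRange,
    resp: RespiratoryModel,
    gate: GateConfig,
    machine: MachineSpec,
    config: SimConfig = SimConfig(),
) -> list[DeliveryTimeline]:
    """Simulate every field of a plan independently at one dynamic range.

    Each field is DR-adjusted (:func:`txtime.dr_engine.field_bot`), then
    delivered from ``config.start_phase`` under the amplitude gate derived
    from ``resp``/``gate``.  Per-field timelines are returned unsummed, the
    way ports are reported clinically.
    """
    schedule = gate_intervals(resp, gate, horizon=10.0 * resp.period)
    out = []
    for f in plan.fields:
        bots = field_bot(f, dr, machine).per_layer
        out.append(simulate_field(bots, schedule, machine, config))
    return out
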
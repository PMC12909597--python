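"""Dynamic-range beam-on-time model for line-scanning delivery.

In line scanning, every segment of an energy layer is delivered at a common
dose rate (MU/s), and the scanning speed implied by a segment is
``speed_i = dose_rate * length_i / mu_i``.  Since speed cannot exceed the
machine maximum, the lowest-weighted segment pins the whole layer's dose rate:

    baseline dose rate = min_i(mu_i / length_i) * speed_max

A dynamic-range (DR) constraint caps the within-layer spread of MU weights at
``mu_max / mu_min <= DR``.  Imposing it raises the minimum-MU floor to
``mu_max / DR``, which lets the layer run at the higher rate

    DR dose rate = (mu_max / length_ref) * speed_max / DR

(``length_ref`` the length of the mu_max segment), at the price of elevating
every sub-floor segment's MU — a deliberate upward violation of MU
conservation that trades intensity-modulation flexibility for speed.  The
per-segment beam-on time is adjusted MU over the layer dose rate, and layer
beam-on time is the sum over segments.

The model operates on a fixed segment layout: it never restructures the plan,
only raises MU floors and dose rates, mirroring how a planning system's DR
constraint predominantly acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .plan_model import EnergyLayer, MachineSpec, TreatmentField

__all__ = [
    "DynamicRange",
    "DRAdjustedLayer",
    "FieldBoT",
    "baseline_dose_rate",
    "dr_dose_rate",
    "elevate_mu",
    "adjust_layer",
    "field_bot",
    "bot_floor",
]


@dataclass(frozen=True)
class DynamicRange:
    """A dynamic-range constraint: ``mu_max/mu_min <= value``, or unconstrained.

    ``value`` is ``None`` for the unconstrained (no-DR) case, otherwise >= 1.
    ``DynamicRange(1)`` forces every MU in a layer up to that layer's mu_max.
    """

    value: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None:
            v = float(self.value)
            if not (v >= 1) or math.isinf(v) or math.isnan(v):
                raise ValueError(f"constrained dynamic range must be finite and >= 1, got {self.value!r}")
            object.__setattr__(self, "value", v)

    @classmethod
    def unconstrained(cls) -> "DynamicRange":
        return cls(None)

    @classmethod
    def parse(cls, text: str | float | None) -> "DynamicRange":
        """Parse 'unconstrained'/'none'/None or a number."""
        if text is None:
            return cls(None)
        if isinstance(text, str):
            if text.strip().lower() in ("unconstrained", "none", "inf", "no"):
                return cls(None)
            return cls(float(text))
        return cls(float(text))

    @property
    def constrained(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        return "unconstrained" if self.value is None else f"{self.value:g}"


@dataclass(frozen=True)
class DRAdjustedLayer:
    """One energy layer after DR adjustment: dose rate, elevated MUs, beam-on times."""

    source: EnergyLayer
    dr: DynamicRange
    dose_rate: float
    adjusted_mu: tuple[float, ...]
    segment_bot: tuple[float, ...]
    layer_bot: float
    n_elevated: int


@dataclass(frozen=True)
class FieldBoT:
    """Per-layer and total beam-on time of one field at a given DR."""

    total: float
    per_layer: tuple[float, ...]
    layers: tuple[DRAdjustedLayer, ...]


def _cap(rate: float, machine: MachineSpec) -> float:
    if machine.max_dose_rate is not None:
        return min(rate, machine.max_dose_rate)
    return rate


def baseline_dose_rate(layer: EnergyLayer, machine: MachineSpec) -> float:
    """Layer dose rate without any DR constraint (MU/s).

    The binding segment is the one minimizing mu_i/length_i; with uniform
    segment lengths this is (mu_min / length) * speed_max.  Capped at the
    machine dose-rate limit when one is configured.
    """
    rate = min(s.mu / s.length for s in layer.segments) * machine.speed_max
    return _cap(rate, machine)


def dr_dose_rate(layer: EnergyLayer, dr: DynamicRange, machine: MachineSpec) -> float:
    """Effective layer dose rate under a DR constraint (MU/s).

    ``(mu_max / length_ref) * speed_max / DR``, where ``length_ref`` is the
    length of the mu_max segment, but never below the baseline rate: a DR
    looser than the layer's intrinsic mu_max/mu_min ratio must not slow
    delivery relative to the unconstrained plan.  Unconstrained DR delegates
    to :func:`baseline_dose_rate`.
    """
    if not dr.constrained:
        return baseline_dose_rate(layer, machine)
    ref = max(layer.segments, key=lambda s: s.mu)
    rate = (ref.mu / ref.length) * machine.speed_max / dr.value
    base = min(s.mu / s.length for s in layer.segments) * machine.speed_max
    return _cap(max(rate, base), machine)


def elevate_mu(layer: EnergyLayer, dr: DynamicRange) -> list[float]:
    """Minimum-MU elevation: clamp each segment MU up to the ``mu_max/DR`` floor.

    Segments already at or above the floor are untouched; the elevated total
    MU is intentionally larger than the planned total (the modulation cost of
    the constraint).
    """
    if not dr.constrained:
        return [s.mu for s in layer.segments]
    floor = layer.mu_max / dr.value
    return [max(s.mu, floor) for s in layer.segments]


def adjust_layer(layer: EnergyLayer, dr: DynamicRange, machine: MachineSpec) -> DRAdjustedLayer:
    """Full DR adjustment of one layer: dose rate, MU elevation, beam-on times.

    Composes the dose-rate and elevation steps, then enforces the machine
    speed limit per segment: any adjusted MU whose implied scan speed
    ``dose_rate * length_i / mu_i`` would exceed ``speed_max`` is raised to
    ``dose_rate * length_i / speed_max`` (a no-op for uniform segment
    lengths).  Per-segment beam-on time is adjusted MU / dose rate; the layer
    beam-on time is their sum.  Unconstrained DR reproduces the baseline
    exactly: MUs untouched, baseline dose rate.
    """
    rate = dr_dose_rate(layer, dr, machine)
    adjusted = elevate_mu(layer, dr)
    n_elevated = sum(1 for a, s in zip(adjusted, layer.segments) if a > s.mu)
    # machine-limit validation: no segment may imply a speed above speed_max
    adjusted = [
        max(a, rate * s.length / machine.speed_max) for a, s in zip(adjusted, layer.segments)
    ]
    bot = tuple(a / rate for a in adjusted)
    return DRAdjustedLayer(
        source=layer,
        dr=dr,
        dose_rate=rate,
        adjusted_mu=tuple(adjusted),
        segment_bot=bot,
        layer_bot=sum(bot),
        n_elevated=n_elevated,
    )


def field_bot(field: TreatmentField, dr: DynamicRange, machine: MachineSpec) -> FieldBoT:
    """Beam-on time of every layer of a field at one DR, plus the field total."""
    layers = tuple(adjust_layer(layer, dr, machine) for layer in field.layers)
    per_layer = tuple(l.layer_bot for l in layers)
    return FieldBoT(total=sum(per_layer), per_layer=per_layer, layers=layers)


def bot_floor(field_or_layer: TreatmentField | EnergyLayer, machine: MachineSpec) -> float:
    """Lower bound on beam-on time: total path length / speed_max.

    Attained exactly when every segment is delivered at the maximum scanning
    speed, which is the DR -> 1 plateau of the model.
    """
    if isinstance(field_or_layer, EnergyLayer):
        layers: Sequence[EnergyLayer] = [field_or_layer]
    else:
        layers = field_or_layer.layers
    return sum(s.length for layer in layers for s in layer.segments) / machine.speed_max
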
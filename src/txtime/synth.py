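"""Seeded synthetic treatment plans and square-gate test fixtures.

The generator emulates the delivery structure of clinical line-scanning liver
plans: 2-3 fields, tens of energy layers stacked from high to low energy
within the 70-230 MeV cyclotron window, 100-500 line segments per layer, and
heavy-tailed within-layer MU distributions spanning two or more orders of
magnitude — the regime in which a dynamic-range constraint has leverage.  It
is purely structural: no anatomy, no dose, and no claim that the MU
distribution matches any particular cohort (a lognormal with the default
parameters reproduces the right magnitudes, 1e-3..1e-2 MU, and spread).

Every draw comes from a named ``numpy`` RNG stream keyed by
``(seed, field_index, layer_index)``, so adding layers or fields never
reshuffles earlier draws and the same seed yields the identical plan on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .plan_model import EnergyLayer, LineSegment, TreatmentField, TreatmentPlan
from .respiration import GateSchedule

__all__ = [
    "PlanGenSpec",
    "generate_plan",
    "square_gate_signal",
    "square_gate_schedule",
]

Range = tuple[float, float]


@dataclass(frozen=True)
class PlanGenSpec:
    """Recipe for a reproducible synthetic plan.

    mu_distribution is ``("lognormal", mu, sigma)`` (parameters of log MU) or
    ``("uniform", a, b)`` with a > 0.  ``n_layers``/``segments_per_layer``/
    ``length_cm`` accept a constant or an inclusive (lo, hi) range.
    """

    n_fields: int = 2
    n_layers: Union[int, tuple[int, int]] = (20, 40)
    segments_per_layer: tuple[int, int] = (100, 500)
    mu_distribution: tuple = ("lognormal", -4.5, 1.2)
    length_cm: Union[float, Range] = 0.6
    energy_range: Range = (70.0, 230.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        for name, rng in (("n_layers", self.n_layers), ("segments_per_layer", self.segments_per_layer)):
            lo, hi = (rng, rng) if isinstance(rng, (int, float)) else rng
            if lo < 1 or hi < lo:
                raise ValueError(f"degenerate {name} range {rng!r}")
        kind = self.mu_distribution[0]
        if kind == "uniform":
            _, a, b = self.mu_distribution
            if not (0 < a <= b):
                raise ValueError(f"uniform MU bounds must satisfy 0 < a <= b, got {a, b}")
        elif kind == "lognormal":
            _, _, sigma = self.mu_distribution
            if sigma < 0:
                raise ValueError("lognormal sigma must be >= 0")
        else:
            raise ValueError(f"unknown mu_distribution kind {kind!r}")
        lo, hi = (self.length_cm, self.length_cm) if isinstance(self.length_cm, (int, float)) else self.length_cm
        if not (0 < lo <= hi):
            raise ValueError(f"degenerate length_cm range {self.length_cm!r}")
        elo, ehi = self.energy_range
        if not (0 < elo <= ehi):
            raise ValueError(f"degenerate energy_range {self.energy_range!r}")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _draw_int(rng: np.random.Generator, spec: Union[int, tuple[int, int]]) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _draw_mu(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "lognormal":
        _, mean, sigma = dist
        return rng.lognormal(mean=mean, sigma=sigma, size=n)
    _, a, b = dist
    return rng.uniform(a, b, size=n)


def generate_plan(spec: PlanGenSpec) -> TreatmentPlan:
    """Deterministic synthetic plan; always passes plan validation."""
    fields = []
    for fi in range(spec.n_fields):
        frng = _stream(spec.seed, fi)
        n_layers = _draw_int(frng, spec.n_layers)
        elo, ehi = spec.energy_range
        energies = np.sort(frng.uniform(elo, ehi, size=n_layers))[::-1]  # descending stack
        layers = []
        for li in range(n_layers):
            lrng = _stream(spec.seed, fi, li)
            n_seg = _draw_int(lrng, spec.segments_per_layer)
            mus = _draw_mu(lrng, spec.mu_distribution, n_seg)
            if isinstance(spec.length_cm, (int, float)):
                lengths = np.full(n_seg, float(spec.length_cm))
            else:
                lengths = lrng.uniform(spec.length_cm[0], spec.length_cm[1], size=n_seg)
            layers.append(
                EnergyLayer(
                    energy=float(energies[li]),
                    segments=tuple(
                        LineSegment(mu=float(m), length=float(l)) for m, l in zip(mus, lengths)
                    ),
                )
            )
        fields.append(TreatmentField(name=f"field_{fi + 1}", layers=tuple(layers)))
    return TreatmentPlan(plan_id=f"synthetic_seed{spec.seed}", fields=tuple(fields))


def square_gate_signal(t: float, period: float, duty: float) -> bool:
    """Idealized square gate: on exactly when ``(t mod period) < duty * period``."""
    if not (0 < duty <= 1):
        raise ValueError(f"duty must be in (0, 1], got {duty!r}")
    if not (period > 0):
        raise ValueError(f"period must be > 0, got {period!r}")
    return (t % period) < duty * period


def square_gate_schedule(period: float, duty: float, horizon: float) -> GateSchedule:
    """GateSchedule of an idealized square gate (windows ``[kT, kT + duty*T)``)."""
    if not (0 < duty <= 1):
        raise ValueError(f"duty must be in (0, 1], got {duty!r}")
    if not (period > 0 and horizon > 0):
        raise ValueError("period and horizon must be > 0")
    base = ((0.0, duty * period),)
    intervals = []
    k = 0
    while k * period < horizon:
        intervals.append((k * period, min(k * period + duty * period, horizon)))
        k += 1
    return GateSchedule(
        period=period,
        base_intervals=base,
        horizon=horizon,
        intervals=tuple(intervals),
        duty_achieved=duty,
    )
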
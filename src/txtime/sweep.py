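"""Dynamic-range parameter sweep, plateau detection and report rendering.

The clinical question the sweep answers: how far can the DR constraint be
tightened before total treatment time stops improving?  Below that plateau
threshold, further DR reduction buys no time and only costs intensity
modulation (hence normal-tissue dose), so the largest DR on the plateau is
the value a planner should take forward to re-optimization.

Plateau detection is grid-based on the computed points only; any
interpolation drawn in the report plot is presentation, never input to the
detector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .dr_engine import DynamicRange
from .gated_delivery import SimConfig, simulate_plan
from .plan_model import MachineSpec, TreatmentPlan
from .respiration import GateConfig, RespiratoryModel

__all__ = [
    "SweepResult",
    "default_dr_grid",
    "sweep_dr",
    "find_plateau",
    "render_report",
]


def default_dr_grid() -> list[DynamicRange]:
    """Unconstrained plus DR 200 down to 10 in steps of 10 (descending)."""
    return [DynamicRange.unconstrained()] + [DynamicRange(v) for v in range(200, 9, -10)]


@dataclass(frozen=True)
class SweepResult:
    """Treatment-time predictions over a DR grid, one row-set per field.

    ``t_total``/``t_bot``/``t_dead`` map field name -> list aligned with
    ``dr_values`` (descending, unconstrained first when present).  ``params``
    echoes every input that determines the result (respiratory period, t_ls,
    duty, phase, grid, plan hash) so reports are self-describing.
    """

    dr_values: tuple[DynamicRange, ...]
    field_names: tuple[str, ...]
    t_total: dict[str, list[float]]
    t_bot: dict[str, list[float]]
    t_dead: dict[str, list[float]]
    plateau_dr: DynamicRange | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.field_names:
            for table in (self.t_total, self.t_bot, self.t_dead):
                if len(table[name]) != len(self.dr_values):
                    raise ValueError(f"sweep lists misaligned with dr grid for field {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "field": name,
                "dr": str(dr),
                "t_total_s": self.t_total[name][i],
                "t_bot_s": self.t_bot[name][i],
                "t_dead_s": self.t_dead[name][i],
            }
            for name in self.field_names
            for i, dr in enumerate(self.dr_values)
        ]
        return pd.DataFrame(rows, columns=["field", "dr", "t_total_s", "t_bot_s", "t_dead_s"])


def _plan_hash(plan: TreatmentPlan) -> str:
    from .plan_model import _plan_to_dict

    return hashlib.sha256(json.dumps(_plan_to_dict(plan)).encode()).hexdigest()[:16]


def _sort_grid(dr_values: Sequence[DynamicRange]) -> tuple[DynamicRange, ...]:
    # descending, unconstrained (infinite) first
    return tuple(
        sorted(dr_values, key=lambda d: float("inf") if not d.constrained else d.value, reverse=True)
    )


def sweep_dr(
    plan: TreatmentPlan,
    dr_values: Sequence[DynamicRange],
    resp: RespiratoryModel,
    gate: GateConfig,
    machine: MachineSpec,
    config: SimConfig = SimConfig(),
) -> SweepResult:
    """Simulate every field at every DR in the grid (deterministic)."""
    if len(dr_values) == 0:
        raise ValueError("dr_values must be non-empty")
    grid = _sort_grid(dr_values)
    names = tuple(f.name for f in plan.fields)
    t_total = {n: [] for n in names}
    t_bot = {n: [] for n in names}
    t_dead = {n: [] for n in names}
    for dr in grid:
        timelines = simulate_plan(plan, dr, resp, gate, machine, config)
        for name, tl in zip(names, timelines):
            t_total[name].append(tl.t_total)
            t_bot[name].append(tl.t_bot)
            t_dead[name].append(tl.t_dead)
    result = SweepResult(
        dr_values=grid,
        field_names=names,
        t_total=t_total,
        t_bot=t_bot,
        t_dead=t_dead,
        params={
            "t_r_s": resp.period,
            "t_ls_s": machine.t_ls,
            "gate_mode": gate.mode,
            "duty": gate.duty,
            "threshold": gate.threshold,
            "start_phase_s": config.start_phase,
            "grid": [str(d) for d in grid],
            "plan_hash": _plan_hash(plan),
        },
    )
    if len(grid) >= 2:
        object.__setattr__(result, "plateau_dr", find_plateau(result))
    return result


def find_plateau(result: SweepResult, epsilon: float | None = None) -> DynamicRange | None:
    """Largest grid DR whose t_total is within epsilon of the grid minimum.

    Computed per field; the plan-level answer is the most conservative
    (largest) per-field plateau, so no field is over-constrained.  Returns
    ``None`` when only the smallest DR qualifies (no plateau: time is still
    falling at the foot of the grid).  ``epsilon`` defaults to 1% of the
    minimum t_total (per field); pass a value in seconds to override.
    """
    if len(result.dr_values) < 2:
        raise ValueError("plateau detection needs a sweep over at least 2 DR values")
    if epsilon is not None and epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    def sort_key(d: DynamicRange) -> float:
        return float("inf") if not d.constrained else d.value

    per_field: list[DynamicRange | None] = []
    for name in result.field_names:
        totals = result.t_total[name]
        if len(totals) != len(result.dr_values):
            raise ValueError(f"misaligned sweep result for field {name!r}")
        tmin = min(totals)
        eps = 0.01 * tmin if epsilon is None else epsilon
        qualifying = [
            dr for dr, t in zip(result.dr_values, totals) if t - tmin <= eps
        ]
        best = max(qualifying, key=sort_key)
        smallest = min(result.dr_values, key=sort_key)
        per_field.append(None if best == smallest else best)
    if any(p is None for p in per_field):
        return None
    return max(per_field, key=sort_key)


def render_report(
    result: SweepResult,
    out: str | Path,
    plot: str | Path | None = None,
) -> None:
    """Write the sweep table (CSV, or JSON for a ``.json`` path) and optional plot.

    The plot shows computed points as markers with piecewise-linear
    interpolation between them and the detected plateau annotated; the
    interpolation is presentation-only.
    """
    frame = result.to_frame()
    # sanity gate: beam-on time can never increase as DR tightens
    for name in result.field_names:
        bots = result.t_bot[name]
        if any(b2 > b1 + 1e-9 for b1, b2 in zip(bots, bots[1:])):
            raise ValueError(f"t_bot not non-increasing over the DR grid for field {name!r}")
    out = Path(out)
    if out.suffix.lower() == ".json":
        doc = {
            "params": result.params,
            "plateau_dr": None if result.plateau_dr is None else str(result.plateau_dr),
            "sweep": frame.to_dict(orient="records"),
        }
        out.write_text(json.dumps(doc, indent=1) + "\n")
    else:
        frame.to_csv(out, index=False)

    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        xs = [1e6 if not d.constrained else d.value for d in result.dr_values]
        for name in result.field_names:
            ax.plot(xs, result.t_total[name], "-", lw=1, alpha=0.7)
            ax.plot(xs, result.t_total[name], "o", ms=4, label=name)
        if result.plateau_dr is not None and result.plateau_dr.constrained:
            ax.axvline(result.plateau_dr.value, ls="--", color="k", lw=1)
            ax.annotate(
                f"plateau DR = {result.plateau_dr}",
                xy=(result.plateau_dr.value, min(min(v) for v in result.t_total.values())),
                xytext=(5, 5),
                textcoords="offset points",
                fontsize=8,
            )
        ax.set_xscale("log")
        ax.set_xlabel("dynamic range")
        ax.set_ylabel("total treatment time (s)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot, dpi=120)
        plt.close(fig)
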
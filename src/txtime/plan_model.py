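"""Domain types for line-scanning proton treatment plans and machine settings.

A plan is a list of fields; each field an ordered list of energy layers; each
layer an ordered list of line segments carrying a monitor-unit (MU) weight and
a path length in cm.  The within-layer MU extrema drive the layer dose rate
and hence the beam-on time, which is what the rest of the package models.

Units are fixed throughout the package: MU dimensionless, lengths in cm,
times in s, energies in MeV.  No unit inference is performed.

The canonical interchange format is a small versioned JSON schema; a flat CSV
dialect (one row per segment) is provided for spreadsheet convenience.
Segment order within a layer is preserved on round-trip but does not affect
any beam-on-time result: the model treats a layer's segments as a set with a
common dose rate.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

__all__ = [
    "PlanValidationError",
    "PlanSchemaError",
    "LineSegment",
    "EnergyLayer",
    "TreatmentField",
    "TreatmentPlan",
    "MachineSpec",
    "layer_extrema",
    "load_plan",
    "save_plan",
    "load_machine",
    "save_machine",
]

SCHEMA_VERSION = 1

#: energies outside this window are legal but warn (typical clinical cyclotron range)
ENERGY_RANGE_MEV = (70.0, 230.0)

CSV_COLUMNS = ["field_name", "layer_index", "energy_mev", "segment_index", "mu", "length_cm"]


class PlanValidationError(ValueError):
    """A plan object violates a structural invariant (non-positive MU, empty layer...)."""


class PlanSchemaError(ValueError):
    """A plan file does not conform to the documented schema."""


@dataclass(frozen=True)
class LineSegment:
    """One scanned line: the atom of delivery.

    Parameters
    ----------
    mu : float
        Monitor-unit weight (dimensionless, > 0).
    length : float
        Scanned path length in cm (> 0).
    """

    mu: float
    length: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise PlanValidationError(f"segment mu must be > 0, got {self.mu!r}")
        if not (self.length > 0):
            raise PlanValidationError(f"segment length must be > 0, got {self.length!r}")


@dataclass(frozen=True)
class EnergyLayer:
    """All segments delivered at one proton energy (one depth).

    ``mu_min``/``mu_max`` are the within-layer MU extrema; their ratio is the
    layer's intrinsic dynamic range and determines how strongly a dynamic-range
    constraint can accelerate the layer.
    """

    energy: float
    segments: tuple[LineSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise PlanValidationError("energy layer must contain at least one segment")
        if not all(isinstance(s, LineSegment) for s in self.segments):
            raise PlanValidationError("layer segments must be LineSegment instances")
        if not (ENERGY_RANGE_MEV[0] <= self.energy <= ENERGY_RANGE_MEV[1]):
            warnings.warn(
                f"layer energy {self.energy} MeV outside typical "
                f"{ENERGY_RANGE_MEV[0]:g}-{ENERGY_RANGE_MEV[1]:g} MeV range",
                stacklevel=2,
            )

    @property
    def mu_min(self) -> float:
        return min(s.mu for s in self.segments)

    @property
    def mu_max(self) -> float:
        return max(s.mu for s in self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class TreatmentField:
    """Ordered energy layers of one beam port; layer order is delivery order."""

    name: str
    layers: tuple[EnergyLayer, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) == 0:
            raise PlanValidationError(f"field {self.name!r} must contain at least one layer")
        if not all(isinstance(l, EnergyLayer) for l in self.layers):
            raise PlanValidationError("field layers must be EnergyLayer instances")

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class TreatmentPlan:
    """A plan: one or more fields, delivered (and reported) independently."""

    plan_id: str
    fields: tuple[TreatmentField, ...]
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple(self.fields))
        if len(self.fields) == 0:
            raise PlanValidationError("plan must contain at least one field")
        if not all(isinstance(f, TreatmentField) for f in self.fields):
            raise PlanValidationError("plan fields must be TreatmentField instances")


@dataclass(frozen=True)
class MachineSpec:
    """Delivery-system parameters.

    Parameters
    ----------
    speed_max : float
        Maximum scanning speed in cm/s.  2000 cm/s for the cyclotron system
        this package's defaults describe.
    t_ls : float
        Energy-layer switching time in s (>= 0); 2 s default.
    max_dose_rate : float or None
        Optional machine dose-rate cap in MU/s; ``None`` means unbounded, in
        which case ``speed_max`` alone bounds the achievable dose rate.
    """

    speed_max: float = 2000.0
    t_ls: float = 2.0
    max_dose_rate: float | None = None

    def __post_init__(self) -> None:
        if not (self.speed_max > 0):
            raise PlanValidationError(f"speed_max must be > 0, got {self.speed_max!r}")
        if self.t_ls < 0:
            raise PlanValidationError(f"t_ls must be >= 0, got {self.t_ls!r}")
        if self.max_dose_rate is not None and not (self.max_dose_rate > 0):
            raise PlanValidationError(
                f"max_dose_rate must be > 0 or None, got {self.max_dose_rate!r}"
            )


def layer_extrema(layer: EnergyLayer) -> tuple[float, float]:
    """Exact (mu_min, mu_max) over a layer's segments."""
    return layer.mu_min, layer.mu_max


# ---------------------------------------------------------------------------
# serialization

def _require_keys(
    obj: Mapping[str, Any], required: set[str], where: str, optional: set[str] = frozenset()
) -> None:
    if not isinstance(obj, Mapping):
        raise PlanSchemaError(f"{where}: expected a JSON object")
    missing = required - set(obj)
    if missing:
        raise PlanSchemaError(f"{where}: missing key(s) {sorted(missing)}")
    extra = set(obj) - required - set(optional)
    if extra:
        raise PlanSchemaError(f"{where}: unexpected key(s) {sorted(extra)}")


def _number(obj: Mapping[str, Any], key: str, where: str) -> float:
    v = obj[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise PlanSchemaError(f"{where}: key {key!r} must be a number, got {type(v).__name__}")
    return float(v)


def _plan_from_dict(doc: Mapping[str, Any]) -> TreatmentPlan:
    if not isinstance(doc, Mapping):
        raise PlanSchemaError("plan document must be a JSON object")
    _require_keys(doc, {"schema_version", "plan_id", "fields"}, "plan", optional={"metadata"})
    if doc["schema_version"] != SCHEMA_VERSION:
        raise PlanSchemaError(
            f"unsupported schema_version {doc['schema_version']!r} (expected {SCHEMA_VERSION})"
        )
    fields = []
    for fi, fobj in enumerate(doc["fields"]):
        _require_keys(fobj, {"name", "layers"}, f"fields[{fi}]")
        layers = []
        for li, lobj in enumerate(fobj["layers"]):
            where = f"fields[{fi}].layers[{li}]"
            _require_keys(lobj, {"energy_mev", "segments"}, where)
            segments = []
            for si, sobj in enumerate(lobj["segments"]):
                swhere = f"{where}.segments[{si}]"
                _require_keys(sobj, {"mu", "length_cm"}, swhere)
                try:
                    segments.append(
                        LineSegment(mu=_number(sobj, "mu", swhere), length=_number(sobj, "length_cm", swhere))
                    )
                except PlanValidationError as e:
                    raise PlanValidationError(f"{swhere}: {e}") from None
            layers.append(EnergyLayer(energy=_number(lobj, "energy_mev", where), segments=tuple(segments)))
        fields.append(TreatmentField(name=str(fobj["name"]), layers=tuple(layers)))
    return TreatmentPlan(
        plan_id=str(doc["plan_id"]), fields=tuple(fields), metadata=dict(doc.get("metadata", {}))
    )


def _plan_to_dict(plan: TreatmentPlan) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "plan_id": plan.plan_id,
        "fields": [
            {
                "name": f.name,
                "layers": [
                    {
                        "energy_mev": layer.energy,
                        "segments": [{"mu": s.mu, "length_cm": s.length} for s in layer.segments],
                    }
                    for layer in f.layers
                ],
            }
            for f in plan.fields
        ],
    }
    if plan.metadata:
        doc["metadata"] = dict(plan.metadata)
    return doc


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "json"


def load_plan(path: str | Path, format: str | None = None) -> TreatmentPlan:
    """Read a validated :class:`TreatmentPlan` from a JSON or CSV plan file.

    ``format`` defaults from the file suffix (``.csv`` -> csv, else json).
    Schema violations raise :class:`PlanSchemaError` naming the offending key;
    invariant violations raise :class:`PlanValidationError` locating the
    offending field/layer/segment.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise PlanSchemaError(f"{path}: not valid JSON: {e}") from None
        return _plan_from_dict(doc)

    # CSV dialect: one row per segment, grouped by (field_name, layer_index)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(CSV_COLUMNS):
            raise PlanSchemaError(
                f"{path}: CSV header must be exactly {CSV_COLUMNS}, got {reader.fieldnames}"
            )
        rows = list(reader)
    if not rows:
        raise PlanSchemaError(f"{path}: CSV plan has no segment rows")

    fields: dict[str, dict[int, dict[str, Any]]] = {}
    field_order: list[str] = []
    for rn, row in enumerate(rows):
        where = f"row {rn + 2}"  # 1-based + header
        try:
            fname = row["field_name"]
            li = int(row["layer_index"])
            si = int(row["segment_index"])
            energy = float(row["energy_mev"])
            mu = float(row["mu"])
            length = float(row["length_cm"])
        except (TypeError, ValueError) as e:
            raise PlanSchemaError(f"{path}: {where}: {e}") from None
        if fname not in fields:
            fields[fname] = {}
            field_order.append(fname)
        layer = fields[fname].setdefault(li, {"energy": energy, "segments": {}})
        if layer["energy"] != energy:
            raise PlanSchemaError(
                f"{path}: {where}: inconsistent energy_mev for field {fname!r} layer {li}"
            )
        try:
            layer["segments"][si] = LineSegment(mu=mu, length=length)
        except PlanValidationError as e:
            raise PlanValidationError(f"{path}: {where}: {e}") from None

    built = []
    for fname in field_order:
        layers = []
        for li in sorted(fields[fname]):
            segs = fields[fname][li]["segments"]
            layers.append(
                EnergyLayer(
                    energy=fields[fname][li]["energy"],
                    segments=tuple(segs[si] for si in sorted(segs)),
                )
            )
        built.append(TreatmentField(name=fname, layers=tuple(layers)))
    return TreatmentPlan(plan_id=path.stem, fields=tuple(built))


def save_plan(plan: TreatmentPlan, path: str | Path, format: str | None = None) -> None:
    """Write a plan in the canonical JSON schema or the flat CSV dialect.

    Output is deterministic (canonical key order, full float precision) so
    save/load/save is byte-identical.
    """
    if not isinstance(plan, TreatmentPlan):
        raise PlanValidationError("save_plan requires a TreatmentPlan")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_plan_to_dict(plan), fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for f in plan.fields:
            for li, layer in enumerate(f.layers):
                for si, seg in enumerate(layer.segments):
                    writer.writerow([f.name, li, repr(layer.energy), si, repr(seg.mu), repr(seg.length)])


def load_machine(path: str | Path) -> MachineSpec:
    """Read a machine-config JSON: speed_max_cm_s, t_ls_s, max_dose_rate_mu_s."""
    with open(path) as fh:
        doc = json.load(fh)
    _require_keys(doc, {"speed_max_cm_s", "t_ls_s", "max_dose_rate_mu_s"}, "machine")
    mdr = doc["max_dose_rate_mu_s"]
    return MachineSpec(
        speed_max=float(doc["speed_max_cm_s"]),
        t_ls=float(doc["t_ls_s"]),
        max_dose_rate=None if mdr is None else float(mdr),
    )


def save_machine(machine: MachineSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "speed_max_cm_s": machine.speed_max,
                "t_ls_s": machine.t_ls,
                "max_dose_rate_mu_s": machine.max_dose_rate,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
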
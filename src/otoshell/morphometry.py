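"""Chamber morphometry: data model, validation, CSV/JSON I/O, built-in data.

A :class:`ChamberMeasurement` records one membranous chamber's wall
thickness ``w`` and radius of curvature ``r`` as mean/max/min in microns,
together with the shell shape model used to emulate it (cylinder, sphere,
ellipsoid, or torus).  A :class:`MeasurementSet` is an ordered, uniquely
named collection with a free-text provenance note.

The bundled oyster-toadfish dataset (:func:`toadfish_fixture`) carries the
published surgical measurements of the anterior semicircular canal, lateral
ampulla, and utricle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "SHAPE_MODELS",
    "CSV_COLUMNS",
    "MeasurementValidationError",
    "SchemaError",
    "ChamberMeasurement",
    "MeasurementSet",
    "toadfish_fixture",
    "read_measurements",
    "write_measurements",
    "set_to_json",
    "set_from_json",
]

SHAPE_MODELS = ("cylinder", "sphere", "ellipsoid", "torus")

#: Flat CSV schema; geometry cells are blank where inapplicable.
CSV_COLUMNS = (
    "chamber",
    "shape_model",
    "w_mean",
    "w_max",
    "w_min",
    "r_mean",
    "r_max",
    "r_min",
    "a",
    "b",
    "r_tube",
    "R_loop",
)


class MeasurementValidationError(ValueError):
    """An invariant of a measurement or measurement set is violated."""


class SchemaError(ValueError):
    """A measurement file does not match the documented schema."""


def _require_positive_ordered(chamber: str, prefix: str, lo: float, mid: float, hi: float) -> None:
    for fname, v in ((f"{prefix}_min", lo), (f"{prefix}_mean", mid), (f"{prefix}_max", hi)):
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise MeasurementValidationError(
                f"chamber {chamber!r}: field {fname} must be finite and positive, got {v!r}"
            )
    if not (lo <= mid <= hi):
        raise MeasurementValidationError(
            f"chamber {chamber!r}: require 0 < {prefix}_min <= {prefix}_mean <= {prefix}_max, "
            f"got {lo} / {mid} / {hi}"
        )


@dataclass(frozen=True)
class ChamberMeasurement:
    """One chamber's measured wall thickness and radius statistics (microns)."""

    name: str
    shape_model: str
    w_mean: float
    w_max: float
    w_min: float
    r_mean: float
    r_max: float
    r_min: float
    a: Optional[float] = None
    b: Optional[float] = None
    r_tube: Optional[float] = None
    R_loop: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise MeasurementValidationError("chamber name must be non-empty")
        if self.shape_model not in SHAPE_MODELS:
            raise MeasurementValidationError(
                f"chamber {self.name!r}: unknown shape_model {self.shape_model!r}; "
                f"expected one of {SHAPE_MODELS}"
            )
        _require_positive_ordered(self.name, "w", self.w_min, self.w_mean, self.w_max)
        _require_positive_ordered(self.name, "r", self.r_min, self.r_mean, self.r_max)
        if self.shape_model == "ellipsoid":
            if self.a is None or self.b is None:
                raise MeasurementValidationError(
                    f"chamber {self.name!r}: ellipsoid shape requires fields a and b"
                )
        if self.shape_model == "torus":
            if self.r_tube is None or self.R_loop is None:
                raise MeasurementValidationError(
                    f"chamber {self.name!r}: torus shape requires fields r_tube and R_loop"
                )


@dataclass(frozen=True)
class MeasurementSet:
    """Ordered collection of chamber measurements with a provenance note."""

    chambers: tuple[ChamberMeasurement, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chambers", tuple(self.chambers))
        if not self.chambers:
            raise MeasurementValidationError("measurement set must contain at least one chamber")
        names = [c.name for c in self.chambers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MeasurementValidationError(f"duplicate chamber names: {sorted(dupes)}")

    def __iter__(self) -> Iterable[ChamberMeasurement]:
        return iter(self.chambers)

    def __len__(self) -> int:
        return len(self.chambers)

    def __getitem__(self, name: str) -> ChamberMeasurement:
        for c in self.chambers:
            if c.name == name:
                return c
        raise KeyError(f"no chamber named {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chambers)


_TOADFISH_PROVENANCE = (
    "Oyster toadfish (Opsanus tau) membranous labyrinth; wall thickness and "
    "radius of curvature measured in microns during live-animal surgery. "
    "Means reflect 12-25 measurements from 3-5 fish; max/min are individual "
    "extremes. The utricle was measured at its narrowest point."
)


def toadfish_fixture() -> MeasurementSet:
    """Bundled toadfish labyrinth morphometry.

    Three chambers with their assigned shell models: the anterior
    semicircular canal and the utricle as cylinders, the lateral ampulla as
    a sphere.  Values are the published surgical measurements in microns,
    mean (max/min).
    """
    return MeasurementSet(
        chambers=(
            ChamberMeasurement(
                name="Anterior Canal", shape_model="cylinder",
                w_mean=70, w_max=86, w_min=45,
                r_mean=307, r_max=322, r_min=270,
            ),
            ChamberMeasurement(
                name="Lateral Ampulla", shape_model="sphere",
                w_mean=58, w_max=75, w_min=44,
                r_mean=697, r_max=788, r_min=625,
            ),
            ChamberMeasurement(
                name="Utricle", shape_model="cylinder",
                w_mean=32, w_max=42, w_min=20,
                r_mean=556, r_max=654, r_min=469,
            ),
        ),
        provenance=_TOADFISH_PROVENANCE,
    )


_NUMERIC = [c for c in CSV_COLUMNS if c not in ("chamber", "shape_model")]


def _row_to_measurement(row: pd.Series) -> ChamberMeasurement:
    def opt(col: str) -> Optional[float]:
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return ChamberMeasurement(
        name=str(row["chamber"]),
        shape_model=str(row["shape_model"]),
        w_mean=float(row["w_mean"]), w_max=float(row["w_max"]), w_min=float(row["w_min"]),
        r_mean=float(row["r_mean"]), r_max=float(row["r_max"]), r_min=float(row["r_min"]),
        a=opt("a"), b=opt("b"), r_tube=opt("r_tube"), R_loop=opt("R_loop"),
    )


def read_measurements(path: str | Path) -> MeasurementSet:
    """Read a measurement set from CSV (schema in :data:`CSV_COLUMNS`).

    Row order is preserved.  Raises :class:`SchemaError` naming any missing
    column and :class:`MeasurementValidationError` naming the chamber and
    field for any violated invariant.
    """
    path = Path(path)
    try:
        # keep_default_na=False so chamber names like "NA" survive; only truly
        # blank cells (inapplicable geometry fields) become missing.
        df = pd.read_csv(
            path,
            encoding="utf-8",
            keep_default_na=False,
            na_values=[""],
            dtype={"chamber": str, "shape_model": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise MeasurementValidationError(f"{path}: empty file; measurement set must be non-empty")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise MeasurementValidationError(f"{path}: no rows; measurement set must be non-empty")
    chambers = tuple(_row_to_measurement(row) for _, row in df.iterrows())
    return MeasurementSet(chambers=chambers, provenance=f"read from {path.name}")


def write_measurements(ms: MeasurementSet, path: str | Path) -> None:
    """Write a measurement set to CSV; lossless round trip with reads.

    Floats are written in shortest-repr form, so re-reading recovers the
    exact binary values.  Inapplicable geometry cells are left blank.
    """
    records = []
    for c in ms.chambers:
        rec = {"chamber": c.name, "shape_model": c.shape_model}
        for col in _NUMERIC:
            v = getattr(c, col)
            rec[col] = "" if v is None else repr(float(v))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")


def set_to_json(ms: MeasurementSet) -> str:
    """Serialize a measurement set to JSON mirroring the CSV field names."""
    payload = {
        "provenance": ms.provenance,
        "chambers": [asdict(c) for c in ms.chambers],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False)


def set_from_json(text: str) -> MeasurementSet:
    payload = json.loads(text)
    chambers = tuple(ChamberMeasurement(**c) for c in payload["chambers"])
    return MeasurementSet(chambers=chambers, provenance=payload.get("provenance", ""))
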
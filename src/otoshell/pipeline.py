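"""Per-chamber stress analysis: thinness, GSF, normalized hoop stress.

The analysis chain for a measurement set is

1. map each chamber's shape model to its shape coefficient ``s``
   (cylinder 1.0, sphere 0.5, ellipsoid 1 - a^2/(2 b^2), torus via the
   anticlastic inner-equator factor);
2. form the thinness ratio r/w per statistic — means paired with means,
   the stress-maximizing extreme pairing (r_max, w_min) for "max" and the
   stress-minimizing pairing (r_min, w_max) for "min";
3. multiply: GSF = s * r/w per statistic;
4. normalize every chamber's GSF by a reference chamber's mean GSF
   (by default the chamber with the smallest mean GSF, so every normalized
   stress t_n is >= 1), giving pressure-free comparative hoop stresses.

Two t_n values are carried per entry: the full-precision ratio and a
one-decimal display value obtained by dividing the unrounded GSF by the
reference GSF *rounded to one decimal* and then rounding half-up — the
convention that reproduces the published summary table.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .morphometry import ChamberMeasurement, MeasurementSet
from .shell import (
    EllipsoidGeometry,
    TorusGeometry,
    shape_coefficient,
    geometric_stress_factor,
    torus_equatorial_factors,
)

__all__ = [
    "THIN_CRITERION",
    "APPROACHES_BAND",
    "ChamberStressSummary",
    "ThinMembraneResult",
    "ExtremesResult",
    "round1",
    "thinness_ratio",
    "thin_membrane_check",
    "chamber_shape_coefficient",
    "summarize_chamber",
    "summarize_set",
    "normalize",
    "extremes_analysis",
    "build_report",
    "summaries_from_json",
]

#: Engineering thin-membrane criterion on r/w.
THIN_CRITERION = 5.0
#: Ratios in [4, 5) are reported as "approaches" the criterion.
APPROACHES_BAND = (4.0, 5.0)

_STAT_PAIRING = {
    # statistic -> (radius field, thickness field); extremes use the
    # stress-maximizing / stress-minimizing pairings.
    "mean": ("r_mean", "w_mean"),
    "max": ("r_max", "w_min"),
    "min": ("r_min", "w_max"),
}


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ThinMembraneResult:
    ratio: float
    is_thin: bool
    band: str  # "thin" | "approaches" | "thick"


@dataclass(frozen=True)
class ChamberStressSummary:
    """Derived stress quantities for one chamber (one report row)."""

    name: str
    shape_model: str
    s: float
    thinness: float
    gsf_mean: float
    gsf_max: float
    gsf_min: float
    thin_ok: bool
    thin_band: str
    t_n_mean: Optional[float] = None
    t_n_max: Optional[float] = None
    t_n_min: Optional[float] = None
    reference: Optional[str] = None
    reference_gsf_mean: Optional[float] = None

    @property
    def is_normalized(self) -> bool:
        return self.t_n_mean is not None

    def _display(self, gsf: float) -> float:
        if self.reference_gsf_mean is None:
            raise ValueError(f"chamber {self.name!r} has not been normalized")
        return round1(gsf / round1(self.reference_gsf_mean))

    @property
    def t_n_mean_display(self) -> float:
        """One-decimal t_n under the rounded-reference display convention."""
        return self._display(self.gsf_mean)

    @property
    def t_n_max_display(self) -> float:
        return self._display(self.gsf_max)

    @property
    def t_n_min_display(self) -> float:
        return self._display(self.gsf_min)


def thinness_ratio(m: ChamberMeasurement, statistic: str = "mean") -> float:
    """Radius-to-thickness ratio r/w for one statistic.

    ``mean`` pairs means; ``max`` pairs r_max with w_min (the widest
    physically recorded stress envelope) and ``min`` pairs r_min with w_max.
    """
    try:
        r_field, w_field = _STAT_PAIRING[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {list(_STAT_PAIRING)}")
    r = getattr(m, r_field)
    w = getattr(m, w_field)
    if w == 0:
        raise ZeroDivisionError(f"chamber {m.name!r}: zero wall thickness")
    return r / w


def thin_membrane_check(m: ChamberMeasurement) -> ThinMembraneResult:
    """Check the mean r/w against the thin-membrane criterion (>= 5).

    Ratios in [4, 5) are labelled "approaches": membrane theory is still a
    reasonable first approximation there, but the report makes borderline
    chambers visible rather than silently passing or failing them.
    """
    ratio = thinness_ratio(m, "mean")
    if ratio >= THIN_CRITERION:
        band = "thin"
    elif APPROACHES_BAND[0] <= ratio < APPROACHES_BAND[1]:
        band = "approaches"
    else:
        band = "thick"
    return ThinMembraneResult(ratio=ratio, is_thin=ratio >= THIN_CRITERION, band=band)


def chamber_shape_coefficient(m: ChamberMeasurement) -> float:
    """Shape coefficient for a chamber's assigned shell model.

    For the torus the coefficient is the inner-equator concentration factor
    (2R - r)/(2(R - r)) > 1, the anticlastic correction to the straight
    cylinder; all other shapes go through the ellipsoid closed form.
    """
    if m.shape_model == "cylinder":
        return shape_coefficient(EllipsoidGeometry.cylinder(m.r_mean))
    if m.shape_model == "sphere":
        return shape_coefficient(EllipsoidGeometry.sphere(m.r_mean))
    if m.shape_model == "ellipsoid":
        return shape_coefficient(EllipsoidGeometry(a=m.a, b=m.b))
    if m.shape_model == "torus":
        geom = TorusGeometry(r_tube=m.r_tube, R_loop=m.R_loop)
        inner, _ = torus_equatorial_factors(geom, w=1.0)
        return inner / geom.r_tube  # strip the r/w part: factor relative to cylinder
    raise ValueError(f"unknown shape model {m.shape_model!r}")


def summarize_chamber(m: ChamberMeasurement) -> ChamberStressSummary:
    """Compute s, thinness and per-statistic GSF for one chamber (t_n unset)."""
    s = chamber_shape_coefficient(m)
    thin = thin_membrane_check(m)
    gsf = {
        stat: geometric_stress_factor(s, *(getattr(m, f) for f in _STAT_PAIRING[stat]))
        for stat in _STAT_PAIRING
    }
    return ChamberStressSummary(
        name=m.name,
        shape_model=m.shape_model,
        s=s,
        thinness=thin.ratio,
        gsf_mean=gsf["mean"],
        gsf_max=gsf["max"],
        gsf_min=gsf["min"],
        thin_ok=thin.is_thin,
        thin_band=thin.band,
    )


def summarize_set(ms: MeasurementSet) -> list[ChamberStressSummary]:
    return [summarize_chamber(m) for m in ms]


def normalize(
    summaries: Sequence[ChamberStressSummary],
    reference: str = "auto",
) -> list[ChamberStressSummary]:
    """Fill in normalized hoop stresses t_n = GSF / GSF_reference.

    ``reference="auto"`` selects the chamber with the smallest mean GSF, so
    the reference t_n is exactly 1.0 and all mean t_n are >= 1.  Normalized
    stress is pressure-free: the common transmural pressure cancels.
    """
    if not summaries:
        raise ValueError("cannot normalize an empty summary collection")
    if reference == "auto":
        ref = min(summaries, key=lambda s: s.gsf_mean)
    else:
        matches = [s for s in summaries if s.name == reference]
        if not matches:
            known = [s.name for s in summaries]
            raise KeyError(f"unknown reference chamber {reference!r}; known chambers: {known}")
        ref = matches[0]
    out = []
    for s in summaries:
        out.append(
            dataclasses.replace(
                s,
                t_n_mean=1.0 if s.name == ref.name else s.gsf_mean / ref.gsf_mean,
                t_n_max=s.gsf_max / ref.gsf_mean,
                t_n_min=s.gsf_min / ref.gsf_mean,
                reference=ref.name,
                reference_gsf_mean=ref.gsf_mean,
            )
        )
    return out


@dataclass(frozen=True)
class ExtremesResult:
    """Per-chamber normalized-stress splay plus inter-individual disparity.

    ``table`` holds t_n_min / t_n_mean / t_n_max per chamber (all relative
    to the reference chamber's *mean* GSF).  Because per-individual (r, w)
    pairs are not published, the extremes pair r_max with w_min (and vice
    versa): the widest envelope consistent with the recorded ranges.

    The largest-individual disparity depends on what the reference
    denominator is, so both candidate conventions are reported:
    ``max_over_reference_mean`` divides the largest chamber GSF by the
    reference chamber's mean GSF; ``max_over_reference_min`` divides by the
    reference chamber's minimum GSF.
    """

    table: pd.DataFrame
    reference: str
    max_over_reference_mean: float
    max_over_reference_min: float


def extremes_analysis(summaries: Sequence[ChamberStressSummary]) -> ExtremesResult:
    """Individual-extremes splay table for normalized summaries."""
    if not summaries:
        raise ValueError("empty summary collection")
    if not all(s.is_normalized for s in summaries):
        raise ValueError("summaries must be normalized before extremes analysis")
    table = pd.DataFrame(
        {
            "t_n_min": [s.t_n_min for s in summaries],
            "t_n_mean": [s.t_n_mean for s in summaries],
            "t_n_max": [s.t_n_max for s in summaries],
        },
        index=pd.Index([s.name for s in summaries], name="chamber"),
    )
    ref_name = summaries[0].reference
    ref = next(s for s in summaries if s.name == ref_name)
    peak = max(summaries, key=lambda s: s.gsf_max)
    return ExtremesResult(
        table=table,
        reference=ref_name,
        max_over_reference_mean=peak.gsf_max / ref.gsf_mean,
        max_over_reference_min=peak.gsf_max / ref.gsf_min,
    )


_SERIAL_FIELDS = [f.name for f in dataclasses.fields(ChamberStressSummary)]


def _summary_frame(summaries: Sequence[ChamberStressSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dataclasses.asdict(s)
        row["t_n_mean_display"] = s.t_n_mean_display
        row["t_n_max_display"] = s.t_n_max_display
        row["t_n_min_display"] = s.t_n_min_display
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(summaries: Sequence[ChamberStressSummary], format: str = "table") -> str:
    """Render normalized summaries as a table, CSV, or JSON report.

    The ``table`` format mirrors the published column order — shape model,
    s, r/w, GSF, t_n — with one-decimal display values; ``csv`` and ``json``
    carry full precision (JSON round-trips via :func:`summaries_from_json`).
    """
    if not summaries:
        raise ValueError("cannot report on an empty summary collection")
    if not all(s.is_normalized for s in summaries):
        raise ValueError("summaries must be normalized before reporting")
    if format == "table":
        df = pd.DataFrame(
            {
                "Chamber": [s.name for s in summaries],
                "Shape": [s.shape_model.capitalize() for s in summaries],
                "s": [f"{round1(s.s):.1f}" for s in summaries],
                "r/w": [f"{round1(s.thinness):.1f}" for s in summaries],
                "GSF": [f"{round1(s.gsf_mean):.1f}" for s in summaries],
                "t_n": [f"{s.t_n_mean_display:.1f}" for s in summaries],
                "thin": [s.thin_band for s in summaries],
            }
        )
        return df.to_string(index=False)
    if format == "csv":
        buf = io.StringIO()
        _summary_frame(summaries).to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        records = []
        for s in summaries:
            rec = {k: getattr(s, k) for k in _SERIAL_FIELDS}
            rec["t_n_mean_display"] = s.t_n_mean_display
            rec["t_n_max_display"] = s.t_n_max_display
            rec["t_n_min_display"] = s.t_n_min_display
            records.append(rec)
        return json.dumps(records, indent=2, ensure_ascii=False)
    raise ValueError(f"unknown report format {format!r}; expected table, csv, or json")


def summaries_from_json(text: str) -> list[ChamberStressSummary]:
    """Reconstruct summaries from a JSON report (inverse of json format)."""
    records = json.loads(text)
    out = []
    for rec in records:
        out.append(ChamberStressSummary(**{k: rec[k] for k in _SERIAL_FIELDS if k in rec}))
    return out
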
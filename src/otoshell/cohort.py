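"""Seeded synthetic morphometry cohorts.

Published chamber morphometry is summarized as mean (max/min) over a small
number of fish; the per-individual (w, r) pairs are not available.  This
module draws synthetic individuals inside stated per-chamber ranges so the
stress pipeline and its invariants can be exercised end to end without real
data.  Thickness and radius are drawn independently within each chamber
(no covariance information exists to do better), either uniformly over
(min, max) — the default, since only ranges are published — or from a
normal truncated to the range for sensitivity checks.

Summarizing a cohort back to a measurement set uses the same reduction the
published table uses: per-chamber mean plus observed extremes.  Note that a
GSF computed from such a summary is s * mean(r) / mean(w), a ratio of means
— not the mean of per-individual ratios s * mean(r/w); the two differ
whenever thickness varies.

A single integer seed governs the whole cohort; per-chamber substreams are
spawned from it deterministically, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import (
    SHAPE_MODELS,
    ChamberMeasurement,
    MeasurementSet,
    MeasurementValidationError,
    toadfish_fixture,
)

__all__ = [
    "ChamberSpec",
    "CohortSpec",
    "SyntheticCohort",
    "toadfish_cohort_spec",
    "generate_cohort",
    "cohort_to_measurements",
    "spec_to_json",
    "spec_from_json",
]

_DISTRIBUTIONS = ("uniform", "truncnorm")


@dataclass(frozen=True)
class ChamberSpec:
    """Sampling ranges (microns) and distribution for one chamber.

    For ``truncnorm``, the location defaults to the range midpoint and the
    scale to a quarter of the range width unless given explicitly.
    """

    name: str
    shape_model: str
    w_min: float
    w_max: float
    r_min: float
    r_max: float
    distribution: str = "uniform"
    w_loc: Optional[float] = None
    w_scale: Optional[float] = None
    r_loc: Optional[float] = None
    r_scale: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    r_tube: Optional[float] = None
    R_loop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape_model not in SHAPE_MODELS:
            raise MeasurementValidationError(
                f"chamber {self.name!r}: unknown shape_model {self.shape_model!r}"
            )
        if self.distribution not in _DISTRIBUTIONS:
            raise MeasurementValidationError(
                f"chamber {self.name!r}: unknown distribution {self.distribution!r}; "
                f"expected one of {_DISTRIBUTIONS}"
            )
        for prefix, lo, hi in (("w", self.w_min, self.w_max), ("r", self.r_min, self.r_max)):
            if not (0 < lo <= hi and math.isfinite(hi)):
                raise MeasurementValidationError(
                    f"chamber {self.name!r}: require 0 < {prefix}_min <= {prefix}_max, "
                    f"got {lo} / {hi}"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of synthetic individuals: chamber specs, size, and seed."""

    chambers: tuple[ChamberSpec, ...]
    n_individuals: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chambers", tuple(self.chambers))
        if not self.chambers:
            raise MeasurementValidationError("cohort spec must contain at least one chamber")
        names = [c.name for c in self.chambers]
        if len(set(names)) != len(names):
            raise MeasurementValidationError("cohort chamber names must be unique")
        if self.n_individuals < 1:
            raise MeasurementValidationError(
                f"n_individuals must be >= 1, got {self.n_individuals}"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """Per-individual, per-chamber (w, r) draws with the generating spec.

    ``data`` has one row per (individual, chamber) with columns
    individual, chamber, w, r.
    """

    data: pd.DataFrame
    spec: CohortSpec


def toadfish_cohort_spec(n_individuals: int = 20, seed: int = 0) -> CohortSpec:
    """Cohort spec with the toadfish chambers' published min/max ranges.

    Defaults emulate the published sampling effort: 20 individuals (the
    source means reflect 12-25 measurements) drawn uniformly within each
    chamber's recorded range.
    """
    chambers = tuple(
        ChamberSpec(
            name=m.name,
            shape_model=m.shape_model,
            w_min=m.w_min,
            w_max=m.w_max,
            r_min=m.r_min,
            r_max=m.r_max,
        )
        for m in toadfish_fixture()
    )
    return CohortSpec(chambers=chambers, n_individuals=n_individuals, seed=seed)


def _draw(rng: np.random.Generator, lo: float, hi: float, n: int,
          distribution: str, loc: Optional[float], scale: Optional[float]) -> np.ndarray:
    if hi == lo:
        return np.full(n, float(lo))
    if distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    loc = (lo + hi) / 2.0 if loc is None else loc
    scale = (hi - lo) / 4.0 if scale is None else scale
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort deterministically from its spec.

    Chambers use independent substreams spawned from the single cohort
    seed, so adding a chamber never perturbs another chamber's draws.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.chambers))
    frames = []
    for chamber, stream in zip(spec.chambers, streams):
        rng = np.random.default_rng(stream)
        n = spec.n_individuals
        w = _draw(rng, chamber.w_min, chamber.w_max, n, chamber.distribution,
                  chamber.w_loc, chamber.w_scale)
        r = _draw(rng, chamber.r_min, chamber.r_max, n, chamber.distribution,
                  chamber.r_loc, chamber.r_scale)
        frames.append(
            pd.DataFrame(
                {"individual": np.arange(n), "chamber": chamber.name, "w": w, "r": r}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return SyntheticCohort(data=data, spec=spec)


def cohort_to_measurements(cohort: SyntheticCohort) -> MeasurementSet:
    """Summarize a cohort the way the published table does.

    Per chamber: w_mean/r_mean are cohort averages, w_max/w_min and
    r_max/r_min the observed extremes.  Shape parameters carry over from
    the generating spec.
    """
    if len(cohort.data) == 0:
        raise MeasurementValidationError("cannot summarize an empty cohort")
    chambers = []
    for chamber in cohort.spec.chambers:
        sub = cohort.data[cohort.data["chamber"] == chamber.name]
        chambers.append(
            ChamberMeasurement(
                name=chamber.name,
                shape_model=chamber.shape_model,
                w_mean=float(sub["w"].mean()),
                w_max=float(sub["w"].max()),
                w_min=float(sub["w"].min()),
                r_mean=float(sub["r"].mean()),
                r_max=float(sub["r"].max()),
                r_min=float(sub["r"].min()),
                a=chamber.a, b=chamber.b,
                r_tube=chamber.r_tube, R_loop=chamber.R_loop,
            )
        )
    prov = (
        f"synthetic cohort: n={cohort.spec.n_individuals}, seed={cohort.spec.seed}, "
        f"summarized as per-chamber mean and observed extremes"
    )
    return MeasurementSet(chambers=tuple(chambers), provenance=prov)


def spec_to_json(spec: CohortSpec) -> str:
    payload = {
        "n_individuals": spec.n_individuals,
        "seed": spec.seed,
        "chambers": [asdict(c) for c in spec.chambers],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False)


def spec_from_json(text: str | Path) -> CohortSpec:
    """Parse a cohort spec from a JSON string or file path."""
    if isinstance(text, Path):
        text = text.read_text(encoding="utf-8")
    payload = json.loads(text)
    chambers = tuple(ChamberSpec(**c) for c in payload["chambers"])
    return CohortSpec(
        chambers=chambers,
        n_individuals=payload.get("n_individuals", 20),
        seed=payload.get("seed", 0),
    )
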
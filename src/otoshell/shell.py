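"""Closed-form membrane stress in pressurized thin shells of revolution.

Membrane (no-bending) shell theory for an internally pressurized shell of
revolution gives the two principal wall stresses from the local principal
radii of curvature ``r1`` (meridional) and ``r2`` (normal, i.e. the distance
along the surface normal to the axis of revolution):

    meridional = p * r2 / (2 w)
    hoop       = (p * r2 / w) * (1 - r2 / (2 r1))

For a prolate ellipsoid of revolution with equatorial radius ``a`` and polar
semi-axis ``b``, the hoop stress peaks at the equator, where it reduces to

    hoop_peak = s * (a / w) * p,      s = 1 - a**2 / (2 b**2)

``s`` is the *shape coefficient*: 0.5 for a sphere (a = b) and exactly 1.0 in
the cylinder limit (b unbounded, represented here by ``math.inf``).  The
dimensionless product ``GSF = s * r / w`` — the geometric stress factor —
converts transmural pressure into peak hoop stress and is the quantity the
rest of the package compares across chambers of the membranous labyrinth.

Radii are luminal (inner-surface) radii as measured; no midwall correction
is applied.  Lengths are in microns throughout; pressure is in arbitrary
consistent units, and most results are reported per unit pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CYLINDER",
    "GeometryError",
    "LoadError",
    "EllipsoidGeometry",
    "TorusGeometry",
    "LoadCondition",
    "ShellStressState",
    "shape_coefficient",
    "geometric_stress_factor",
    "peak_hoop_stress",
    "principal_radii",
    "meridian_stress_profile",
    "torus_equatorial_factors",
]

#: Sentinel for an unbounded semimajor axis (the cylinder limit of the
#: ellipsoid of revolution).  Using IEEE infinity keeps the limit exact.
CYLINDER = math.inf


class GeometryError(ValueError):
    """Raised for geometrically invalid shell parameters."""


class LoadError(ValueError):
    """Raised for physically invalid load conditions (negative pressure)."""


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Ellipsoid of revolution emulating a membranous chamber.

    Parameters
    ----------
    a : float
        Semiminor (equatorial) radius in microns.  Must be positive.
    b : float
        Semimajor (polar) semi-axis in microns.  ``math.inf`` (the module
        constant :data:`CYLINDER`) denotes the cylinder limit.  Defaults to
        the cylinder.
    allow_oblate : bool
        The labyrinthine continuum runs sphere -> prolate -> cylinder, so
        oblate shapes (b < a) are rejected unless this flag is set.
    """

    a: float
    b: float = CYLINDER
    allow_oblate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (isinstance(self.a, (int, float)) and math.isfinite(self.a) and self.a > 0):
            raise GeometryError(f"semiminor radius a must be finite and positive, got {self.a!r}")
        if math.isnan(self.b) or self.b <= 0:
            raise GeometryError(f"semimajor semi-axis b must be positive, got {self.b!r}")
        if self.b < self.a and not self.allow_oblate:
            raise GeometryError(
                f"oblate geometry (b={self.b} < a={self.a}) rejected; "
                "pass allow_oblate=True to override"
            )

    @property
    def is_sphere(self) -> bool:
        return self.b == self.a

    @property
    def is_cylinder(self) -> bool:
        return math.isinf(self.b)

    @classmethod
    def sphere(cls, radius: float) -> "EllipsoidGeometry":
        return cls(a=radius, b=radius)

    @classmethod
    def cylinder(cls, radius: float) -> "EllipsoidGeometry":
        return cls(a=radius, b=CYLINDER)


@dataclass(frozen=True)
class TorusGeometry:
    """Toroidal shell (semicircular-canal loop): tube and centerline radii."""

    r_tube: float
    R_loop: float

    def __post_init__(self) -> None:
        if not (self.r_tube > 0 and math.isfinite(self.r_tube)):
            raise GeometryError(f"tube radius must be finite and positive, got {self.r_tube!r}")
        if not (self.R_loop > self.r_tube):
            raise GeometryError(
                f"loop radius R_loop={self.R_loop!r} must exceed tube radius r_tube={self.r_tube!r}"
            )


@dataclass(frozen=True)
class LoadCondition:
    """Transmural pressure across the membrane, arbitrary consistent units.

    A non-negative resting pressure is assumed: endolymph secretion keeps the
    labyrinth inflated, however slight the excess pressure.
    """

    p: float

    def __post_init__(self) -> None:
        if not (self.p >= 0):
            raise LoadError(f"transmural pressure must be non-negative, got {self.p!r}")


@dataclass(frozen=True)
class ShellStressState:
    """Principal membrane stresses at one latitude of a shell of revolution.

    ``latitude`` is the parametric meridian angle in radians, 0 at the
    equator (the point of peak hoop stress) and +pi/2 at the pole.
    """

    hoop: float
    meridional: float
    latitude: float


def shape_coefficient(geom: EllipsoidGeometry) -> float:
    """Equatorial peak-hoop-stress shape coefficient s = 1 - a^2/(2 b^2).

    Exactly 1.0 in the cylinder limit (b unbounded) and 0.5 for a sphere.
    Strictly decreasing in a/b; in (0.5, 1.0) for all prolate shapes.
    """
    if geom.is_cylinder:
        return 1.0
    return 1.0 - geom.a**2 / (2.0 * geom.b**2)


def geometric_stress_factor(s: float, r: float, w: float) -> float:
    """Geometric stress factor GSF = s * r / w.

    Dimensionless multiplier converting transmural pressure into peak
    membrane hoop stress.  ``r`` is the (luminal) radius of curvature and
    ``w`` the wall thickness, both in the same length unit; the factor is
    invariant under joint rescaling of (r, w).
    """
    if w == 0:
        raise ZeroDivisionError("wall thickness w must be nonzero")
    if w < 0 or r <= 0:
        raise GeometryError(f"radius and thickness must be positive, got r={r!r}, w={w!r}")
    if not s > 0:
        raise GeometryError(f"shape coefficient must be positive, got s={s!r}")
    return s * r / w


def peak_hoop_stress(gsf: float, load: LoadCondition) -> float:
    """Peak hoop stress t = GSF * p, in the units of the pressure ``p``."""
    if not gsf > 0:
        raise GeometryError(f"geometric stress factor must be positive, got {gsf!r}")
    return gsf * load.p


def principal_radii(geom: EllipsoidGeometry, latitude: float) -> tuple[float, float]:
    """Principal radii of curvature (r1 meridional, r2 normal) at a latitude.

    The meridian is parametrized as (a cos t, b sin t) with t = latitude;
    then r1 = (a^2 sin^2 t + b^2 cos^2 t)^(3/2) / (a b) and
    r2 = (a/b) * sqrt(a^2 sin^2 t + b^2 cos^2 t).  For the cylinder,
    r1 is infinite and r2 = a at every interior latitude.
    """
    if geom.is_cylinder:
        if not abs(latitude) < math.pi / 2:
            raise GeometryError(
                f"cylinder profile is open: |latitude| must be < pi/2, got {latitude!r}"
            )
        return math.inf, geom.a
    if not abs(latitude) <= math.pi / 2:
        raise GeometryError(f"|latitude| must be <= pi/2, got {latitude!r}")
    a, b = geom.a, geom.b
    q = a * a * math.sin(latitude) ** 2 + b * b * math.cos(latitude) ** 2
    r1 = q**1.5 / (a * b)
    r2 = (a / b) * math.sqrt(q)
    return r1, r2


def meridian_stress_profile(
    geom: EllipsoidGeometry,
    w: float,
    load: LoadCondition,
    latitude: float = 0.0,
) -> ShellStressState:
    """Membrane stresses at one latitude of a pressurized shell of revolution.

    Evaluates meridional = p r2 / (2 w) and hoop = (p r2 / w)(1 - r2/(2 r1)).
    At the equator the hoop value coincides with the closed-form peak
    ``s * (a/w) * p``; for a sphere both stresses equal p a/(2 w) at every
    latitude, and for a cylinder the meridional (axial) stress is exactly
    half the hoop stress.
    """
    if not (w > 0 and math.isfinite(w)):
        raise GeometryError(f"wall thickness must be finite and positive, got {w!r}")
    r1, r2 = principal_radii(geom, latitude)
    meridional = load.p * r2 / (2.0 * w)
    if math.isinf(r1):
        hoop = load.p * r2 / w
    else:
        hoop = (load.p * r2 / w) * (1.0 - r2 / (2.0 * r1))
    return ShellStressState(hoop=hoop, meridional=meridional, latitude=latitude)


def torus_equatorial_factors(geom: TorusGeometry, w: float) -> tuple[float, float]:
    """Hoop-stress-per-unit-pressure factors at the torus equators.

    For a toroid with tube radius r and loop radius R, membrane theory gives
    hoop factors at the innermost and outermost equatorial circles:

        inner = (r/w) * (2R - r) / (2 (R - r))
        outer = (r/w) * (2R + r) / (2 (R + r))

    The anticlastic inner equator concentrates stress: inner >= r/w >= outer,
    both approaching the straight-cylinder value r/w as R/r grows.  At
    R = 11 r the inner factor is 1.05 * (r/w) — a 5% increase over the
    cylinder, the correction relevant to a slender semicircular-canal loop.
    """
    if not (w > 0 and math.isfinite(w)):
        raise GeometryError(f"wall thickness must be finite and positive, got {w!r}")
    r, R = geom.r_tube, geom.R_loop
    inner = (r / w) * (2.0 * R - r) / (2.0 * (R - r))
    outer = (r / w) * (2.0 * R + r) / (2.0 * (R + r))
    return inner, outer
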
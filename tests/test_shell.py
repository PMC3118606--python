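"""Closed-form shell mechanics: limits, examples, and membrane-theory oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otoshell.shell import (
    CYLINDER,
    EllipsoidGeometry,
    GeometryError,
    LoadCondition,
    LoadError,
    TorusGeometry,
    geometric_stress_factor,
    meridian_stress_profile,
    peak_hoop_stress,
    principal_radii,
    shape_coefficient,
    torus_equatorial_factors,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestShapeCoefficient:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1.0, 1.0, 0.5),       # sphere
            (307.0, 307.0, 0.5),   # sphere at chamber scale
            (1.0, CYLINDER, 1.0),  # cylinder limit, exact
            (556.0, CYLINDER, 1.0),
            (1.0, 2.0, 0.875),     # 1 - 1/8
        ],
    )
    def test_examples(self, a, b, expected):
        assert shape_coefficient(EllipsoidGeometry(a, b)) == expected

    def test_nonpositive_semiminor_rejected(self):
        with pytest.raises(GeometryError):
            EllipsoidGeometry(0.0, 1.0)
        with pytest.raises(GeometryError):
            EllipsoidGeometry(-1.0, 1.0)

    def test_oblate_rejected_without_override(self):
        with pytest.raises(GeometryError):
            EllipsoidGeometry(2.0, 1.0)
        geom = EllipsoidGeometry(2.0, 1.0, allow_oblate=True)
        assert shape_coefficient(geom) == 1.0 - 4.0 / 2.0  # s < 0 for strongly oblate

    @given(a=positive, scale=st.floats(min_value=1.0, max_value=1e3))
    @settings(max_examples=200)
    def test_range_and_monotonicity(self, a, scale):
        """s lies in [0.5, 1) for b >= a and decreases strictly in a/b."""
        b = a * scale
        s = shape_coefficient(EllipsoidGeometry(a, b))
        assert 0.5 <= s < 1.0
        if scale > 1.05:
            # a larger a/b (smaller scale) gives a smaller s
            s_rounder = shape_coefficient(EllipsoidGeometry(a, a * math.sqrt(scale)))
            assert s_rounder < s


class TestGeometricStressFactor:
    @pytest.mark.parametrize(
        "s,r,w,expected,decimals",
        [
            (1.0, 307.0, 70.0, 4.4, 1),   # anterior canal, printed value
            (0.5, 697.0, 58.0, 6.0, 1),   # lateral ampulla, printed value
            (1.0, 50.0, 50.0, 1.0, 12),   # r = w identity
        ],
    )
    def test_examples(self, s, r, w, expected, decimals):
        assert geometric_stress_factor(s, r, w) == pytest.approx(expected, abs=0.5 * 10**-decimals)

    def test_error_paths(self):
        with pytest.raises(ZeroDivisionError):
            geometric_stress_factor(1.0, 10.0, 0.0)
        with pytest.raises(GeometryError):
            geometric_stress_factor(1.0, -10.0, 1.0)
        with pytest.raises(GeometryError):
            geometric_stress_factor(0.0, 10.0, 1.0)

    @given(s=st.floats(min_value=0.5, max_value=1.0), r=positive, w=positive,
           k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200)
    def test_scale_invariance(self, s, r, w, k):
        """GSF depends only on the ratio r/w, not on the absolute scale."""
        assert geometric_stress_factor(s, k * r, k * w) == pytest.approx(
            geometric_stress_factor(s, r, w), rel=1e-12
        )


class TestPeakHoopStress:
    @pytest.mark.parametrize("gsf,p,expected", [(4.4, 0.0, 0.0), (4.4, 1.0, 4.4), (17.4, 2.0, 34.8)])
    def test_examples(self, gsf, p, expected):
        assert peak_hoop_stress(gsf, LoadCondition(p)) == expected

    def test_negative_pressure_rejected(self):
        with pytest.raises(LoadError):
            LoadCondition(-1.0)

    @given(gsf=positive,
           p=st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1e6)))
    @settings(max_examples=100)
    def test_exact_linearity(self, gsf, p):
        """Doubling the pressure exactly doubles the stress (power-of-two scaling)."""
        assert peak_hoop_stress(gsf, LoadCondition(2.0 * p)) == 2.0 * peak_hoop_stress(
            gsf, LoadCondition(p)
        )


def numeric_principal_radii(a, b, t, h=1e-4):
    """Independent curvature oracle: finite differences on the meridian (a cos t, b sin t)."""
    rho = lambda u: a * math.cos(u)
    z = lambda u: b * math.sin(u)
    d = lambda f, u: (f(u + h) - f(u - h)) / (2 * h)
    dd = lambda f, u: (f(u + h) - 2 * f(u) + f(u - h)) / h**2
    rp, zp = d(rho, t), d(z, t)
    rpp, zpp = dd(rho, t), dd(z, t)
    speed = math.hypot(rp, zp)
    r1 = speed**3 / abs(rp * zpp - zp * rpp)
    r2 = rho(t) * speed / abs(zp)
    return r1, r2


class TestMeridianProfile:
    @pytest.mark.parametrize("t", [-1.2, -0.5, 0.0, 0.3, 1.0])
    def test_closed_form_radii_match_numerical_curvature(self, t):
        geom = EllipsoidGeometry(1.3, 2.7)
        r1, r2 = principal_radii(geom, t)
        n1, n2 = numeric_principal_radii(1.3, 2.7, t)
        assert r1 == pytest.approx(n1, rel=1e-6)
        assert r2 == pytest.approx(n2, rel=1e-6)

    def test_sphere_isotropic_and_constant(self):
        """On a sphere, hoop = meridional = p a / (2 w) at every latitude."""
        geom = EllipsoidGeometry.sphere(697.0)
        load = LoadCondition(1.0)
        values = []
        for t in np.linspace(-math.pi / 2, math.pi / 2, 31):
            st_ = meridian_stress_profile(geom, 58.0, load, t)
            assert st_.hoop == pytest.approx(st_.meridional, rel=1e-12)
            values.append(st_.hoop)
        expected = 697.0 / (2 * 58.0)
        assert max(values) - min(values) < 1e-12 * expected
        assert values[0] == pytest.approx(expected, rel=1e-12)

    def test_cylinder_axial_is_half_hoop(self):
        state = meridian_stress_profile(EllipsoidGeometry.cylinder(307.0), 70.0, LoadCondition(3.0), 0.0)
        assert state.meridional / state.hoop == pytest.approx(0.5, rel=1e-15)
        assert state.hoop == pytest.approx(3.0 * 307.0 / 70.0, rel=1e-15)

    def test_equatorial_example(self):
        state = meridian_stress_profile(EllipsoidGeometry(1.0, 2.0), 0.1, LoadCondition(1.0), 0.0)
        assert state.hoop == pytest.approx(8.75, rel=1e-12)

    def test_equator_matches_shape_coefficient_form(self):
        """The general profile at latitude 0 reduces to s * (a/w) * p."""
        rng = np.random.default_rng(20110608)
        load = LoadCondition(1.0)
        for _ in range(1000):
            a = rng.uniform(1.0, 1000.0)
            b = a * rng.uniform(1.0, 50.0)
            w = rng.uniform(0.1, 100.0)
            geom = EllipsoidGeometry(a, b)
            closed = peak_hoop_stress(
                geometric_stress_factor(shape_coefficient(geom), a, w), load
            )
            assert meridian_stress_profile(geom, w, load, 0.0).hoop == pytest.approx(
                closed, rel=1e-9
            )

    def test_invalid_latitude_rejected(self):
        with pytest.raises(GeometryError):
            meridian_stress_profile(EllipsoidGeometry.cylinder(1.0), 0.1, LoadCondition(1.0), math.pi / 2)
        with pytest.raises(GeometryError):
            meridian_stress_profile(EllipsoidGeometry(1.0, 2.0), 0.1, LoadCondition(1.0), 2.0)


class TestTorus:
    def test_five_percent_at_slender_loop(self):
        """R = 11 r puts the inner-equator stress 5% above the straight cylinder."""
        inner, outer = torus_equatorial_factors(TorusGeometry(1.0, 11.0), 1.0)
        assert inner == pytest.approx(21.0 / 20.0, rel=1e-15)
        assert outer < 1.0

    def test_direct_evaluation(self):
        inner, _ = torus_equatorial_factors(TorusGeometry(1.0, 2.0), 0.1)
        assert inner == pytest.approx(15.0, rel=1e-12)

    def test_ordering_and_cylinder_limit(self):
        """inner >= r/w >= outer; both approach r/w monotonically as R/r grows."""
        r, w = 5.0, 0.5
        cylinder = r / w
        previous_inner = math.inf
        for ratio in [1.5, 2.0, 5.0, 20.0, 100.0, 1e4, 1e8]:
            inner, outer = torus_equatorial_factors(TorusGeometry(r, ratio * r), w)
            assert inner >= cylinder >= outer
            assert inner < previous_inner
            previous_inner = inner
        assert inner == pytest.approx(cylinder, rel=1e-7)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            TorusGeometry(2.0, 2.0)
        with pytest.raises(GeometryError):
            TorusGeometry(3.0, 2.0)
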
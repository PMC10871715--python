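"""The ROAR surface g(x, y): rational form, polynomial expansion, gradient, h."""

from fractions import Fraction

import numpy as np
import pytest

import roar


def _cleared_rational(surface, x, y):
    """Denominator-cleared g computed directly from the restored table (oracle)."""
    a, b, c, d = surface.table.cells()
    if surface.direction is roar.Direction.RR_GT_1:
        ra, rb, rc, rd = a, b + x, c + y, d
    else:
        ra, rb, rc, rd = a + x, b, c, d + y
    num = (ra + rb + rc + rd) * (ra * rd - rb * rc) ** 2
    den = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
    return num - surface.nu_c * den


def test_g_at_origin_is_chi_square_minus_threshold(example_surface, example_table, nu05):
    expected = roar.chi_square_statistic(example_table) - nu05
    assert example_surface.g_value(0.0, 0.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(4.492, abs=5e-4)


def test_g_at_equal_risk_restoration(example_surface, nu05):
    # x = ad/c - b = 40 equalizes arm risks; restored chi-square is exactly 0
    assert example_surface.g_value(40.0, 0.0) == pytest.approx(-nu05, rel=1e-12)


def test_g_near_printed_fock_point(example_surface):
    # the published FOCK point (6.89, 4.79) lies just inside the exact-threshold region
    value = example_surface.g_value(6.89, 4.79)
    assert -0.1 < value < 0.0


@pytest.mark.parametrize("direction", [roar.Direction.RR_GT_1, roar.Direction.RR_LT_1])
def test_expansion_structure(example_table, nu05, direction):
    surface = roar.RoarSurface(example_table, direction, nu05)
    coeffs = surface.expand_polynomial()
    assert len(coeffs) <= 15
    assert all(0 <= i <= 3 and 0 <= j <= 3 for i, j in coeffs)
    assert (3, 3) not in coeffs


def test_expansion_constant_term_exact(example_surface, example_table, nu05):
    a, b, c, d = example_table.cells()
    n = example_table.n
    exact = float(
        Fraction(n * (a * d - b * c) ** 2)
    ) - nu05 * float(Fraction((a + b) * (c + d) * (a + c) * (b + d)))
    assert example_surface.expand_polynomial()[(0, 0)] == pytest.approx(exact, rel=1e-12)


@pytest.mark.parametrize("direction", [roar.Direction.RR_GT_1, roar.Direction.RR_LT_1])
def test_polynomial_matches_cleared_rational(example_table, nu05, direction):
    surface = roar.RoarSurface(example_table, direction, nu05)
    rng = np.random.default_rng(7)
    pts = rng.uniform(0.0, 50.0, size=(1000, 2))
    poly = surface.g_poly_value(pts[:, 0], pts[:, 1])
    cleared = _cleared_rational(surface, pts[:, 0], pts[:, 1])
    scale = surface._g_scale(pts[:, 0], pts[:, 1])
    assert np.all(np.abs(poly - cleared) <= 1e-9 * scale)


def test_unit_table_zero_threshold_factors():
    # with nu_c = 0 the polynomial reduces to (4+x+y) * (1-(1+x)(1+y))^2
    surface = roar.RoarSurface(
        roar.DichotomousTable(1, 1, 1, 1), roar.Direction.RR_GT_1, 0.0
    )
    rng = np.random.default_rng(3)
    for x, y in rng.uniform(0.0, 5.0, size=(50, 2)):
        expected = (4 + x + y) * (1 - (1 + x) * (1 + y)) ** 2
        assert surface.g_poly_value(x, y) == pytest.approx(expected, rel=1e-12)


def test_gradient_matches_finite_differences(example_surface):
    rng = np.random.default_rng(11)
    step = 1e-5
    for x, y in rng.uniform(0.5, 40.0, size=(100, 2)):
        gx, gy = example_surface.grad_g(x, y)
        fd_x = (
            example_surface.g_poly_value(x + step, y)
            - example_surface.g_poly_value(x - step, y)
        ) / (2 * step)
        fd_y = (
            example_surface.g_poly_value(x, y + step)
            - example_surface.g_poly_value(x, y - step)
        ) / (2 * step)
        scale = example_surface._g_scale(x, y)
        assert abs(gx - fd_x) <= 1e-5 * (abs(gx) + 1e-6 * scale)
        assert abs(gy - fd_y) <= 1e-5 * (abs(gy) + 1e-6 * scale)


def test_mirror_symmetry_of_g(example_table, mirror_table, nu05):
    surface = roar.RoarSurface(example_table, roar.Direction.RR_GT_1, nu05)
    mirrored = roar.RoarSurface(mirror_table, roar.Direction.RR_LT_1, nu05)
    rng = np.random.default_rng(5)
    for x, y in rng.uniform(0.0, 30.0, size=(200, 2)):
        assert mirrored.g_value(x, y) == pytest.approx(surface.g_value(y, x), rel=1e-10)
        gx, gy = surface.grad_g(x, y)
        mx, my = mirrored.grad_g(y, x)
        assert mx == pytest.approx(gy, rel=1e-9)
        assert my == pytest.approx(gx, rel=1e-9)


def test_h_vanishes_at_origin_and_reduces_on_axes(example_surface):
    assert example_surface.h_value(0.0, 0.0) == 0.0
    for y in (1.0, 7.3, 20.0):
        gx, _ = example_surface.grad_g(0.0, y)
        assert example_surface.h_value(0.0, y) == pytest.approx(y * gx, rel=1e-12)
    for x in (1.0, 7.3, 20.0):
        _, gy = example_surface.grad_g(x, 0.0)
        assert example_surface.h_value(x, 0.0) == pytest.approx(-x * gy, rel=1e-12)


def test_h_vanishes_at_solved_fock_point(example_surface):
    point, _ = roar.fock_point(example_surface)
    scale = example_surface._h_scale(point.x, point.y)
    assert abs(example_surface.h_value(point.x, point.y)) < 1e-6 * scale


def test_contains_membership(example_surface):
    assert not example_surface.contains(0.0, 0.0)
    assert example_surface.contains(40.0, 0.0)
    assert example_surface.contains(9.0, 2.0)
    assert not example_surface.contains(8.0, 2.0)


def test_boundary_slice_roots(example_surface):
    assert example_surface.boundary_slice(1000.0) == []
    ys = example_surface.boundary_slice(0.0)
    assert 16.5 < ys[0] < 16.6
    for x in (0.0, 2.0, 5.0, 9.0):
        for y in example_surface.boundary_slice(x):
            residual = abs(example_surface.g_poly_value(x, y))
            assert residual < 1e-8 * max(example_surface._g_scale(x, y), 1.0)
    assert example_surface.boundary_slice(0.0) == sorted(example_surface.boundary_slice(0.0))


def test_region_bounded_on_x_axis(example_surface):
    """The axis cubic's two positive roots straddle the equal-risk point x=40."""
    coeffs = np.asarray(example_surface.poly[:, 0], dtype=float)
    roots = [r.real for r in np.roots(coeffs[::-1]) if abs(r.imag) < 1e-9 and r.real > 0]
    assert len(roots) == 2
    assert min(roots) < 40.0 < max(roots)


def test_sign_anchor_for_significant_fixtures(fixture_tables, nu05):
    for table in fixture_tables:
        surface = roar.RoarSurface(table, roar.classify_direction(table), nu05)
        assert surface.g_value(0.0, 0.0) > 0.0
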
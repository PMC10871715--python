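"""Region of Attainable Redaction (ROAR) analysis for 2x2 dichotomous-outcome tables.

ROAR quantifies how fragile an ostensibly significant trial result is to
*data redaction*: the omission (accidental, systematic, or deliberate) of
subjects from a reported analysis.  Given reported counts

    a  experimental endpoint-positive      b  experimental endpoint-negative
    c  control endpoint-positive           d  control endpoint-negative

we ask how many hypothetically redacted subjects x (experimental arm) and
y (control arm), restored to the cells that would have worked *against* the
reported effect, would drop the Pearson chi-square statistic of the restored
table below the significance threshold ``nu_c``.  The locus g(x, y) = 0 of
the threshold identity bounds a region in the non-negative quadrant (the
ROAR); any point inside it is a redaction pattern that nullifies the result.

The headline summary is the FOCK vector (Fewest Observations / Censored
Knowledge): the minimum-Euclidean-length vector from the origin to the ROAR
boundary, found by Lagrange multipliers — solving g = 0 together with
h = y*dg/dx - x*dg/dy = 0.  Axis intercepts x_c and y_c give the minimal
single-arm redactions, and the tolerances rho_E, rho_C, rho_A express these
as fractions of the experimental arm, control arm, and total sample.

The module is laid out in the order the method runs:

1. tables and classical statistics (chi-square, risk ratio, direction)
2. the ROAR surface g, its polynomial expansion, gradient, and h
3. the FOCK solver and redaction metrics
4. pooling of per-study tables with the CMH confounding gate
5. brute-force oracles and a seeded fixture generator
6. report building and boundary export (consumed by the CLI)
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats

__version__ = "1.0.0"

__all__ = [
    "RoarError",
    "MarginError",
    "DegenerateEffectError",
    "NoEffectError",
    "SolverError",
    "BoundExceededError",
    "GeneratorError",
    "Direction",
    "DichotomousTable",
    "SignificanceThreshold",
    "EffectEstimate",
    "chi_square_statistic",
    "chi_square_p_value",
    "relative_risk",
    "classify_direction",
    "critical_value",
    "RedactionPair",
    "RoarSurface",
    "FockResult",
    "axis_intercept_x",
    "axis_intercept_y",
    "fock_point",
    "r_min",
    "redaction_metrics",
    "analyze",
    "StudyTable",
    "PooledAnalysis",
    "pooled_table",
    "pooled_crude_rr",
    "cmh_rr",
    "assess_pooling",
    "read_studies_csv",
    "OracleResult",
    "integer_min_redaction",
    "grid_min_distance",
    "random_significant_table",
    "build_report",
    "export_boundary",
]

# --------------------------------------------------------------------------
# Configuration: numerical tolerances and defaults
# --------------------------------------------------------------------------

#: Default significance level; nu_c is always derived from alpha at run time.
DEFAULT_ALPHA = 0.05

#: Default confounding gate for pooled meta-analysis tables (|1 - RR_CMH/RR_C|).
DEFAULT_CONFOUNDING_THRESHOLD = 0.10

#: Solver convergence: |g| and |h| below RESIDUAL_RTOL times the local
#: magnitude of the respective polynomial (sum of |coeff| * x^i * y^j).
RESIDUAL_RTOL = 1e-9

#: Acceptance residual for boundary/root candidates (looser than convergence).
ROOT_RESIDUAL_RTOL = 1e-8

#: A candidate root is real if |Im| <= this times (1 + |Re|).
ROOT_IMAG_RTOL = 1e-7

#: Coordinates this far below zero are clamped to the axis.
AXIS_CLAMP = 1e-9

MAX_NEWTON_ITER = 100

#: Number of scan intervals used to seed the FOCK Newton iteration.
FOCK_SCAN_SLICES = 4096

#: Rejection-sampling cap for the fixture generator.
MAX_GENERATOR_DRAWS = 100_000


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class RoarError(Exception):
    """Base class for all ROAR-specific errors."""


class MarginError(RoarError, ValueError):
    """A margin of the 2x2 table is zero; chi-square and RR are undefined."""


class DegenerateEffectError(RoarError, ValueError):
    """No finite effect estimate (e.g. zero event count in an arm)."""


class NoEffectError(RoarError, ValueError):
    """Relative risk is exactly 1; there is no effect direction to redact toward."""


class SolverError(RoarError, RuntimeError):
    """FOCK solver failed to converge; carries the best candidate found."""

    def __init__(self, message: str, best: "RedactionPair | None" = None):
        super().__init__(message)
        self.best = best


class BoundExceededError(RoarError, RuntimeError):
    """Exhaustive integer search found no feasible redaction within the bound."""


class GeneratorError(RoarError, RuntimeError):
    """Fixture generator exhausted its rejection-sampling budget."""


# --------------------------------------------------------------------------
# Section 1 — 2x2 tables and classical statistics
# --------------------------------------------------------------------------


class Direction(enum.Enum):
    """Effect direction of the reported table.

    ``RR_GT_1`` (experimental risk higher): redaction restores x
    endpoint-negatives to the experimental arm and y endpoint-positives to
    the control arm (restored table a, b+x / c+y, d).  ``RR_LT_1`` is the
    mirror scheme (restored table a+x, b / c, d+y).
    """

    RR_GT_1 = "rr-gt-1"
    RR_LT_1 = "rr-lt-1"

    @classmethod
    def from_string(cls, text: str) -> "Direction":
        for member in cls:
            if member.value == text:
                return member
        raise ValueError(f"unknown direction {text!r}; expected 'rr-gt-1' or 'rr-lt-1'")

    def flipped(self) -> "Direction":
        return Direction.RR_LT_1 if self is Direction.RR_GT_1 else Direction.RR_GT_1


def _as_count(value, name: str) -> int:
    if isinstance(value, bool):
        raise ValueError(f"{name} must be an integer count, got bool")
    if isinstance(value, (int, np.integer)):
        out = int(value)
    elif isinstance(value, float) and value.is_integer():
        out = int(value)
    else:
        raise ValueError(f"{name} must be an integer count, got {value!r}")
    if out < 0:
        raise ValueError(f"{name} must be >= 0, got {out}")
    return out


@dataclass(frozen=True)
class DichotomousTable:
    """Reported 2x2 counts of a dichotomous-outcome comparison.

    a/b are experimental endpoint-positive/negative, c/d the control-arm
    counterparts.  All four margins must be positive for the chi-square
    statistic and the risk ratio to be defined.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _as_count(getattr(self, name), name))
        if self.n <= 0:
            raise ValueError("table total must be positive")
        for label, margin in self.margins.items():
            if margin <= 0:
                raise MarginError(f"margin {label} is zero; statistic undefined")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> dict:
        return {
            "a+b": self.a + self.b,
            "c+d": self.c + self.d,
            "a+c": self.a + self.c,
            "b+d": self.b + self.d,
        }

    def swapped_arms(self) -> "DichotomousTable":
        """The same data with experimental and control arms exchanged."""
        return DichotomousTable(self.c, self.d, self.a, self.b)

    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignificanceThreshold:
    """Significance level alpha and the matching chi-square(1 df) critical value."""

    alpha: float
    nu_c: float

    @classmethod
    def from_alpha(cls, alpha: float) -> "SignificanceThreshold":
        return cls(alpha=alpha, nu_c=critical_value(alpha))


@dataclass(frozen=True)
class EffectEstimate:
    """Relative risk of the experimental arm versus control with a Wald CI."""

    rr: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def chi_square_statistic(table: DichotomousTable) -> float:
    """Pearson chi-square statistic (1 df, no continuity correction).

    Computed as n*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the numerator is
    formed in exact integer arithmetic before the single division.
    """
    a, b, c, d = table.cells()
    num = table.n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def chi_square_p_value(table: DichotomousTable) -> float:
    """Upper-tail p of the 1-df chi-square statistic (not Fisher's exact test)."""
    return float(stats.chi2.sf(chi_square_statistic(table), df=1))


def critical_value(alpha: float) -> float:
    """(1 - alpha) quantile of the chi-square distribution with 1 df."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.chi2.ppf(1.0 - alpha, df=1))


def relative_risk(table: DichotomousTable, level: float = 0.95) -> EffectEstimate:
    """Risk ratio a(c+d)/(c(a+b)) with a Katz log-RR Wald confidence interval."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    a, b, c, d = table.cells()
    if a == 0 or c == 0:
        raise DegenerateEffectError("zero event count; log-RR interval undefined")
    rr = (a * (c + d)) / (c * (a + b))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    log_rr = math.log(rr)
    return EffectEstimate(
        rr=rr,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        level=level,
    )


def classify_direction(table: DichotomousTable) -> Direction:
    """Which redaction scheme applies: RR_GT_1 if RR > 1, RR_LT_1 if RR < 1."""
    a, b, c, d = table.cells()
    # RR > 1  <=>  a(c+d) > c(a+b)  <=>  ad > bc (exact integer comparison)
    lhs, rhs = a * d, b * c
    if lhs > rhs:
        return Direction.RR_GT_1
    if lhs < rhs:
        return Direction.RR_LT_1
    raise NoEffectError("relative risk is exactly 1; redaction direction undefined")


# --------------------------------------------------------------------------
# Section 2 — the ROAR surface g(x, y), its expansion, gradient, and h(x, y)
# --------------------------------------------------------------------------


class RedactionPair(NamedTuple):
    """Hypothetical redacted counts (x: experimental arm, y: control arm)."""

    x: float
    y: float

    @property
    def distance(self) -> float:
        return math.hypot(self.x, self.y)


def _pmul(A, B):
    """Multiply two bivariate polynomials given as coefficient grids C[i,j] x^i y^j."""
    A = np.asarray(A)
    B = np.asarray(B)
    out = np.zeros(
        (A.shape[0] + B.shape[0] - 1, A.shape[1] + B.shape[1] - 1), dtype=object
    )
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if A[i, j] != 0:
                out[i : i + B.shape[0], j : j + B.shape[1]] += A[i, j] * B
    return out


def _pad_to(C, shape):
    out = np.zeros(shape, dtype=object)
    out[: C.shape[0], : C.shape[1]] = C
    return out


def _pdiff(C: np.ndarray, axis: int) -> np.ndarray:
    """Partial derivative of a float coefficient grid along x (axis 0) or y (axis 1)."""
    if C.shape[axis] == 1:
        return np.zeros((1, 1))
    powers = np.arange(1, C.shape[axis])
    if axis == 0:
        return C[1:, :] * powers[:, None]
    return C[:, 1:] * powers[None, :]


def _shift(C: np.ndarray, axis: int) -> np.ndarray:
    """Multiply a coefficient grid by x (axis 0) or y (axis 1)."""
    pad = [(1, 0), (0, 0)] if axis == 0 else [(0, 0), (1, 0)]
    return np.pad(C, pad)


class RoarSurface:
    """The ROAR-defining function g(x, y) for one table, direction, and threshold.

    g is the chi-square statistic of the restored table minus ``nu_c``;
    g(x, y) <= 0 exactly when the restored table is no longer significant.
    Internally the denominator-cleared polynomial form of g (degree <= 3 in
    each variable, at most 15 monomials) is expanded once with exact integer
    coefficients; the gradient and the Lagrange elimination function
    h = y*dg/dx - x*dg/dy are derived from it analytically.  On the domain
    x, y >= 0 the rational denominator is strictly positive, so the rational
    and polynomial forms agree in sign everywhere.
    """

    def __init__(self, table: DichotomousTable, direction: Direction, nu_c: float):
        if nu_c < 0:
            raise ValueError("nu_c must be non-negative")
        self.table = table
        self.direction = direction
        self.nu_c = float(nu_c)
        num_int, den_int = self._build_cleared_polys()
        self.poly = num_int.astype(float) - self.nu_c * den_int.astype(float)
        self.poly_gx = _pdiff(self.poly, axis=0)
        self.poly_gy = _pdiff(self.poly, axis=1)
        # h = y * dg/dx - x * dg/dy  (lambda from the Lagrange system eliminated)
        self.poly_h = _pad_to(
            _shift(self.poly_gx, axis=1), self._hshape()
        ).astype(float) - _pad_to(_shift(self.poly_gy, axis=0), self._hshape()).astype(
            float
        )
        self.poly_hx = _pdiff(self.poly_h, axis=0)
        self.poly_hy = _pdiff(self.poly_h, axis=1)
        self._abs_poly = np.abs(self.poly)
        self._abs_h = np.abs(self.poly_h)

    def _hshape(self):
        gx = _shift(self.poly_gx, axis=1)
        gy = _shift(self.poly_gy, axis=0)
        return (max(gx.shape[0], gy.shape[0]), max(gx.shape[1], gy.shape[1]))

    def _build_cleared_polys(self):
        a, b, c, d = self.table.cells()
        n = self.table.n
        one_x = np.array([[0], [1]], dtype=object)  # x
        one_y = np.array([[0, 1]], dtype=object)  # y
        lin = np.array([[n, 1], [1, 0]], dtype=object)  # n + x + y
        if self.direction is Direction.RR_GT_1:
            # restored table: a, b+x / c+y, d
            cross = np.array([[a * d - b * c, -b], [-c, -1]], dtype=object)
            rows = _pmul(
                np.array([[a + b], [1]], dtype=object),
                np.array([[c + d, 1]], dtype=object),
            )
            cols = _pmul(
                np.array([[a + c, 1]], dtype=object),
                np.array([[b + d], [1]], dtype=object),
            )
        else:
            # restored table: a+x, b / c, d+y
            cross = np.array([[a * d - b * c, a], [d, 1]], dtype=object)
            rows = _pmul(
                np.array([[a + b], [1]], dtype=object),
                np.array([[c + d, 1]], dtype=object),
            )
            cols = _pmul(
                np.array([[a + c], [1]], dtype=object),
                np.array([[b + d, 1]], dtype=object),
            )
        num = _pmul(lin, _pmul(cross, cross))
        den = _pmul(rows, cols)
        shape = (max(num.shape[0], den.shape[0]), max(num.shape[1], den.shape[1]))
        return _pad_to(num, shape), _pad_to(den, shape)

    # -- restored-table arithmetic (rational form) --------------------------

    def _restored_cells(self, x, y):
        a, b, c, d = self.table.cells()
        if self.direction is Direction.RR_GT_1:
            return a, b + x, c + y, d
        return a + x, b, c, d + y

    def g_value(self, x: float, y: float) -> float:
        """Rational-form g: chi-square of the restored table minus nu_c."""
        ra, rb, rc, rd = self._restored_cells(np.asarray(x, float), np.asarray(y, float))
        num = (ra + rb + rc + rd) * (ra * rd - rb * rc) ** 2
        den = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
        out = num / den - self.nu_c
        return float(out) if np.isscalar(x) or np.ndim(out) == 0 else out

    def contains(self, x: float, y: float):
        """True iff restoring (x, y) renders the table non-significant (g <= 0)."""
        ra, rb, rc, rd = self._restored_cells(np.asarray(x, float), np.asarray(y, float))
        num = (ra + rb + rc + rd) * (ra * rd - rb * rc) ** 2
        den = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
        out = num <= self.nu_c * den
        return bool(out) if np.ndim(out) == 0 else out

    # -- polynomial form ------------------------------------------------------

    def expand_polynomial(self) -> dict:
        """Monomial coefficients {(i, j): coeff} of the denominator-cleared g."""
        return {
            (i, j): float(self.poly[i, j])
            for i in range(self.poly.shape[0])
            for j in range(self.poly.shape[1])
            if self.poly[i, j] != 0.0
        }

    def g_poly_value(self, x, y):
        """Denominator-cleared polynomial form of g (same sign as ``g_value``)."""
        return npoly.polyval2d(x, y, self.poly)

    def grad_g(self, x, y):
        """(dg/dx, dg/dy) of the polynomial form, by analytic differentiation."""
        return (
            npoly.polyval2d(x, y, self.poly_gx),
            npoly.polyval2d(x, y, self.poly_gy),
        )

    def h_value(self, x, y):
        """Lagrange elimination function h = y*dg/dx - x*dg/dy."""
        return npoly.polyval2d(x, y, self.poly_h)

    def _g_scale(self, x, y):
        """Local magnitude of the cleared polynomial, for relative residuals."""
        return npoly.polyval2d(x, y, self._abs_poly)

    def _h_scale(self, x, y):
        return npoly.polyval2d(x, y, self._abs_h)

    # -- boundary slicing ------------------------------------------------------

    def _y_coeffs_at(self, x):
        """Coefficients (ascending in y) of g(x, .) for scalar or vector x."""
        return np.stack(
            [npoly.polyval(x, self.poly[:, j]) for j in range(self.poly.shape[1])],
            axis=-1,
        )

    def boundary_slice(self, x_fixed: float) -> list:
        """All non-negative real roots y of the cubic g(x_fixed, y) = 0, ascending.

        Roots are extracted from the companion matrix, polished with a Newton
        step on the polynomial, filtered to real non-negative values, and
        verified against a relative residual bound.  Returns an empty list
        when the vertical line misses the region.
        """
        if x_fixed < 0:
            raise ValueError("x_fixed must be >= 0")
        coeffs = np.asarray(self._y_coeffs_at(float(x_fixed)), dtype=float)
        scale = np.max(np.abs(coeffs))
        if scale == 0.0:
            return []
        # trim negligible leading (highest-order) coefficients before np.roots
        keep = len(coeffs)
        while keep > 1 and abs(coeffs[keep - 1]) <= 1e-13 * scale:
            keep -= 1
        if keep == 1:
            return []
        roots = np.roots(coeffs[:keep][::-1])
        out = []
        for r in roots:
            if abs(r.imag) > ROOT_IMAG_RTOL * (1.0 + abs(r.real)):
                continue
            y = float(r.real)
            for _ in range(2):  # Newton polish on the bivariate polynomial
                fy = npoly.polyval2d(x_fixed, y, self.poly_gy)
                if fy == 0.0:
                    break
                y -= npoly.polyval2d(x_fixed, y, self.poly) / fy
            if y < -AXIS_CLAMP * (1.0 + abs(y)):
                continue
            y = max(y, 0.0)
            res = abs(npoly.polyval2d(x_fixed, y, self.poly))
            if res > ROOT_RESIDUAL_RTOL * max(self._g_scale(x_fixed, y), scale):
                continue
            out.append(y)
        out.sort()
        deduped: list = []
        for y in out:
            if not deduped or y - deduped[-1] > 1e-7 * (1.0 + y):
                deduped.append(y)
        return deduped

    def _boundary_roots_batch(self, xs: np.ndarray) -> np.ndarray:
        """Vectorized boundary_slice: (m, 3) array of y roots, NaN where absent.

        Solves the cubic in y at every x via stacked companion-matrix
        eigenvalues, with a per-slice fallback where the cubic degenerates.
        """
        xs = np.asarray(xs, dtype=float)
        C = self._y_coeffs_at(xs)  # (m, 4)
        m = xs.shape[0]
        roots = np.full((m, 3), np.nan)
        scale = np.max(np.abs(C), axis=1)
        lead = C[:, 3]
        ok = np.abs(lead) > 1e-12 * np.maximum(scale, 1.0)
        if np.any(ok):
            mon = C[ok] / lead[ok, None]
            comp = np.zeros((mon.shape[0], 3, 3))
            comp[:, 1, 0] = 1.0
            comp[:, 2, 1] = 1.0
            comp[:, 0, 2] = -mon[:, 0]
            comp[:, 1, 2] = -mon[:, 1]
            comp[:, 2, 2] = -mon[:, 2]
            ev = np.linalg.eigvals(comp)
            real = np.abs(ev.imag) <= ROOT_IMAG_RTOL * (1.0 + np.abs(ev.real))
            cand = np.where(real, ev.real, np.nan)
            roots[ok] = cand
        for idx in np.nonzero(~ok)[0]:  # degenerate cubics: per-slice fallback
            ys = self.boundary_slice(xs[idx])
            roots[idx, : len(ys)] = ys[:3]
        # one vectorized Newton polish, then domain/residual filtering
        X = np.broadcast_to(xs[:, None], roots.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            for _ in range(2):
                fy = npoly.polyval2d(X, roots, self.poly_gy)
                step = npoly.polyval2d(X, roots, self.poly) / fy
                roots = np.where(np.isfinite(step), roots - step, roots)
            bad = roots < -AXIS_CLAMP * (1.0 + np.abs(roots))
            roots = np.where(bad, np.nan, np.maximum(roots, 0.0))
            res = np.abs(npoly.polyval2d(X, roots, self.poly))
            tol = ROOT_RESIDUAL_RTOL * np.maximum(self._g_scale(X, roots), 1.0)
            roots = np.where(res <= tol, roots, np.nan)
        return roots


# --------------------------------------------------------------------------
# Section 3 — FOCK solver, axis intercepts, and redaction metrics
# --------------------------------------------------------------------------


@dataclass
class FockResult:
    """Full result of a ROAR analysis of one table.

    ``fock`` is the minimal-Euclidean-redaction point (x_e, y_e) on the
    boundary g = 0; ``rmin`` the combined redaction count (nearest integer to
    x_e + y_e); ``xc``/``yc`` the single-arm axis intercepts; ``rho_e``,
    ``rho_c``, ``rho_a`` the redaction tolerances as fractions.  For a table
    that is not significant at alpha, ``significant`` is False and every
    redaction field is zero.
    """

    table: DichotomousTable
    alpha: float
    nu_c: float
    direction: Direction | None
    chi_square: float
    significant: bool
    fock: RedactionPair
    distance: float
    raw_sum: float
    rmin: int
    xc: float
    yc: float
    rho_e: float
    rho_c: float
    rho_a: float
    diagnostics: dict = field(default_factory=dict)


def _smallest_positive_root(coeffs: np.ndarray, surface: RoarSurface, axis: str) -> float:
    """Smallest positive real root of a univariate cubic given ascending coeffs."""
    scale = np.max(np.abs(coeffs))
    keep = len(coeffs)
    while keep > 1 and abs(coeffs[keep - 1]) <= 1e-13 * scale:
        keep -= 1
    if keep > 1:
        roots = np.roots(np.asarray(coeffs[:keep][::-1], dtype=float))
    else:
        roots = np.array([])
    best = None
    poly1d = np.asarray(coeffs, dtype=float)
    dpoly = npoly.polyder(poly1d)
    for r in roots:
        if abs(r.imag) > ROOT_IMAG_RTOL * (1.0 + abs(r.real)):
            continue
        t = float(r.real)
        for _ in range(2):
            dv = npoly.polyval(t, dpoly)
            if dv == 0.0:
                break
            t -= npoly.polyval(t, poly1d) / dv
        if t > AXIS_CLAMP and (best is None or t < best):
            best = t
    if best is None:
        raise SolverError(
            f"no positive real root on the {axis}-axis; the region should be "
            "bounded for a significant table — input may be invalid"
        )
    return best


def axis_intercept_x(surface: RoarSurface) -> float:
    """Minimal experimental-arm-only redaction x_c, i.e. smallest root of g(x, 0) = 0."""
    if surface.g_value(0.0, 0.0) <= 0:
        raise ValueError("table is not significant at nu_c; no intercept to find")
    return _smallest_positive_root(surface.poly[:, 0], surface, "x")


def axis_intercept_y(surface: RoarSurface) -> float:
    """Minimal control-arm-only redaction y_c, i.e. smallest root of g(0, y) = 0."""
    if surface.g_value(0.0, 0.0) <= 0:
        raise ValueError("table is not significant at nu_c; no intercept to find")
    return _smallest_positive_root(surface.poly[0, :], surface, "y")


def _newton_gh(surface: RoarSurface, x0: float, y0: float):
    """Newton iteration on the square system {g_poly = 0, h = 0}."""
    x, y = float(x0), float(y0)
    step_cap = 1.0 + 0.25 * math.hypot(x0, y0)
    for it in range(MAX_NEWTON_ITER):
        g = npoly.polyval2d(x, y, surface.poly)
        h = npoly.polyval2d(x, y, surface.poly_h)
        gtol = RESIDUAL_RTOL * max(surface._g_scale(x, y), 1.0)
        htol = RESIDUAL_RTOL * max(surface._h_scale(x, y), 1.0)
        if abs(g) <= gtol and abs(h) <= htol:
            return x, y, it, True
        J = np.array(
            [
                [npoly.polyval2d(x, y, surface.poly_gx), npoly.polyval2d(x, y, surface.poly_gy)],
                [npoly.polyval2d(x, y, surface.poly_hx), npoly.polyval2d(x, y, surface.poly_hy)],
            ]
        )
        try:
            dx, dy = np.linalg.solve(J, [g, h])
        except np.linalg.LinAlgError:
            return x, y, it, False
        norm = math.hypot(dx, dy)
        if norm > step_cap:  # damp wild steps away from the seed
            dx *= step_cap / norm
            dy *= step_cap / norm
        x -= dx
        y -= dy
    return x, y, MAX_NEWTON_ITER, False


def fock_point(
    surface: RoarSurface, scan_slices: int = FOCK_SCAN_SLICES
) -> tuple[RedactionPair, dict]:
    """Minimal-Euclidean-distance point on {g = 0, x >= 0, y >= 0}.

    Strategy (global scan + Newton polish): slice the boundary at
    ``scan_slices`` x positions in [0, min(xc, yc)] — no boundary point with a
    larger x coordinate can beat the nearer axis intercept — take the
    minimum-distance sample, then polish it by Newton iteration on the
    simultaneous system {g = 0, h = 0}.  Axis intercepts compete as
    candidates (an axis minimum needs only g = 0, not h = 0).  Among feasible
    candidates the minimum-norm one wins.  Returns the point and a
    diagnostics record; if polishing fails the scan minimum is returned with
    a diagnostic flag rather than raising.
    """
    xc = axis_intercept_x(surface)
    yc = axis_intercept_y(surface)
    bound = min(xc, yc)
    xs = np.linspace(0.0, bound, scan_slices + 1)
    roots = surface._boundary_roots_batch(xs)
    X = np.broadcast_to(xs[:, None], roots.shape)
    with np.errstate(invalid="ignore"):
        dist = np.hypot(X, roots)
    dist = np.where(np.isnan(dist), np.inf, dist)
    flat = int(np.argmin(dist))
    scan_best = RedactionPair(float(X.flat[flat]), float(roots.flat[flat]))
    n_candidates = int(np.sum(np.isfinite(roots))) + 2

    candidates: list[tuple[RedactionPair, dict]] = [
        (RedactionPair(xc, 0.0), {"kind": "axis-x", "iterations": 0, "converged": True}),
        (RedactionPair(0.0, yc), {"kind": "axis-y", "iterations": 0, "converged": True}),
    ]
    converged_any = False
    if math.isfinite(scan_best.distance):
        px, py, iters, ok = _newton_gh(surface, scan_best.x, scan_best.y)
        if ok and px >= -AXIS_CLAMP and py >= -AXIS_CLAMP:
            pt = RedactionPair(max(px, 0.0), max(py, 0.0))
            res_g = abs(npoly.polyval2d(pt.x, pt.y, surface.poly))
            if res_g <= ROOT_RESIDUAL_RTOL * max(surface._g_scale(pt.x, pt.y), 1.0):
                candidates.append(
                    (pt, {"kind": "newton", "iterations": iters, "converged": True})
                )
                converged_any = True
        if not converged_any:
            candidates.append(
                (
                    scan_best,
                    {"kind": "scan-fallback", "iterations": 0, "converged": False},
                )
            )

    best_pt, best_info = min(candidates, key=lambda item: item[0].distance)
    diagnostics = {
        "residual_g": abs(surface.g_value(best_pt.x, best_pt.y)),
        "residual_g_poly": abs(float(npoly.polyval2d(best_pt.x, best_pt.y, surface.poly))),
        "residual_h": abs(float(surface.h_value(best_pt.x, best_pt.y))),
        "newton_iterations": best_info["iterations"],
        "candidates_examined": n_candidates,
        "selected": best_info["kind"],
        "converged": best_info["converged"],
        "scan_slices": scan_slices,
    }
    return best_pt, diagnostics


def r_min(fock: RedactionPair) -> int:
    """Combined minimal redaction count: x_e + y_e rounded to the nearest integer."""
    return int(math.floor(fock.x + fock.y + 0.5))


def redaction_metrics(
    table: DichotomousTable, xc: float, yc: float, rmin: int
) -> tuple[float, float, float]:
    """Redaction tolerances (rho_E, rho_C, rho_A) as fractions in [0, 1).

    rho_E = 1 - (a+b)/(a+b+xc) and rho_C = 1 - (c+d)/(c+d+yc) use the real
    axis intercepts; rho_A = 1 - n/(n+rmin) uses the integer count.
    """
    if xc < 0 or yc < 0 or rmin < 0:
        raise ValueError("xc, yc, rmin must be non-negative")
    e_arm = table.a + table.b
    c_arm = table.c + table.d
    rho_e = 1.0 - e_arm / (e_arm + xc)
    rho_c = 1.0 - c_arm / (c_arm + yc)
    rho_a = 1.0 - table.n / (table.n + rmin)
    return rho_e, rho_c, rho_a


def analyze(
    table: DichotomousTable,
    alpha: float = DEFAULT_ALPHA,
    direction: Direction | None = None,
    scan_slices: int = FOCK_SCAN_SLICES,
) -> FockResult:
    """Full ROAR analysis of one table: direction, FOCK point, and tolerances.

    A table that is not significant at ``alpha`` yields a flagged result with
    all redaction fields zero rather than an exception, so batch and
    meta-analysis callers can proceed.
    """
    threshold = SignificanceThreshold.from_alpha(alpha)
    chi2 = chi_square_statistic(table)
    if chi2 <= threshold.nu_c:
        return FockResult(
            table=table,
            alpha=alpha,
            nu_c=threshold.nu_c,
            direction=None,
            chi_square=chi2,
            significant=False,
            fock=RedactionPair(0.0, 0.0),
            distance=0.0,
            raw_sum=0.0,
            rmin=0,
            xc=0.0,
            yc=0.0,
            rho_e=0.0,
            rho_c=0.0,
            rho_a=0.0,
            diagnostics={"warning": "input not significant at alpha; ROAR undefined"},
        )
    if direction is None:
        direction = classify_direction(table)
    surface = RoarSurface(table, direction, threshold.nu_c)
    xc = axis_intercept_x(surface)
    yc = axis_intercept_y(surface)
    fock, diagnostics = fock_point(surface, scan_slices=scan_slices)
    rmin = r_min(fock)
    rho_e, rho_c, rho_a = redaction_metrics(table, xc, yc, rmin)
    return FockResult(
        table=table,
        alpha=alpha,
        nu_c=threshold.nu_c,
        direction=direction,
        chi_square=chi2,
        significant=True,
        fock=fock,
        distance=fock.distance,
        raw_sum=fock.x + fock.y,
        rmin=rmin,
        xc=xc,
        yc=yc,
        rho_e=rho_e,
        rho_c=rho_c,
        rho_a=rho_a,
        diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# Section 4 — meta-analysis pooling and the CMH confounding gate
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyTable:
    """One study's 2x2 table with a non-empty identifying label."""

    study_id: str
    table: DichotomousTable

    def __post_init__(self):
        if not str(self.study_id).strip():
            raise ValueError("study_id must be non-empty")


@dataclass
class PooledAnalysis:
    """Crude vs CMH pooled risk ratios and the resulting ROAR applicability gate."""

    studies: list
    pooled: DichotomousTable
    rr_crude: float
    rr_cmh: float
    confounding: float
    threshold: float
    roar_applicable: bool
    warnings: list = field(default_factory=list)


def _check_studies(studies: Sequence[StudyTable]):
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValueError("study_id values must be unique")


def pooled_table(studies: Sequence[StudyTable]) -> DichotomousTable:
    """Exact cellwise integer sum of the per-study tables."""
    _check_studies(studies)
    return DichotomousTable(
        a=sum(s.table.a for s in studies),
        b=sum(s.table.b for s in studies),
        c=sum(s.table.c for s in studies),
        d=sum(s.table.d for s in studies),
    )


def pooled_crude_rr(studies: Sequence[StudyTable]) -> float:
    """Crude pooled risk ratio: sum(a_i) sum(c_i + d_i) / (sum(c_i) sum(a_i + b_i))."""
    _check_studies(studies)
    sa = sum(s.table.a for s in studies)
    sc = sum(s.table.c for s in studies)
    s_cd = sum(s.table.c + s.table.d for s in studies)
    s_ab = sum(s.table.a + s.table.b for s in studies)
    if sa == 0 or sc == 0:
        raise DegenerateEffectError("pooled event count is zero; crude RR undefined")
    return (sa * s_cd) / (sc * s_ab)


def cmh_rr(studies: Sequence[StudyTable]) -> float:
    """Cochran–Mantel–Haenszel risk ratio: stratum-weighted pooling that
    adjusts for between-study allocation differences."""
    _check_studies(studies)
    num = sum(s.table.a * (s.table.c + s.table.d) / s.table.n for s in studies)
    den = sum(s.table.c * (s.table.a + s.table.b) / s.table.n for s in studies)
    if den == 0 or num == 0:
        raise DegenerateEffectError("CMH sum is zero; adjusted RR undefined")
    return num / den


def assess_pooling(
    studies: Sequence[StudyTable],
    threshold: float = DEFAULT_CONFOUNDING_THRESHOLD,
) -> PooledAnalysis:
    """Pool studies and gate ROAR applicability on the confounding magnitude.

    The gate compares |1 - RR_CMH/RR_C| against ``threshold`` (strictly
    less-than); when it passes, confounding between studies is deemed minimal
    and ROAR may be run on the crude pooled table.
    """
    _check_studies(studies)
    warnings = []
    for s in studies:
        if 0 in s.table.cells():
            warnings.append(
                f"study {s.study_id!r} has a zero cell; CMH pooling uses it "
                "without continuity treatment"
            )
    pooled = pooled_table(studies)
    rr_crude = pooled_crude_rr(studies)
    rr_cmh = cmh_rr(studies)
    confounding = abs(1.0 - rr_cmh / rr_crude)
    return PooledAnalysis(
        studies=list(studies),
        pooled=pooled,
        rr_crude=rr_crude,
        rr_cmh=rr_cmh,
        confounding=confounding,
        threshold=threshold,
        roar_applicable=confounding < threshold,
        warnings=warnings,
    )


STUDY_CSV_COLUMNS = ["study", "a", "b", "c", "d"]


def read_studies_csv(path) -> list:
    """Read per-study tables from CSV with header exactly ``study,a,b,c,d``."""
    frame = pd.read_csv(path, dtype={"study": str})
    if list(frame.columns) != STUDY_CSV_COLUMNS:
        raise ValueError(
            f"CSV header must be exactly {','.join(STUDY_CSV_COLUMNS)}; "
            f"got {','.join(map(str, frame.columns))}"
        )
    studies = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            cells = {}
            for col in ("a", "b", "c", "d"):
                raw = getattr(row, col)
                if pd.isna(raw) or float(raw) != int(raw):
                    raise ValueError(f"column {col} must be a non-negative integer")
                cells[col] = int(raw)
            studies.append(StudyTable(study_id=str(row.study), table=DichotomousTable(**cells)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {row_number}: {exc}") from exc
    if not studies:
        raise ValueError("CSV contains no study rows")
    return studies


# --------------------------------------------------------------------------
# Section 5 — brute-force oracles and the fixture generator
# --------------------------------------------------------------------------


@dataclass
class OracleResult:
    """Brute-force minima used to validate the analytic solver.

    ``min_total_integer``/``argmin`` come from exhaustive integer search over
    x + y <= max_total; ``grid_min_distance``/``grid_argmin`` from a dense
    boundary scan.  Fields not computed by a given oracle are None.
    """

    min_total_integer: int | None = None
    argmin: RedactionPair | None = None
    grid_min_distance: float | None = None
    grid_argmin: RedactionPair | None = None


def integer_min_redaction(surface: RoarSurface, max_total: int) -> OracleResult:
    """Exhaustive integer search for the minimal total redaction x + y.

    Scans integer pairs in order of increasing total; within a total, ties
    break toward the smallest x.  Raises :class:`BoundExceededError` when no
    feasible pair exists with x + y <= max_total.
    """
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    if surface.g_value(0.0, 0.0) <= 0:
        return OracleResult(min_total_integer=0, argmin=RedactionPair(0.0, 0.0))
    for total in range(1, max_total + 1):
        xs = np.arange(total + 1, dtype=float)
        ys = total - xs
        inside = surface.contains(xs, ys)
        if np.any(inside):
            i = int(np.argmax(inside))  # first True = smallest x
            return OracleResult(
                min_total_integer=total,
                argmin=RedactionPair(float(xs[i]), float(ys[i])),
            )
    raise BoundExceededError(
        f"no integer redaction with total <= {max_total} nullifies the result"
    )


def grid_min_distance(surface: RoarSurface, slices: int = 10_000) -> OracleResult:
    """Dense-scan oracle for the minimal boundary distance.

    Slices the boundary at ``slices + 1`` evenly spaced x positions in
    [0, min(xc, yc)] — a boundary point with larger x is necessarily farther
    from the origin than the nearer axis intercept — and always includes the
    two axis intercepts as samples.  Doubling ``slices`` refines the grid by
    nesting, so the reported minimum never increases under refinement.
    """
    if slices < 100:
        raise ValueError("slices must be >= 100")
    xc = axis_intercept_x(surface)
    yc = axis_intercept_y(surface)
    bound = min(xc, yc)
    xs = np.linspace(0.0, bound, slices + 1)
    roots = surface._boundary_roots_batch(xs)
    X = np.broadcast_to(xs[:, None], roots.shape)
    with np.errstate(invalid="ignore"):
        dist = np.hypot(X, roots)
    dist = np.where(np.isnan(dist), np.inf, dist)
    flat = int(np.argmin(dist))
    best = RedactionPair(float(X.flat[flat]), float(roots.flat[flat]))
    for pt in (RedactionPair(xc, 0.0), RedactionPair(0.0, yc)):
        if pt.distance < best.distance:
            best = pt
    return OracleResult(grid_min_distance=best.distance, grid_argmin=best)


def random_significant_table(
    seed: int,
    n_range: tuple[int, int] = (40, 400),
    alpha: float = DEFAULT_ALPHA,
) -> DichotomousTable:
    """Seeded generator of random tables significant at ``alpha``.

    Draws the total n uniformly from ``n_range``, allocates cells by a
    symmetric multinomial, and rejection-samples until the table has positive
    margins and chi-square above the critical value.  Deterministic in
    ``seed``.
    """
    lo, hi = n_range
    if not (4 <= lo <= hi):
        raise ValueError("n_range must satisfy 4 <= lo <= hi")
    nu = critical_value(alpha)
    rng = np.random.default_rng(seed)
    for _ in range(MAX_GENERATOR_DRAWS):
        n = int(rng.integers(lo, hi + 1))
        a, b, c, d = (int(v) for v in rng.multinomial(n, [0.25] * 4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        table = DichotomousTable(a, b, c, d)
        if chi_square_statistic(table) > nu and table.a * table.d != table.b * table.c:
            return table
    raise GeneratorError(
        f"no significant table found in {MAX_GENERATOR_DRAWS} draws; "
        "n_range may be too restrictive"
    )


# --------------------------------------------------------------------------
# Section 6 — report building and boundary export (consumed by the CLI)
# --------------------------------------------------------------------------


def _display_pct(fraction: float) -> str:
    return f"{100.0 * fraction:.2f}%"


def build_report(
    table: DichotomousTable,
    alpha: float = DEFAULT_ALPHA,
    direction: Direction | None = None,
    seed: int | None = None,
) -> dict:
    """Run a full analysis and assemble the JSON-serializable report.

    All reals appear at full double precision under ``effect``/``roar``;
    the ``display`` block carries two-decimal twins (coordinates and
    percentages) plus floor-based whole-subject counts for the intercepts.
    """
    result = analyze(table, alpha=alpha, direction=direction)
    warnings: list[str] = []
    if "warning" in result.diagnostics:
        warnings.append(result.diagnostics["warning"])
    effect: dict = {
        "chi_square": result.chi_square,
        "p_value": chi_square_p_value(table),
        "rr": None,
        "ci_low": None,
        "ci_high": None,
        "ci_level": 0.95,
    }
    try:
        est = relative_risk(table)
        effect.update(rr=est.rr, ci_low=est.ci_low, ci_high=est.ci_high, ci_level=est.level)
    except DegenerateEffectError as exc:
        warnings.append(str(exc))
    report = {
        "schema": "roar-report/1",
        "input": {
            "a": table.a,
            "b": table.b,
            "c": table.c,
            "d": table.d,
            "n": table.n,
            "alpha": alpha,
            "nu_c": result.nu_c,
            "direction": result.direction.value if result.direction else None,
        },
        "effect": effect,
        "roar": {
            "significant": result.significant,
            "xe": result.fock.x,
            "ye": result.fock.y,
            "distance": result.distance,
            "raw_sum": result.raw_sum,
            "rmin": result.rmin,
            "xc": result.xc,
            "yc": result.yc,
            "rho_e": result.rho_e,
            "rho_c": result.rho_c,
            "rho_a": result.rho_a,
        },
        "display": {
            "fock": f"({result.fock.x:.2f}, {result.fock.y:.2f})",
            "rmin": f"{result.rmin} subjects",
            "rho_e": _display_pct(result.rho_e),
            "rho_c": _display_pct(result.rho_c),
            "rho_a": _display_pct(result.rho_a),
            "xc_subjects": int(math.floor(result.xc)),
            "yc_subjects": int(math.floor(result.yc)),
        },
        "provenance": {"tool": "roar", "version": __version__, "seed": seed},
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if k != "warning"
        },
        "warnings": warnings,
    }
    return report


def format_report(report: dict) -> str:
    """Human-readable summary of a report dict (the CLI's stdout payload)."""
    inp = report["input"]
    eff = report["effect"]
    roar = report["roar"]
    disp = report["display"]
    lines = [
        f"ROAR analysis (alpha={inp['alpha']}, nu_c={inp['nu_c']:.4f})",
        f"  table: a={inp['a']} b={inp['b']} c={inp['c']} d={inp['d']}  (n={inp['n']})",
        f"  chi-square = {eff['chi_square']:.4f}  (p = {eff['p_value']:.4g})",
    ]
    if eff["rr"] is not None:
        lines.append(
            f"  relative risk = {eff['rr']:.2f} "
            f"({eff['ci_level']:.0%} CI {eff['ci_low']:.2f}-{eff['ci_high']:.2f})"
        )
    if not roar["significant"]:
        lines.append("  not significant at alpha: no attainable redaction to report")
        return "\n".join(lines)
    lines += [
        f"  direction: {inp['direction']}",
        f"  FOCK point (xe, ye) = {disp['fock']}   |FOCK| = {roar['distance']:.2f}",
        f"  rmin = {disp['rmin']}  (xe + ye = {roar['raw_sum']:.2f})",
        f"  axis intercepts: xc = {roar['xc']:.2f}  yc = {roar['yc']:.2f}",
        f"  redaction tolerances: rho_E = {disp['rho_e']}  "
        f"rho_C = {disp['rho_c']}  rho_A = {disp['rho_a']}",
    ]
    for w in report["warnings"]:
        lines.append(f"  warning: {w}")
    return "\n".join(lines)


def export_boundary(surface: RoarSurface, path, samples: int = 512) -> pd.DataFrame:
    """Write the ROAR boundary polyline to CSV (header ``x,y``).

    Samples the boundary at evenly spaced x positions spanning the region's
    x extent, emitting the near (smallest-root) branch with ascending x
    followed by the far (largest-root) branch with descending x, and always
    including the axis intercept points (xc, 0) and (0, yc).  Every exported
    point lies on g = 0 to the root-residual tolerance.  Returns the frame
    written.
    """
    if samples < 2:
        raise ValueError("samples must be >= 2")
    xc = axis_intercept_x(surface)
    yc = axis_intercept_y(surface)
    # x extent of the region: the largest positive real root of g(x, 0)
    coeffs = np.asarray(surface.poly[:, 0], dtype=float)
    roots = np.roots(coeffs[::-1])
    real = [
        float(r.real)
        for r in roots
        if abs(r.imag) <= ROOT_IMAG_RTOL * (1.0 + abs(r.real)) and r.real > 0
    ]
    x_extent = max(real)
    xs = np.linspace(0.0, x_extent, samples)
    lower, upper = [], []
    for x in xs:
        ys = surface.boundary_slice(float(x))
        if ys:
            lower.append((float(x), ys[0]))
            upper.append((float(x), ys[-1]))
    points = [(0.0, yc)] + lower + [(xc, 0.0), (x_extent, 0.0)] + upper[::-1]
    frame = pd.DataFrame(points, columns=["x", "y"])
    frame.to_csv(path, index=False)
    return frame


def write_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
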
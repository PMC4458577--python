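"""Derived quantities of the transport models.

Turning points of the advection-rate curve, the crossover concentration at
which passive and energy-dependent transport balance, the kinetics-of-
dissolution boundary points and three-phase solubility classification, and
dosing-interval acceleration summaries.

Roots are located by a dense-grid pre-scan for sign changes followed by
bracketed root polishing (Brent's method), so no root inside the scanned
domain is missed and every reported location is refined to ~1e−12.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import (
    ConvectionTimeParams,
    PrimaryRateParams,
    RateConstantParams,
    acceleration_rate_constant,
    acceleration_zero_crossing,
    advection_rate_constant,
    convection_rate_constant_time,
    primary_advection_rate,
    primary_advection_rate_derivative,
)

__all__ = [
    "TurningPoint",
    "PhaseBoundaries",
    "Phase",
    "SubRegion",
    "PhaseLabel",
    "DominanceCase",
    "find_turning_points",
    "dominance_crossover",
    "classify_dominance",
    "solve_boundaries",
    "classify_kinetic_phase",
    "classification_table",
    "acceleration_profile",
    "BoundaryError",
]

#: default search domain for turning points — the fitted concentration range
DEFAULT_TURNING_DOMAIN = (0.01, 15.5)
#: grid step of the sign-change pre-scan, μg/ml
SCAN_STEP = 0.005
#: relative tolerance on | |II| − |III| | defining the balanced dominance case
DOMINANCE_RTOL = 1e-3
#: absolute slack on the phase-defining inequalities near boundary points
PHASE_ATOL = 1e-8


class BoundaryError(RuntimeError):
    """The rate-constant model admits no dissolution-phase boundary."""


class DominanceCase(str, enum.Enum):
    """Which transport mode dominates at a concentration."""

    ENERGY_DEPENDENT = "case_i"
    BALANCED = "case_ii"
    PASSIVE = "case_iii"


class Phase(str, enum.Enum):
    GOOD = "R_I"
    POOR = "R_II"
    UNDEFINED = "R_III"


class SubRegion(str, enum.Enum):
    VERY = "very"
    FREELY = "freely"
    SOLUBLE = "soluble"
    SPARINGLY = "sparingly"
    SLIGHTLY = "slightly"
    VERY_SLIGHTLY = "very_slightly"
    UNDEFINED = "undefined"


_RI_SUBS = {SubRegion.VERY, SubRegion.FREELY, SubRegion.SOLUBLE}
_RII_SUBS = {SubRegion.SPARINGLY, SubRegion.SLIGHTLY, SubRegion.VERY_SLIGHTLY}


@dataclass(frozen=True)
class TurningPoint:
    """A stationary point of the advection-rate curve."""

    x: float  # μg/ml
    rate: float  # ml/(μg·h)
    kind: str  # "minimum" | "maximum"


@dataclass(frozen=True)
class PhaseLabel:
    phase: Phase
    sub_region: SubRegion

    def __post_init__(self) -> None:
        ok = (
            (self.phase is Phase.GOOD and self.sub_region in _RI_SUBS)
            or (self.phase is Phase.POOR and self.sub_region in _RII_SUBS)
            or (self.phase is Phase.UNDEFINED and self.sub_region is SubRegion.UNDEFINED)
        )
        if not ok:
            raise ValueError(f"sub-region {self.sub_region} invalid for phase {self.phase}")


@dataclass(frozen=True)
class PhaseBoundaries:
    """Kinetics-of-dissolution boundary points and neighbourhood radii.

    ``x0 = 0`` is the rest point (all movement entities zero); ``x_Ad`` is
    the root of the advection rate constant (good → poor dissolution);
    ``x_C`` is the effective convection-extinction point, the smallest
    ``x > x_Ad`` at which the convection rate constant falls to the
    tolerance ``eps_c``.  The ε radii bound the named solubility
    neighbourhoods of 0, x_Ad and x_C and must keep them pairwise disjoint.
    """

    x_ad: float
    x_c: float
    eps1: float
    eps2: float
    eps3: float
    eps4: float
    eps_c: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("x_ad", "x_c", "eps1", "eps2", "eps3", "eps4", "eps_c"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        if not self.x_ad < self.x_c:
            raise ValueError(f"x_Ad must be < x_C, got {self.x_ad} >= {self.x_c}")
        if not self.eps1 < self.x_ad - self.eps2:
            raise ValueError("neighbourhoods of 0 and x_Ad overlap: need eps1 + eps2 < x_Ad")
        if not self.x_ad + self.eps3 < self.x_c - self.eps4:
            raise ValueError(
                "neighbourhoods of x_Ad and x_C overlap: need eps3 + eps4 < x_C - x_Ad"
            )


# ---------------------------------------------------------------------------
# Turning points & transport-mode dominance (primary rate model)
# ---------------------------------------------------------------------------


def find_turning_points(
    params: PrimaryRateParams,
    domain: tuple[float, float] = DEFAULT_TURNING_DOMAIN,
    step: float = SCAN_STEP,
) -> list[TurningPoint]:
    """Locate stationary points of the advection rate within ``domain``.

    Scans the analytic derivative on a uniform grid for sign changes,
    polishes each bracketed root with Brent's method, and classifies the
    point by the direction of the sign change (− to + is a minimum).
    Returns points sorted by concentration; an empty list if the derivative
    does not change sign in the domain.
    """
    x_lo, x_hi = domain
    if not 0 < x_lo < x_hi:
        raise ValueError(f"domain must satisfy 0 < x_lo < x_hi, got {domain!r}")
    grid = np.arange(x_lo, x_hi + step / 2, step)
    grid[-1] = min(grid[-1], x_hi)
    deriv = primary_advection_rate_derivative(grid, params)
    points: list[TurningPoint] = []
    sign = np.sign(deriv)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(
            lambda x: primary_advection_rate_derivative(x, params),
            grid[i],
            grid[i + 1],
            xtol=1e-12,
        )
        kind = "minimum" if deriv[i] < 0 else "maximum"
        rate = primary_advection_rate(root, params).total
        points.append(TurningPoint(x=float(root), rate=float(rate), kind=kind))
    return sorted(points, key=lambda tp: tp.x)


def _dominance_gap(x: float, params: PrimaryRateParams) -> float:
    """|II|(x) − III(x): magnitude of energy-dependent minus passive rate."""
    return abs(params.n) * x / (params.b + x) - params.m * (params.p / x + 1.0)


def dominance_crossover(
    params: PrimaryRateParams, bracket: tuple[float, float] = (1e-6, 1e3)
) -> float:
    """Concentration x̄ (μg/ml) at which |II| = III.

    Below x̄ the passive (E_I) rate dominates the energy-dependent (E_D)
    rate; above it the ordering reverses.  Solved by bracketing on
    ``bracket``; raises if the gap does not change sign there (e.g. n = 0).
    """
    if params.n == 0 or params.m <= 0:
        raise ValueError("crossover requires n != 0 and m > 0")
    lo, hi = bracket
    f_lo, f_hi = _dominance_gap(lo, params), _dominance_gap(hi, params)
    if f_lo * f_hi > 0:
        raise ValueError(f"no dominance crossover in bracket {bracket!r}")
    return float(brentq(_dominance_gap, lo, hi, args=(params,), xtol=1e-12))


def classify_dominance(
    x: float, params: PrimaryRateParams, rtol: float = DOMINANCE_RTOL
) -> DominanceCase:
    """Which transport mode dominates at concentration ``x``.

    ``case_i`` when the energy-dependent magnitude exceeds the passive
    rate, ``case_iii`` when the passive rate dominates, and ``case_ii``
    when they agree to relative tolerance ``rtol``.
    """
    if x <= 0:
        raise ValueError("x must be > 0")
    comp = primary_advection_rate(x, params)
    ii, iii = abs(comp.energy_dependent), abs(comp.energy_independent)
    scale = max(ii, iii, 1e-300)
    if abs(ii - iii) <= rtol * scale:
        return DominanceCase.BALANCED
    return DominanceCase.ENERGY_DEPENDENT if ii > iii else DominanceCase.PASSIVE


# ---------------------------------------------------------------------------
# Kinetics-of-dissolution boundaries & phase classification
# ---------------------------------------------------------------------------


def solve_boundaries(
    params: RateConstantParams,
    eps_c: float = 0.01,
    eps_radii: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5),
    x_max: float = 1e3,
) -> PhaseBoundaries:
    """Locate the dissolution-phase boundary points x_Ad and x_C.

    ``x_Ad`` is the root of the advection rate constant beyond the curve's
    maximum (advection turns negative there); ``x_C`` is the smallest
    ``x > x_Ad`` at which the convection rate constant has decayed to
    ``eps_c`` (1/h) — a tolerance surrogate for the exact zero the Ricker
    term only attains asymptotically.

    Raises
    ------
    BoundaryError
        If the advection rate constant never changes sign on (0, x_max]
        (the system never leaves the good-dissolution phase), or if
        convection never decays below ``eps_c``.
    """
    if eps_c <= 0:
        raise ValueError("eps_c must be > 0")

    def a_r(x: float) -> float:
        return advection_rate_constant(x, params).a_r

    grid = np.linspace(1e-6, x_max, 200_001)
    vals = advection_rate_constant(grid, params).a_r
    i_pk = int(np.argmax(vals))
    sign = np.sign(vals[i_pk:])
    changes = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if changes.size == 0:
        raise BoundaryError(
            "advection rate constant never changes sign: "
            "system never leaves the good-dissolution phase under these parameters"
        )
    i = i_pk + int(changes[0])
    x_ad = float(brentq(a_r, grid[i], grid[i + 1], xtol=1e-12))

    def c_gap(x: float) -> float:
        return advection_rate_constant(x, params).c_r - eps_c

    x_peak_c = 1.0 / params.lam  # Ricker maximum of c_r
    lo = max(x_ad, x_peak_c)
    if c_gap(lo) <= 0:
        raise BoundaryError(
            "convection rate constant is already below eps_c at x_Ad; "
            "no poor-dissolution phase exists — lower eps_c"
        )
    hi = lo
    while c_gap(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise BoundaryError("convection rate constant never decays below eps_c")
    x_c = float(brentq(c_gap, lo, hi, xtol=1e-12))
    e1, e2, e3, e4 = eps_radii
    return PhaseBoundaries(
        x_ad=x_ad, x_c=x_c, eps1=e1, eps2=e2, eps3=e3, eps4=e4, eps_c=eps_c
    )


def classify_kinetic_phase(
    x: float, params: RateConstantParams, boundaries: PhaseBoundaries
) -> PhaseLabel:
    """Assign a concentration to a dissolution phase and solubility sub-region.

    The phase is determined both by interval membership relative to
    (x_Ad, x_C) and by the defining inequalities on (a_r, c_r, st_r):

    * R_I (good):  a_r > 0 and 0 < st_r < c_r on (0, x_Ad);
    * R_II (poor): a_r < 0 and 0 < c_r < st_r on (x_Ad, x_C);
    * R_III (undefined): x > x_C, convection effectively extinct.

    The two determinations must agree (a mismatch signals boundaries that
    do not belong to ``params``).  Sub-regions are the ε-neighbourhoods of
    the boundary points; boundary concentrations belong to the
    neighbourhood (soluble / very-slightly-soluble) regions.
    """
    if x <= 0:
        raise ValueError("x must be > 0")
    b = boundaries
    rc = advection_rate_constant(x, params)

    if x <= b.x_ad:
        interval_phase = Phase.GOOD
    elif x <= b.x_c:
        interval_phase = Phase.POOR
    else:
        interval_phase = Phase.UNDEFINED

    # a_r > 0 is equivalent to st_r < c_r by the exact decomposition; the
    # convection-extinction test only applies once advection has turned
    # negative (c_r also vanishes as x -> 0, inside the good phase).
    tol = PHASE_ATOL
    if rc.a_r > tol:
        ineq_phase = Phase.GOOD
    elif rc.a_r < -tol:
        if rc.c_r > b.eps_c + tol:
            ineq_phase = Phase.POOR
        elif rc.c_r < b.eps_c - tol:
            ineq_phase = Phase.UNDEFINED
        else:
            ineq_phase = interval_phase  # within tolerance of x_C
    else:
        ineq_phase = interval_phase  # within tolerance of x_Ad
    if ineq_phase is not interval_phase:
        raise BoundaryError(
            f"phase inequalities at x={x} disagree with interval membership "
            f"({ineq_phase.value} vs {interval_phase.value}): boundaries "
            "inconsistent with the rate-constant parameters"
        )

    if interval_phase is Phase.GOOD:
        if x < b.eps1:
            sub = SubRegion.VERY
        elif x < b.x_ad - b.eps2:
            sub = SubRegion.FREELY
        else:
            sub = SubRegion.SOLUBLE
    elif interval_phase is Phase.POOR:
        if x < b.x_ad + b.eps3:
            sub = SubRegion.SPARINGLY
        elif x < b.x_c - b.eps4:
            sub = SubRegion.SLIGHTLY
        else:
            sub = SubRegion.VERY_SLIGHTLY
    else:
        sub = SubRegion.UNDEFINED
    return PhaseLabel(phase=interval_phase, sub_region=sub)


def classification_table(
    params: RateConstantParams,
    boundaries: PhaseBoundaries,
    x_grid: np.ndarray,
) -> pd.DataFrame:
    """Tabulate rate constants and phase labels over a concentration grid.

    Beyond x_C the saturable rate constant is reported frozen at its x_C
    value (the system no longer dissolves; saturation holds at the optimum
    dissolution capacity).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    rc = advection_rate_constant(x_grid, params)
    st_cap = advection_rate_constant(boundaries.x_c, params).st_r
    rows = []
    for xi, ai, ci, si in zip(x_grid, rc.a_r, rc.c_r, rc.st_r):
        label = classify_kinetic_phase(float(xi), params, boundaries)
        s_out = st_cap if xi > boundaries.x_c else si
        rows.append(
            {
                "x": xi,
                "a_r": ai,
                "c_r": ci,
                "st_r": s_out,
                "phase": label.phase.value,
                "sub_region": label.sub_region.value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dosing-interval acceleration
# ---------------------------------------------------------------------------


def acceleration_profile(
    params: ConvectionTimeParams, times: np.ndarray
) -> pd.DataFrame:
    """Tabulate the convection rate constant and its acceleration over time.

    ``times`` must be sorted and lie within [0, 24] h.  The returned frame
    has columns ``t``, ``c_r``, ``acceleration`` and carries the analytic
    acceleration zero-crossing time in ``frame.attrs["zero_crossing"]``;
    the acceleration is positive strictly before that time and negative
    strictly after it.
    """
    ta = np.asarray(times, dtype=float)
    if np.any(ta < 0) or np.any(ta > 24):
        raise ValueError("times must lie within [0, 24] h")
    if np.any(np.diff(ta) < 0):
        raise ValueError("times must be sorted")
    frame = pd.DataFrame(
        {
            "t": ta,
            "c_r": convection_rate_constant_time(ta, params),
            "acceleration": acceleration_rate_constant(ta, params),
        }
    )
    frame.attrs["zero_crossing"] = acceleration_zero_crossing(params)
    return frame
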
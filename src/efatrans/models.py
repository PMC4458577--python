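"""Closed-form transport-rate models for an efavirenz "solution particle".

The solution particle is an idealised zero-sum movement entity of a drug
solution: at every concentration it carries equal pro-solvation and
anti-solvation movement components.  Three model families describe its
kinetics in a homogeneous uptake volume:

* the **primary advection rate** ``y(x)`` (ml/(μg·h)) as a function of
  plasma concentration ``x`` (μg/ml) — a Ricker convection term plus a
  Michaelis–Menten energy-dependent term plus an inverse-MM passive term;
* the **advection rate constant** ``a_r(x)`` (1/h) — a Ricker convection
  rate constant minus a Hill-form saturable transport rate constant;
* the **convection rate constant in time** ``c_r(t)`` (1/h) over a 24-h
  dosing interval — a Bateman (difference-of-exponentials) profile, with
  its time derivative, the acceleration rate constant (1/h²).

A macro-level mass balance ties the advection rate to dose ``D`` (mg),
uptake volume ``V`` (L), bioavailable amount ``A`` (mg) and the
elimination rate constant ``k_e`` (1/h); mg/L and μg/ml are used
interchangeably.

All evaluators accept scalars or NumPy arrays and require strictly
positive concentrations (the passive term diverges at ``x = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "PrimaryRateParams",
    "RateConstantParams",
    "ConvectionTimeParams",
    "MacroTransportParams",
    "RateComponents",
    "RateConstantComponents",
    "primary_advection_rate",
    "primary_advection_rate_derivative",
    "advection_rate_constant",
    "convection_rate_constant_time",
    "acceleration_rate_constant",
    "acceleration_zero_crossing",
    "macro_advection_rate",
    "uptake_concentration",
    "REFERENCE_PRIMARY",
    "REFERENCE_RATE_CONSTANT",
    "REFERENCE_CONVECTION_TIME",
]

#: Gap below which difference-of-exponential profiles switch to their
#: analytic confluent limit, avoiding catastrophic cancellation.
EXPONENT_GAP_TOL = 1e-8


def _positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _as_positive_array(x: ArrayLike, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive (passive term diverges at 0)")
    return arr


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimaryRateParams:
    """Parameters of the primary advection-rate model.

    ``y(x) = g·x·e^(−h·x) + n·x/(b+x) + m·(p/x + 1)``

    Attributes
    ----------
    g : residence rate of the convection rate, (ml/μg)²·h⁻¹.
    h : decline rate of convection with concentration, ml/μg.
    n : maximum energy-dependent (E_D) transport rate, ml/(μg·h); may be
        negative (E_D opposes the pro-solvation movements).
    b : concentration at which the E_D rate is half of ``n``, μg/ml.
    m : minimum energy-independent (E_I, passive) transport rate, ml/(μg·h).
    p : concentration at which the E_I rate is twice ``m``, μg/ml.
    """

    g: float
    h: float
    n: float
    b: float
    m: float
    p: float

    def __post_init__(self) -> None:
        _positive(self.g, "g")
        _positive(self.h, "h")
        _positive(self.b, "b")
        _positive(self.m, "m")
        _positive(self.p, "p")
        if not math.isfinite(self.n):
            raise ValueError("n must be finite")


@dataclass(frozen=True)
class RateConstantParams:
    """Parameters of the advection rate-constant model.

    ``a_r(x) = ζ·x·e^(−λ·x) + α·x^ω/(κ + x^ω)`` with ``κ = η^ω``;
    the convection rate constant is ``c_r = ζ·x·e^(−λ·x)`` and the
    saturable transport rate constant ``st_r = −α·x^ω/(κ + x^ω)``
    (positive when ``α < 0``), so that ``a_r = c_r − st_r``.

    Attributes
    ----------
    zeta : residence rate of the convection rate constant, ml/(μg·h).
    lam : decline rate of convection with concentration, ml/μg.
    alpha : maximum saturable transport rate constant, 1/h; may be negative.
    omega : Hill coefficient, dimensionless.
    kappa : η^ω, (μg/ml)^ω — the half-saturation concentration raised to ω.
    """

    zeta: float
    lam: float
    alpha: float
    omega: float
    kappa: float

    def __post_init__(self) -> None:
        _positive(self.zeta, "zeta")
        _positive(self.lam, "lam")
        _positive(self.omega, "omega")
        _positive(self.kappa, "kappa")
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    @property
    def eta(self) -> float:
        """Half-saturation concentration η = κ^(1/ω), μg/ml."""
        return self.kappa ** (1.0 / self.omega)


@dataclass(frozen=True)
class ConvectionTimeParams:
    """Parameters of the Bateman-shaped convection rate-constant profile.

    ``c_r(t) = j/(w−l)·(e^(−l·t) − e^(−w·t))``

    Attributes
    ----------
    j : amplitude rate constant, 1/h.
    w : fast exponent, 1/h.
    l : slow exponent, 1/h; canonical ordering is ``w > l``.
    """

    j: float
    w: float
    l: float

    def __post_init__(self) -> None:
        _positive(self.j, "j")
        _positive(self.w, "w")
        _positive(self.l, "l")
        if not self.w > self.l:
            raise ValueError(
                f"canonical ordering requires w > l, got w={self.w!r}, l={self.l!r}"
            )


@dataclass(frozen=True)
class MacroTransportParams:
    """Macro mass-balance parameters at the point of full absorption.

    ``k_e = −1/γ · (D/V − A/V)`` ties the elimination rate constant to the
    advection rate ``−1/γ`` of the solution particle; ``D/V`` and ``A/V``
    are read in mg/L ≡ μg/ml.

    Attributes
    ----------
    D : dose, mg.
    V : uptake (transport) volume, L.
    A : absolute bioavailable amount, mg; 0 < A < D.
    k_e : elimination rate constant, 1/h.
    """

    D: float
    V: float
    A: float
    k_e: float

    def __post_init__(self) -> None:
        _positive(self.D, "D")
        _positive(self.V, "V")
        _positive(self.A, "A")
        if not self.A < self.D:
            raise ValueError(f"A must be < D (mass balance), got A={self.A!r}, D={self.D!r}")
        if not self.k_e >= 0:
            raise ValueError(f"k_e must be >= 0, got {self.k_e!r}")


@dataclass(frozen=True)
class RateComponents:
    """Decomposition of the primary advection rate, all in ml/(μg·h)."""

    convection: float | np.ndarray
    energy_dependent: float | np.ndarray
    energy_independent: float | np.ndarray

    @property
    def total(self) -> float | np.ndarray:
        return self.convection + self.energy_dependent + self.energy_independent


@dataclass(frozen=True)
class RateConstantComponents:
    """Decomposition of the advection rate constant, all in 1/h.

    ``a_r = c_r − st_r`` holds exactly by construction.
    """

    a_r: float | np.ndarray
    c_r: float | np.ndarray
    st_r: float | np.ndarray


# Published estimates for efavirenz at 600 mg (uptake volume 35.56 L),
# used as defaults by the simulator and the command-line pipeline.
REFERENCE_PRIMARY = PrimaryRateParams(
    g=0.0089, h=0.0598, n=-0.0561, b=7.4315, m=0.0034, p=0.8808
)
REFERENCE_RATE_CONSTANT = RateConstantParams(
    zeta=0.1440, lam=0.0596, alpha=-0.7427, omega=1.1477, kappa=6.071
)
REFERENCE_CONVECTION_TIME = ConvectionTimeParams(
    j=0.332908, w=0.340341, l=0.032229
)


# ---------------------------------------------------------------------------
# Primary micro-level transport (rate vs concentration)
# ---------------------------------------------------------------------------


def primary_advection_rate(x: ArrayLike, params: PrimaryRateParams) -> RateComponents:
    """Evaluate the primary advection rate and its three components.

    Parameters
    ----------
    x : concentration(s), μg/ml; strictly positive.
    params : model parameters.

    Returns
    -------
    RateComponents
        Convection (Ricker, term I), energy-dependent (MM, term II) and
        energy-independent (inverse MM, term III) rates; ``.total`` is
        their exact sum, the advection rate ``y = −1/γ``.
    """
    xa = _as_positive_array(x)
    conv = params.g * xa * np.exp(-params.h * xa)
    ed = params.n * xa / (params.b + xa)
    ei = params.m * (params.p / xa + 1.0)
    if np.ndim(x) == 0:
        return RateComponents(float(conv), float(ed), float(ei))
    return RateComponents(conv, ed, ei)


def primary_advection_rate_derivative(
    x: ArrayLike, params: PrimaryRateParams
) -> float | np.ndarray:
    """Analytic slope dy/dx of the primary advection rate, ml²/(μg²·h).

    ``y'(x) = g·e^(−hx)·(1 − h·x) + n·b/(b+x)² − m·p/x²``
    """
    xa = _as_positive_array(x)
    d = (
        params.g * np.exp(-params.h * xa) * (1.0 - params.h * xa)
        + params.n * params.b / (params.b + xa) ** 2
        - params.m * params.p / xa**2
    )
    return float(d) if np.ndim(x) == 0 else d


# ---------------------------------------------------------------------------
# Secondary micro-level transport (rate constants vs concentration)
# ---------------------------------------------------------------------------


def advection_rate_constant(
    x: ArrayLike, params: RateConstantParams
) -> RateConstantComponents:
    """Evaluate the advection, convection and saturable rate constants (1/h).

    ``c_r = ζ·x·e^(−λx)``; ``st_r = −α·x^ω/(κ + x^ω)`` (positive for the
    fitted negative ``α``); ``a_r = c_r − st_r`` exactly.
    """
    xa = _as_positive_array(x)
    c_r = params.zeta * xa * np.exp(-params.lam * xa)
    xw = xa**params.omega
    st_r = -params.alpha * xw / (params.kappa + xw)
    a_r = c_r - st_r
    if np.ndim(x) == 0:
        return RateConstantComponents(float(a_r), float(c_r), float(st_r))
    return RateConstantComponents(a_r, c_r, st_r)


# ---------------------------------------------------------------------------
# Convection over the dosing interval (rate constant vs time)
# ---------------------------------------------------------------------------


def _nonneg_time(t: ArrayLike) -> np.ndarray:
    ta = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(ta)):
        raise ValueError("t must be finite")
    if np.any(ta < 0):
        raise ValueError("t must be >= 0")
    return ta


def convection_rate_constant_time(
    t: ArrayLike, params: ConvectionTimeParams
) -> float | np.ndarray:
    """Convection rate constant ``c_r(t) = j/(w−l)·(e^(−lt) − e^(−wt))``, 1/h.

    Non-negative for ``t ≥ 0`` (canonical ``w > l``); for ``w ≈ l`` the
    confluent limit ``j·t·e^(−lt)`` is used.
    """
    ta = _nonneg_time(t)
    j, w, l = params.j, params.w, params.l
    if abs(w - l) < EXPONENT_GAP_TOL:
        out = j * ta * np.exp(-l * ta)
    else:
        out = j / (w - l) * (np.exp(-l * ta) - np.exp(-w * ta))
    return float(out) if np.ndim(t) == 0 else out


def acceleration_rate_constant(
    t: ArrayLike, params: ConvectionTimeParams
) -> float | np.ndarray:
    """Acceleration rate constant ``c_r'(t) = j/(w−l)·(w·e^(−wt) − l·e^(−lt))``, 1/h².

    The time derivative of :func:`convection_rate_constant_time`; positive
    before the convection peak and negative after it.
    """
    ta = _nonneg_time(t)
    j, w, l = params.j, params.w, params.l
    if abs(w - l) < EXPONENT_GAP_TOL:
        out = j * (1.0 - l * ta) * np.exp(-l * ta)
    else:
        out = j / (w - l) * (w * np.exp(-w * ta) - l * np.exp(-l * ta))
    return float(out) if np.ndim(t) == 0 else out


def acceleration_zero_crossing(params: ConvectionTimeParams) -> float:
    """Time (h) at which the acceleration changes sign: ``ln(w/l)/(w−l)``.

    Coincides with the maximum of the convection rate constant; independent
    of the amplitude ``j``.
    """
    return math.log(params.w / params.l) / (params.w - params.l)


# ---------------------------------------------------------------------------
# Macro mass balance and uptake concentration
# ---------------------------------------------------------------------------


def macro_advection_rate(mp: MacroTransportParams) -> float:
    """Advection rate ``−1/γ = k_e·V/(D − A)``, ml/(μg·h).

    From the full-absorption mass balance ``k_e = −1/γ·(D/V − A/V)`` with
    concentrations in mg/L ≡ μg/ml.
    """
    return mp.k_e * mp.V / (mp.D - mp.A)


def uptake_concentration(
    t: ArrayLike, A: float, V: float, k_e: float
) -> float | np.ndarray:
    """Uptake concentration ``x_u(t) = A/(V·(1−k_e))·(e^(−k_e·t) − e^(−t))``, μg/ml.

    The Bateman-shaped concentration time course at the point of full
    absorption (absorption rate constant normalised to 1 h⁻¹); for
    ``k_e ≈ 1`` the confluent limit ``A/V·t·e^(−t)`` is used.
    """
    _positive(V, "V")
    _positive(A, "A")
    if not k_e > 0:
        raise ValueError(f"k_e must be > 0, got {k_e!r}")
    ta = _nonneg_time(t)
    if abs(1.0 - k_e) < EXPONENT_GAP_TOL:
        out = A / V * ta * np.exp(-ta)
    else:
        out = A / (V * (1.0 - k_e)) * (np.exp(-k_e * ta) - np.exp(-ta))
    return float(out) if np.ndim(t) == 0 else out
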
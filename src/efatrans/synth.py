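"""Synthetic study data for the transport-analysis pipeline.

Generates everything the downstream stages consume without any external
data: a cohort of virtual patients on a 600-mg efavirenz dose with a
shared 35.56-L uptake volume, concentration grids spanning the fitted
range, and noisy rate / rate-constant observations around the model
curves.

The cohort emulates the structure of a 61-patient simulated efavirenz
study: the dose and uptake volume are fixed, the elimination rate constant
is log-normal across patients, and the bioavailable fraction A/D is
beta-distributed in (0, 1).  The residual model for rate observations is
multiplicative Gaussian by default (σ = 5%), because the rates span two
orders of magnitude over the fitted concentration range; an additive
option is retained.  All draws are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    ConvectionTimeParams,
    MacroTransportParams,
    PrimaryRateParams,
    RateConstantParams,
    advection_rate_constant,
    convection_rate_constant_time,
    macro_advection_rate,
    primary_advection_rate,
)

__all__ = [
    "CohortSpec",
    "NoiseSpec",
    "generate_cohort",
    "cohort_table",
    "generate_rate_dataset",
    "generate_convection_profile",
    "default_concentration_grid",
    "default_time_grid",
]

#: fitted concentration range of the rate regressions, μg/ml
FIT_RANGE = (0.05, 15.5)


def default_concentration_grid(n: int = 200) -> np.ndarray:
    """Log-spaced concentration grid over the fitted range (0, 15.5] μg/ml."""
    return np.geomspace(FIT_RANGE[0], FIT_RANGE[1], n)


def default_time_grid(step_h: float = 0.25) -> np.ndarray:
    """Uniform time grid over one 24-h dosing interval."""
    return np.arange(0.0, 24.0 + step_h / 2, step_h)


@dataclass(frozen=True)
class CohortSpec:
    """Virtual-patient cohort on a fixed oral dose.

    Attributes
    ----------
    n_patients : cohort size (61 in the emulated study).
    D : dose, mg (fixed at 600).
    V : uptake volume, L (fixed at 35.56).
    ke_median : median elimination rate constant, 1/h.
    ke_gcv : geometric coefficient of variation of k_e (log-normal sigma).
    bio_a, bio_b : beta-distribution shapes for the A/D ratio.
    seed : reproducibility seed.
    """

    n_patients: int = 61
    D: float = 600.0
    V: float = 35.56
    ke_median: float = 0.05
    ke_gcv: float = 0.3
    bio_a: float = 8.0
    bio_b: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for nm in ("D", "V", "ke_median", "ke_gcv", "bio_a", "bio_b"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for generated rate data.

    ``multiplicative-gaussian``: value = curve · (1 + ε), ε ~ N(0, σ²);
    ``additive-gaussian``: value = curve + ε, ε ~ N(0, σ²).
    σ = 0 reproduces the model curve exactly.
    """

    model: str = "multiplicative-gaussian"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, curve: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(curve, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sigma, size=np.shape(curve))
        if self.model == "multiplicative-gaussian":
            return curve * (1.0 + eps)
        return curve + eps


def generate_cohort(spec: CohortSpec) -> list[MacroTransportParams]:
    """Draw a reproducible cohort of macro transport parameter sets.

    k_e is log-normal around the median with geometric CV ``ke_gcv``;
    A = D · Beta(bio_a, bio_b) (degenerate draws at the open endpoints are
    nudged inward so 0 < A < D always holds).
    """
    rng = np.random.default_rng(spec.seed)
    ke = spec.ke_median * np.exp(rng.normal(0.0, spec.ke_gcv, spec.n_patients))
    frac = rng.beta(spec.bio_a, spec.bio_b, spec.n_patients)
    frac = np.clip(frac, 1e-9, 1.0 - 1e-9)
    return [
        MacroTransportParams(D=spec.D, V=spec.V, A=float(spec.D * f), k_e=float(k))
        for f, k in zip(frac, ke)
    ]


def cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Cohort as a table with each patient's implied macro advection rate."""
    patients = generate_cohort(spec)
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, len(patients) + 1),
            "D": [mp.D for mp in patients],
            "V": [mp.V for mp in patients],
            "A": [mp.A for mp in patients],
            "k_e": [mp.k_e for mp in patients],
            "y_macro": [macro_advection_rate(mp) for mp in patients],
        }
    )


def generate_rate_dataset(
    true_params: PrimaryRateParams | RateConstantParams,
    grid: np.ndarray,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> pd.DataFrame:
    """Noisy observations of a rate curve on a concentration grid.

    For :class:`PrimaryRateParams` the value column is the total advection
    rate y(x); for :class:`RateConstantParams` it is the advection rate
    constant a_r(x).  Returns a frame with columns ``x`` and ``value``.
    """
    xa = np.asarray(grid, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("concentration grid must be strictly positive")
    if np.any(xa > 60.0):
        raise ValueError("concentration grid must lie within (0, 60] μg/ml")
    if isinstance(true_params, PrimaryRateParams):
        curve = primary_advection_rate(xa, true_params).total
    elif isinstance(true_params, RateConstantParams):
        curve = advection_rate_constant(xa, true_params).a_r
    else:
        raise TypeError(f"unsupported parameter type {type(true_params).__name__}")
    return pd.DataFrame({"x": xa, "value": noise.apply(curve)})


def generate_convection_profile(
    true_params: ConvectionTimeParams,
    times: np.ndarray,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> pd.DataFrame:
    """Noisy observations of the Bateman convection profile on a time grid.

    Returns a frame with columns ``t`` and ``value``; times must lie within
    one 24-h dosing interval.
    """
    ta = np.asarray(times, dtype=float)
    if np.any(ta < 0) or np.any(ta > 24):
        raise ValueError("times must lie within [0, 24] h")
    curve = convection_rate_constant_time(ta, true_params)
    return pd.DataFrame({"t": ta, "value": noise.apply(curve)})
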
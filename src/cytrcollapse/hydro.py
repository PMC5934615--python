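"""Hydrodynamics of a disordered chain from dynamic light scattering.

Converts concentration series of translational diffusion coefficients to
infinite-dilution values (``D = D0 * (1 + a*C)``), applies the
Stokes-Einstein relation to obtain hydrodynamic radii, interconverts
hydrodynamic radius and radius of gyration for disordered chains, and
evaluates Flory-type polymer scaling laws ``R_G = rho0 * N**nu``.

Units contract: diffusion coefficients in m^2 s^-1, temperatures in K,
radii in Angstrom at the API boundary, concentrations in mg mL^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DiffusionSeries",
    "DiffusionFit",
    "HydroResult",
    "ChainScaling",
    "RgRhConversion",
    "water_viscosity",
    "fit_diffusion_series",
    "stokes_einstein_rh",
    "rg_to_rh",
    "rh_to_rg",
    "scaling_rg",
    "percent_compaction",
    "hydro_pipeline",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class DiffusionSeries:
    """Diffusion coefficients vs protein concentration at one temperature.

    Parameters
    ----------
    T : float
        Temperature in K.
    concentrations : array-like
        Protein concentrations in mg mL^-1 (non-negative).
    D : array-like
        Translational diffusion coefficients in m^2 s^-1 (positive).
    """

    T: float
    concentrations: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.D, dtype=float)
        if c.size == 0:
            raise ValueError("DiffusionSeries needs at least one entry")
        if c.shape != d.shape:
            raise ValueError("concentrations and D must have the same shape")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(d <= 0):
            raise ValueError("diffusion coefficients must be positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "D", d)


@dataclass(frozen=True)
class DiffusionFit:
    """Infinite-dilution intercept and non-ideality slope of a DLS series."""

    D0: float
    a: float
    residual_norm: float

    def __post_init__(self):
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")


@dataclass(frozen=True)
class HydroResult:
    """Hydrodynamic radius (and optional R_G) at one temperature."""

    T: float
    Rh: float
    N: int
    Rg: float | None = None

    def __post_init__(self):
        if self.Rh <= 0:
            raise ValueError("Rh must be positive")
        if self.N < 2:
            raise ValueError("chain length N must be >= 2")


@dataclass(frozen=True)
class ChainScaling:
    """Flory scaling law R_G = rho0 * N**nu.

    nu = 1/3 marks a compact globule, 1/2 the ideal (theta-state) chain and
    3/5 a self-avoiding coil; values outside [1/3, 3/5] are accepted with a
    warning since empirical fits may fall slightly outside.
    """

    rho0: float
    nu: float

    def __post_init__(self):
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if not (1.0 / 3.0 <= self.nu <= 3.0 / 5.0):
            warnings.warn(
                f"Flory exponent nu={self.nu} outside the physical range "
                "[1/3, 3/5]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RgRhConversion:
    """Empirical disordered-chain R_G/R_h ratio, linear in R_G.

    alpha(Rg, N) = a1*(Rg - a2*N**0.33)/(N**0.60 - N**0.33) + a3, with
    alpha = Rg/Rh.  The anchoring exponents 0.33 and 0.60 are the literal
    constants of the published calibration (not 1/3 and 3/5).
    """

    a1: float = 0.216  # 1/Angstrom
    a2: float = 4.06  # Angstrom
    a3: float = 0.821


DEFAULT_CONVERSION = RgRhConversion()


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of water in Pa s at temperature ``T`` (K).

    Uses the empirical Vogel-type correlation
    ``eta = 2.414e-5 * 10**(247.8 / (T - 140))``, accurate to ~1% over
    273-373 K.  Strictly decreasing in T.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 273.0) or np.any(T >= 373.0):
        raise ValueError("water_viscosity is defined for 273 K < T < 373 K")
    return 2.414e-5 * 10.0 ** (247.8 / (T - 140.0))


def fit_diffusion_series(series: DiffusionSeries) -> DiffusionFit:
    """Least-squares fit of D = D0*(1 + a*C) to one temperature's series.

    With a single entry the fit degenerates to ``D0 = D, a = 0`` and a
    warning is emitted.  Exact on noiseless linear input.
    """
    c, d = series.concentrations, series.D
    if np.unique(c).size < 2:
        if c.size == 1:
            warnings.warn(
                "single concentration: returning D0 = D with a = 0",
                stacklevel=2,
            )
            return DiffusionFit(D0=float(d[0]), a=0.0, residual_norm=0.0)
        # replicated single concentration: fit intercept only
        warnings.warn(
            "all entries share one concentration: a fixed at 0",
            stacklevel=2,
        )
        d0 = float(np.mean(d))
        return DiffusionFit(
            D0=d0, a=0.0, residual_norm=float(np.linalg.norm(d - d0))
        )
    # D = D0 + (D0*a) * C  -> ordinary least squares in (intercept, slope)
    A = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(A, d, rcond=None)
    d0, slope = float(coef[0]), float(coef[1])
    resid = float(np.linalg.norm(A @ coef - d))
    return DiffusionFit(D0=d0, a=slope / d0, residual_norm=resid)


def stokes_einstein_rh(D0: float, T: float) -> float:
    """Hydrodynamic radius in Angstrom from the Stokes-Einstein relation.

    Rh = k_B * T / (6 * pi * eta(T) * D0), with eta the water viscosity.
    """
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    eta = water_viscosity(T)
    rh_m = BOLTZMANN_J_PER_K * T / (6.0 * np.pi * eta * D0)
    return float(rh_m * 1e10)


def stokes_einstein_d0(Rh: float, T: float) -> float:
    """Inverse of :func:`stokes_einstein_rh`: D0 (m^2 s^-1) from Rh (A)."""
    if Rh <= 0:
        raise ValueError("Rh must be positive")
    eta = water_viscosity(T)
    return float(BOLTZMANN_J_PER_K * T / (6.0 * np.pi * eta * Rh * 1e-10))


def _alpha(Rg: float, N: int, conv: RgRhConversion) -> float:
    n33 = N**0.33
    n60 = N**0.60
    return conv.a1 * (Rg - conv.a2 * n33) / (n60 - n33) + conv.a3


def rg_to_rh(
    Rg: float, N: int, conv: RgRhConversion = DEFAULT_CONVERSION
) -> float:
    """Hydrodynamic radius (A) of a disordered N-residue chain from R_G (A)."""
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    if N < 2:
        raise ValueError("N must be >= 2")
    return float(Rg / _alpha(Rg, N, conv))


def rh_to_rg(
    Rh: float, N: int, conv: RgRhConversion = DEFAULT_CONVERSION
) -> float:
    """Invert :func:`rg_to_rh` for R_G (A) by bracketed root finding.

    The forward map is strictly increasing in R_G over the physical
    bracket [2, 5*N**0.6] A, so the root is unique when it exists.
    """
    if Rh <= 0:
        raise ValueError("Rh must be positive")
    if N < 2:
        raise ValueError("N must be >= 2")
    lo, hi = 2.0, 5.0 * N**0.60

    def f(rg: float) -> float:
        return rg_to_rh(rg, N, conv) - Rh

    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"no R_G root in the physical bracket [{lo:.3g}, {hi:.3g}] A "
            f"for Rh={Rh} A, N={N}"
        )
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def scaling_rg(N: int, scaling: ChainScaling) -> float:
    """Radius of gyration in Angstrom from the Flory law rho0 * N**nu."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(scaling.rho0 * N**scaling.nu)


def percent_compaction(Rh_a: float, Rh_b: float) -> float:
    """Relative size difference 100*(Rh_a - Rh_b)/Rh_a in percent."""
    if Rh_a <= 0:
        raise ValueError("reference radius must be positive")
    return float(100.0 * (Rh_a - Rh_b) / Rh_a)


def hydro_pipeline(
    series_list: list[DiffusionSeries],
    N: int,
    conv: RgRhConversion = DEFAULT_CONVERSION,
    use: str = "D0",
) -> list[HydroResult]:
    """Full DLS pipeline: per-temperature fit, Rh, and R_G conversion.

    ``use`` selects the diffusion coefficient entering Stokes-Einstein:
    ``"D0"`` (default) takes the infinite-dilution intercept; ``"lowest"``
    takes the measured D at the lowest concentration.  Both were used in
    the experimental protocol this reproduces; the intercept is the less
    biased estimator and is the default.
    """
    if use not in ("D0", "lowest"):
        raise ValueError("use must be 'D0' or 'lowest'")
    results = []
    for series in series_list:
        fit = fit_diffusion_series(series)
        if use == "D0":
            d = fit.D0
        else:
            d = float(series.D[np.argmin(series.concentrations)])
        rh = stokes_einstein_rh(d, series.T)
        rg = rh_to_rg(rh, N, conv)
        results.append(HydroResult(T=series.T, Rh=rh, N=N, Rg=rg))
    return results
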
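"""Absolute heat capacity from concentration-series DSC and the
variable-barrier (Landau) model of a continuous collapse transition.

The experimental chain is: apparent (buffer-displaced) heat capacities at
several protein concentrations -> per-temperature linear regression against
protein mass in the cell -> absolute specific (then molar) heat capacity ->
subtraction of an empirical folded baseline -> excess heat capacity and the
enthalpy-fluctuation curve dH2(T) = R*T^2*Cp_excess(T).

The variable-barrier model treats enthalpy H as the order parameter of a
Landau free-energy functional

    G0(H) = -2*beta*(H/alpha)^2 + |beta|*(H/alpha)^4,

with alpha = alpha_neg for H < 0 and alpha_pos for H >= 0 so that the two
lobes can be asymmetric (alpha_neg + alpha_pos = sum_alpha, asymmetry
f = min/max).  A negative beta gives a single minimum (downhill, second
order-like); positive beta a two-minimum (barrier-limited) profile.  The
functional defines a microcanonical entropy S0(H) = (H - G0(H))/T0 (so
that the T0-ensemble density is exp(-G0/(R*T0))), giving

    P(H, T) ~ exp(S0(H)/R - H/(R*T)),

a proper Boltzmann form in which the model heat capacity obeys the
fluctuation-dissipation identity exactly: d<H>/dT = var(H)/(R*T^2).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_KJ_PER_MOL_K",
    "CpThermogram",
    "AbsoluteCpCurve",
    "VBParams",
    "EnthalpyDensity",
    "VBFitResult",
    "water_density",
    "water_specific_heat",
    "absolute_cp",
    "folded_baseline",
    "unfolded_baseline",
    "excess_fluctuations",
    "vb_density",
    "vb_cp",
    "vb_fit",
]

R_KJ_PER_MOL_K = 8.314e-3

# --- water property correlations (273-373 K) ------------------------------

# Kell (1975) density of air-free water at 1 atm, g/mL, t in Celsius.
_KELL_NUM = (
    999.83952,
    16.945176,
    -7.9870401e-3,
    -46.170461e-6,
    105.56302e-9,
    -280.54253e-12,
)
_KELL_DEN = 16.897850e-3

# isobaric specific heat of liquid water, J g^-1 K^-1, 0-100 C (steam tables)
_CPW_T_C = np.array([0.0, 10, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100])
_CPW = np.array(
    [4.2176, 4.1921, 4.1818, 4.1796, 4.1785, 4.1786, 4.1807, 4.1844,
     4.1896, 4.1964, 4.2051, 4.2159]
)


def water_density(T):
    """Density of water in g mL^-1 at temperature T (K), Kell correlation."""
    t = np.asarray(T, dtype=float) - 273.15
    num = sum(c * t**i for i, c in enumerate(_KELL_NUM))
    return num / (1.0 + _KELL_DEN * t) / 1000.0


def water_specific_heat(T):
    """Specific heat of water in kJ g^-1 K^-1 at T (K), interpolated."""
    t = np.asarray(T, dtype=float) - 273.15
    return np.interp(t, _CPW_T_C, _CPW) / 1000.0


# --- domain types ---------------------------------------------------------


@dataclass(frozen=True)
class CpThermogram:
    """One apparent heat-capacity scan.

    ``cp_app`` is the buffer-displaced apparent heat capacity of the filled
    cell in kJ K^-1 (protein scan minus buffer scan), on a strictly
    increasing temperature grid.
    """

    T: np.ndarray
    cp_app: np.ndarray
    concentration_uM: float
    scan_id: str = "scan"

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        cp = np.asarray(self.cp_app, dtype=float)
        if T.ndim != 1 or T.size < 2:
            raise ValueError("thermogram needs a 1-D grid of >= 2 points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if T.shape != cp.shape:
            raise ValueError("T and cp_app must have the same shape")
        if self.concentration_uM <= 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "cp_app", cp)


@dataclass(frozen=True)
class AbsoluteCpCurve:
    """Absolute molar heat capacity with baselines and fluctuation curve.

    All heat capacities in kJ mol^-1 K^-1; ``dH2`` in (kJ mol^-1)^2.
    ``cp_excess = cp_abs - baseline_folded`` by construction.
    """

    T: np.ndarray
    cp_abs: np.ndarray
    baseline_folded: np.ndarray
    baseline_unfolded: np.ndarray
    cp_excess: np.ndarray
    dH2: np.ndarray


@dataclass(frozen=True)
class VBParams:
    """Variable-barrier model parameters.

    sum_alpha : total enthalpy scale alpha_neg + alpha_pos, kJ mol^-1.
    beta : curvature parameter, kJ mol^-1 (negative = downhill profile,
        positive = barrier of height beta at T0).
    T0 : characteristic temperature, K.
    f : asymmetry factor min(alpha)/max(alpha) in (0, 1].
    larger_side : which lobe carries the larger alpha ("high" places it on
        the high-enthalpy side, matching positively skewed densities).
    n_grid, span_mult : enthalpy grid settings (points; half-span as a
        multiple of sum_alpha).
    """

    sum_alpha: float
    beta: float
    T0: float
    f: float = 1.0
    larger_side: str = "high"
    n_grid: int = 2001
    span_mult: float = 2.5

    def __post_init__(self):
        if self.sum_alpha <= 0:
            raise ValueError("sum_alpha must be positive")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("asymmetry f must lie in (0, 1]")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.larger_side not in ("high", "low"):
            raise ValueError("larger_side must be 'high' or 'low'")

    @property
    def alphas(self) -> tuple[float, float]:
        """(alpha_neg, alpha_pos) for the H<0 and H>=0 lobes."""
        large = self.sum_alpha / (1.0 + self.f)
        small = self.sum_alpha - large
        if self.larger_side == "high":
            return small, large
        return large, small


@dataclass(frozen=True)
class EnthalpyDensity:
    """Normalized probability density over enthalpy at one temperature."""

    H: np.ndarray
    P: np.ndarray
    T: float

    def mean(self) -> float:
        return float(np.trapezoid(self.P * self.H, self.H))

    def variance(self) -> float:
        m = self.mean()
        return float(np.trapezoid(self.P * (self.H - m) ** 2, self.H))

    def n_modes(self) -> int:
        """Count strict interior local maxima of the density."""
        p = self.P
        return int(np.sum((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])))


@dataclass(frozen=True)
class VBFitResult:
    params: VBParams
    residual_norm: float
    per_start: list[dict]


# --- absolute heat capacity ----------------------------------------------


def _common_grid(thermograms: list[CpThermogram]) -> np.ndarray:
    grids = [t.T for t in thermograms]
    first = grids[0]
    if all(g.shape == first.shape and np.allclose(g, first) for g in grids):
        return first
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    if hi <= lo:
        raise ValueError("thermogram temperature ranges do not overlap")
    warnings.warn(
        "thermogram grids differ; regridding to the overlap by "
        "interpolation (no extrapolation)",
        stacklevel=3,
    )
    n = max(g.size for g in grids)
    return np.linspace(lo, hi, n)


def protein_mass_in_cell(
    concentration_uM: float, molar_mass: float, cell_volume_mL: float
) -> float:
    """Protein mass (g) in the calorimeter cell for a given loading."""
    return concentration_uM * 1e-6 * molar_mass * cell_volume_mL * 1e-3


def absolute_cp(
    thermograms: list[CpThermogram],
    molar_mass: float,
    partial_specific_volume: float = 0.73,
    cell_volume_mL: float = 0.137,
    composition: dict[str, int] | None = None,
) -> AbsoluteCpCurve:
    """Absolute molar heat capacity from a DSC concentration series.

    At each temperature the apparent heat capacities are regressed against
    protein mass m in the cell; the slope s(T) equals
    ``c_p(T) - vbar*rho_w(T)*c_pw(T)`` (the displaced-buffer deficit), so
    the absolute specific heat is recovered as
    ``c_p(T) = s(T) + vbar*rho_w(T)*c_pw(T)`` and scaled by the molar mass.

    The excess heat capacity subtracts the folded (Freire-type) baseline;
    ``composition`` (residue one-letter counts) feeds the unfolded
    Makhatadze-Privalov-type baseline and defaults to a uniform composition
    if omitted.
    """
    if len(thermograms) < 2:
        raise ValueError("absolute Cp extraction needs >= 2 concentrations")
    concs = [t.concentration_uM for t in thermograms]
    if np.unique(np.round(concs, 9)).size < 2:
        raise ValueError("need >= 2 distinct concentrations for the slope")
    grid = _common_grid(thermograms)
    masses = np.array(
        [
            protein_mass_in_cell(t.concentration_uM, molar_mass, cell_volume_mL)
            for t in thermograms
        ]
    )
    cp_matrix = np.vstack(
        [np.interp(grid, t.T, t.cp_app) for t in thermograms]
    )  # (n_scans, n_T)
    A = np.column_stack([np.ones_like(masses), masses])
    coef, *_ = np.linalg.lstsq(A, cp_matrix, rcond=None)
    slope = coef[1]  # kJ K^-1 g^-1
    c_spec = slope + partial_specific_volume * water_density(
        grid
    ) * water_specific_heat(grid)
    cp_abs = c_spec * molar_mass
    folded = folded_baseline(grid, molar_mass)
    if composition is None:
        composition = uniform_composition(max(2, round(molar_mass / 110.0)))
    unfolded = unfolded_baseline(grid, composition)
    cp_excess = cp_abs - folded
    return AbsoluteCpCurve(
        T=grid,
        cp_abs=cp_abs,
        baseline_folded=folded,
        baseline_unfolded=unfolded,
        cp_excess=cp_excess,
        dH2=excess_fluctuations(grid, cp_excess),
    )


# --- baselines ------------------------------------------------------------

# Freire-type folded-state specific heat: linear in T, ~1.25 J g^-1 K^-1 at
# 298 K with slope 5.0e-3 J g^-1 K^-2 (typical of compact folded proteins).
FOLDED_CP_298 = 1.25e-3  # kJ g^-1 K^-1
FOLDED_CP_SLOPE = 5.0e-6  # kJ g^-1 K^-2


def folded_baseline(
    T,
    molar_mass: float,
    cp_298: float = FOLDED_CP_298,
    slope: float = FOLDED_CP_SLOPE,
) -> np.ndarray:
    """Folded-state molar heat capacity baseline, linear in T (kJ/mol/K)."""
    T = np.asarray(T, dtype=float)
    return (cp_298 + slope * (T - 298.15)) * molar_mass


def _load_unfolded_table() -> tuple[np.ndarray, dict[str, np.ndarray]]:
    path = resources.files("cytrcollapse.data") / "unfolded_residue_cp.csv"
    with path.open() as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    temps = np.array([float(x) for x in header[1:]])
    table = {r[0]: np.array([float(x) for x in r[1:]]) for r in rows[1:]}
    return temps, table


_UNFOLDED_CACHE: tuple[np.ndarray, dict[str, np.ndarray]] | None = None


def uniform_composition(n_residues: int) -> dict[str, float]:
    """Composition with equal weight on all 20 residue types (fallback
    when the true sequence composition is not supplied)."""
    global _UNFOLDED_CACHE
    if _UNFOLDED_CACHE is None:
        _UNFOLDED_CACHE = _load_unfolded_table()
    _, table = _UNFOLDED_CACHE
    return {res: n_residues / len(table) for res in table}


def unfolded_baseline(T, composition: dict[str, float]) -> np.ndarray:
    """Unfolded-state molar Cp baseline from residue composition (kJ/mol/K).

    Composition-weighted sum of tabulated per-residue heat capacities
    (additive Makhatadze-Privalov-type scheme; the packaged coefficient
    table is an approximate, editable transcription), linearly
    interpolated in temperature.
    """
    global _UNFOLDED_CACHE
    if _UNFOLDED_CACHE is None:
        _UNFOLDED_CACHE = _load_unfolded_table()
    temps, table = _UNFOLDED_CACHE
    unknown = sorted(set(composition) - set(table))
    if unknown:
        raise KeyError(f"unknown residue codes: {', '.join(unknown)}")
    T = np.asarray(T, dtype=float)
    total = np.zeros_like(T)
    for res, count in composition.items():
        total += count * np.interp(T, temps, table[res])
    return total / 1000.0  # J -> kJ


def excess_fluctuations(T, cp_excess) -> np.ndarray:
    """Excess enthalpy variance dH2(T) = R*T^2*Cp_excess(T), (kJ/mol)^2."""
    T = np.asarray(T, dtype=float)
    return R_KJ_PER_MOL_K * T**2 * np.asarray(cp_excess, dtype=float)


# --- variable-barrier model ----------------------------------------------


def _vb_g0(H: np.ndarray, params: VBParams) -> np.ndarray:
    a_neg, a_pos = params.alphas
    alpha = np.where(H < 0, a_neg, a_pos)
    x2 = (H / alpha) ** 2
    return -2.0 * params.beta * x2 + abs(params.beta) * x2**2


def _vb_logdens(H: np.ndarray, params: VBParams, T: float) -> np.ndarray:
    s0_over_r = (H - _vb_g0(H, params)) / (R_KJ_PER_MOL_K * params.T0)
    return s0_over_r - H / (R_KJ_PER_MOL_K * T)


def vb_density(params: VBParams, T: float) -> EnthalpyDensity:
    """Normalized enthalpy probability density P(H, T) of the VB model.

    The H grid spans ``+-span_mult*sum_alpha``; if more than 1e-6 of the
    probability mass sits in the edge bins the grid is widened once (x2)
    before erroring out.
    """
    span = params.span_mult * params.sum_alpha
    for attempt in range(2):
        H = np.linspace(-span, span, params.n_grid)
        logp = _vb_logdens(H, params, T)
        logp -= logp.max()
        p = np.exp(logp)
        norm = np.trapezoid(p, H)
        p /= norm
        dH = H[1] - H[0]
        edge_mass = (p[0] + p[-1]) * dH
        if edge_mass <= 1e-6:
            return EnthalpyDensity(H=H, P=p, T=float(T))
        span *= 2.0
    raise ValueError(
        "enthalpy grid too narrow even after widening: density mass "
        f"{edge_mass:.2e} at the edges (T={T} K)"
    )


def vb_cp(params: VBParams, T_grid) -> np.ndarray:
    """Model excess heat capacity Cp_excess(T) = var[H]/(R*T^2), kJ/mol/K."""
    T_grid = np.asarray(T_grid, dtype=float)
    out = np.empty_like(T_grid)
    for i, T in enumerate(T_grid):
        dens = vb_density(params, T)
        out[i] = dens.variance() / (R_KJ_PER_MOL_K * T**2)
    return out


def vb_mean_enthalpy(params: VBParams, T_grid) -> np.ndarray:
    """Ensemble mean enthalpy <H>(T) of the VB density, kJ/mol."""
    T_grid = np.asarray(T_grid, dtype=float)
    return np.array([vb_density(params, T).mean() for T in T_grid])


def _vb_from_vector(x: np.ndarray, template: VBParams) -> VBParams:
    return replace(
        template,
        sum_alpha=float(np.exp(x[0])),
        beta=float(x[1]),
        T0=float(x[2]),
        f=float(min(x[3], 1.0)),
    )


def vb_fit(
    T_grid,
    cp_excess,
    init: VBParams,
    multistart: int = 5,
    seed: int | None = None,
    perturbation: float = 0.2,
) -> VBFitResult:
    """Least-squares fit of the VB model to an excess heat-capacity curve.

    Runs ``multistart`` local optimizations from the given initial guess
    perturbed by +-``perturbation`` (uniform, seeded), with sum_alpha
    log-parameterized and f bounded in (0, 1]; returns the best start and
    a per-start diagnostic table.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    y = np.asarray(cp_excess, dtype=float)
    rng = np.random.default_rng(seed)

    def residual(x: np.ndarray) -> np.ndarray:
        return vb_cp(_vb_from_vector(x, init), T_grid) - y

    x0_base = np.array([np.log(init.sum_alpha), init.beta, init.T0, init.f])
    lb = [np.log(10.0), -5000.0, 200.0, 1e-3]
    ub = [np.log(1e6), 5000.0, 400.0, 1.0]
    per_start: list[dict] = []
    best = None
    for k in range(multistart):
        if k == 0:
            x0 = x0_base.copy()
        else:
            fac = 1.0 + rng.uniform(-perturbation, perturbation, size=4)
            x0 = np.array(
                [
                    np.log(init.sum_alpha * fac[0]),
                    init.beta * fac[1],
                    init.T0 * fac[2],
                    np.clip(init.f * fac[3], 1e-3, 1.0),
                ]
            )
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                residual, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14,
                gtol=1e-14,
            )
            cost = float(np.linalg.norm(sol.fun))
            per_start.append(
                {"start": k, "cost": cost, "success": bool(sol.success),
                 "x": sol.x.tolist()}
            )
            if sol.success and (best is None or cost < best[0]):
                best = (cost, sol.x)
        except Exception as exc:  # keep going; report in diagnostics
            per_start.append(
                {"start": k, "cost": np.inf, "success": False,
                 "error": str(exc)}
            )
    if best is None:
        raise RuntimeError(
            f"VB fit failed to converge from any start: {per_start}"
        )
    cost, x = best
    return VBFitResult(
        params=_vb_from_vector(x, init), residual_norm=cost,
        per_start=per_start,
    )
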
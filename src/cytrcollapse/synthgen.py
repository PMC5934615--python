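"""Synthetic instrument data with the statistical structure the analyses
assume.

Each generator is the exact forward model of its analysis stage, so that at
zero noise the corresponding analysis inverts it to machine precision:

* DLS concentration series from a two-state coil/globule radius scenario
  through the Stokes-Einstein relation and D = D0*(1 + a*C);
* apparent DSC thermograms from a variable-barrier excess heat capacity on
  top of a folded baseline, through the displaced-buffer relation;
* anisotropy binding isotherms from the quenched-heterogeneity ensemble;
* single-probe melt curves and rank-2 emission spectral matrices from the
  two-state mixture model.

Noise is additive Gaussian on the measured signal, controlled by a single
seeded :class:`NoiseSpec` per call; identical (parameters, seed) give
bitwise-identical output.  Default parameters describe the study
conditions of the disordered CytR DNA-binding domain: R_h contracting
from 24 to ~17 A over 283-333 K with a collapse midpoint near 312 K,
DSC loadings of 52-110 uM, titrations over 1 nM - 100 uM, and probe
midpoints at 301/307/312 K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import binding as _binding
from . import calorimetry as _cal
from . import hydro as _hydro
from . import melts as _melts

R_KJ_PER_MOL_K = 8.314e-3

__all__ = [
    "NoiseSpec",
    "CollapseScenario",
    "TwoStateParams",
    "DEFAULT_MOLAR_MASS",
    "DEFAULT_PROBE_MIDPOINTS",
    "gen_dls_series",
    "gen_thermograms",
    "gen_binding_isotherm",
    "gen_melt_curve",
    "gen_spectral_matrix",
]

# 66-residue disordered DNA-binding domain, ~7.5 kDa
DEFAULT_MOLAR_MASS = 7500.0
DEFAULT_N_RESIDUES = 66

# apparent probe midpoints (K): local structure melts before the chain
# collapses, producing the decoupled 301/307/312 pattern
DEFAULT_PROBE_MIDPOINTS = {
    "fluorescence_shift": 301.0,
    "near_uv_cd": 307.0,
    "dls_rh": 312.0,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise in the units of the signal."""

    sd: float = 0.0
    seed: int | None = None
    kind: str = "additive-gaussian"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.kind != "additive-gaussian":
            raise ValueError("only additive-gaussian noise is supported")

    def apply(self, signal: np.ndarray, rng: np.random.Generator | None = None):
        if self.sd == 0.0:
            return np.asarray(signal, dtype=float).copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return np.asarray(signal, dtype=float) + rng.normal(
            0.0, self.sd, size=np.shape(signal)
        )


NOISELESS = NoiseSpec(sd=0.0)


@dataclass(frozen=True)
class CollapseScenario:
    """Two-state coil/globule hydrodynamic-radius scenario.

    The pure-state radii are linear in temperature (intercept at 298 K,
    slope per K) and mixed through a van't Hoff two-state equilibrium with
    midpoint ``T_c`` and enthalpy ``dH_c``.
    """

    T_grid: np.ndarray = field(
        default_factory=lambda: np.arange(283.0, 334.0, 10.0)
    )
    Rh_expanded: tuple[float, float] = (24.0, 0.0)  # A at 298 K, A/K
    Rh_collapsed: tuple[float, float] = (16.8, 0.0)
    T_c: float = 312.0
    dH_c: float = 150.0  # kJ/mol

    def __post_init__(self):
        T = np.asarray(self.T_grid, dtype=float)
        if not (T[0] <= self.T_c <= T[-1]):
            raise ValueError("T_c must lie inside the temperature grid")
        re = self._line(self.Rh_expanded, T)
        rc = self._line(self.Rh_collapsed, T)
        if np.any(re <= rc):
            raise ValueError("expanded radius must exceed collapsed radius")
        object.__setattr__(self, "T_grid", T)

    @staticmethod
    def _line(coeffs: tuple[float, float], T: np.ndarray) -> np.ndarray:
        return coeffs[0] + coeffs[1] * (np.asarray(T, dtype=float) - 298.0)

    def rh(self, T) -> np.ndarray:
        """Population-weighted mixed hydrodynamic radius (A)."""
        T = np.asarray(T, dtype=float)
        p_e = _melts.two_state_population(T, self.T_c, self.dH_c)
        return p_e * self._line(self.Rh_expanded, T) + (1.0 - p_e) * self._line(
            self.Rh_collapsed, T
        )


def gen_dls_series(
    scenario: CollapseScenario,
    concentrations=(0.45, 0.90, 1.35),
    a: float = 0.01,
    noise: NoiseSpec = NOISELESS,
) -> list[_hydro.DiffusionSeries]:
    """Diffusion-vs-concentration series at every scenario temperature.

    At each T the infinite-dilution coefficient is the Stokes-Einstein
    inverse of the mixed scenario radius and the concentration dependence
    follows D = D0*(1 + a*C) (a in mL/mg) plus additive noise.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0 or np.any(conc <= 0):
        raise ValueError("concentrations must be non-empty and positive")
    rng = np.random.default_rng(noise.seed)
    out = []
    for T in scenario.T_grid:
        d0 = _hydro.stokes_einstein_d0(float(scenario.rh(T)), float(T))
        d = d0 * (1.0 + a * conc)
        d = noise.apply(d, rng)
        out.append(
            _hydro.DiffusionSeries(T=float(T), concentrations=conc, D=d)
        )
    return out


def gen_thermograms(
    vb: _cal.VBParams,
    concentrations_uM=(52.0, 110.0),
    molar_mass: float = DEFAULT_MOLAR_MASS,
    partial_specific_volume: float = 0.73,
    cell_volume_mL: float = 0.137,
    T_grid=None,
    noise: NoiseSpec = NOISELESS,
    folded_cp_298: float = _cal.FOLDED_CP_298,
    folded_cp_slope: float = _cal.FOLDED_CP_SLOPE,
) -> list[_cal.CpThermogram]:
    """Apparent DSC thermograms for a concentration series.

    The underlying absolute molar heat capacity is the folded baseline plus
    the variable-barrier excess; each apparent trace is the exact
    displaced-buffer image m * (c_p - vbar*rho_w*c_pw) that
    :func:`cytrcollapse.calorimetry.absolute_cp` inverts.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    if conc.size < 2:
        warnings.warn(
            "fewer than 2 concentrations: absolute-Cp extraction downstream "
            "will be impossible",
            stacklevel=2,
        )
    if T_grid is None:
        T_grid = np.arange(278.0, 374.0, 1.0)
    T_grid = np.asarray(T_grid, dtype=float)
    cp_molar = _cal.folded_baseline(
        T_grid, molar_mass, folded_cp_298, folded_cp_slope
    ) + _cal.vb_cp(vb, T_grid)
    c_spec = cp_molar / molar_mass  # kJ/g/K
    deficit = c_spec - partial_specific_volume * _cal.water_density(
        T_grid
    ) * _cal.water_specific_heat(T_grid)
    rng = np.random.default_rng(noise.seed)
    out = []
    for i, c in enumerate(conc):
        m = _cal.protein_mass_in_cell(float(c), molar_mass, cell_volume_mL)
        cp_app = noise.apply(m * deficit, rng)
        out.append(
            _cal.CpThermogram(
                T=T_grid,
                cp_app=cp_app,
                concentration_uM=float(c),
                scan_id=f"synthetic-{i}",
            )
        )
    return out


def gen_binding_isotherm(
    model: _binding.HeterogeneityModel,
    grid=None,
    r_free: float = 0.06,
    r_bound: float = 0.16,
    noise: NoiseSpec = NOISELESS,
) -> _binding.BindingIsotherm:
    """Anisotropy titration of the heterogeneous ensemble.

    anisotropy = r_free + (r_bound - r_free) * bulk fraction bound, plus
    additive noise; the bulk fraction comes from
    :func:`cytrcollapse.binding.ensemble_isotherm`.
    """
    if r_bound <= r_free:
        raise ValueError("r_bound must exceed r_free")
    if grid is None:
        grid = _binding.default_titration_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    f = _binding.ensemble_isotherm(model, grid)
    r = _binding.anisotropy_from_fraction(f, r_free, r_bound)
    r = noise.apply(r)
    return _binding.BindingIsotherm(
        T=model.T, ligand=grid, signal=r, signal_kind="anisotropy"
    )


@dataclass(frozen=True)
class TwoStateParams:
    """Midpoint and van't Hoff enthalpy of one probe's transition."""

    T_m: float
    dH_vH: float = 150.0
    probe: str = "probe"


def gen_melt_curve(
    two_state: TwoStateParams,
    baseline_E: tuple[float, float] = (1.0, 0.0),
    baseline_C: tuple[float, float] = (0.0, 0.0),
    T_grid=None,
    noise: NoiseSpec = NOISELESS,
) -> _melts.ProbeSignalCurve:
    """Population-weighted two-state melt for one probe.

    Baselines are (intercept at T_m, slope per K) for the expanded and
    collapsed states; at zero noise :func:`cytrcollapse.melts.two_state_fit`
    recovers T_m and dH_vH exactly.
    """
    if T_grid is None:
        T_grid = np.arange(278.0, 351.0, 2.0)
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("temperature grid must be non-empty")
    y = _melts.two_state_signal(
        T_grid, two_state.T_m, two_state.dH_vH, baseline_E, baseline_C
    )
    y = noise.apply(y)
    return _melts.ProbeSignalCurve(T=T_grid, signal=y, probe=two_state.probe)


def default_melt_set(
    noise: NoiseSpec = NOISELESS, dH_vH: float = 150.0
) -> list[_melts.ProbeSignalCurve]:
    """The three decoupled probe melts (301/307/312 K defaults)."""
    rng = np.random.default_rng(noise.seed)
    curves = []
    for probe, tm in DEFAULT_PROBE_MIDPOINTS.items():
        y = _melts.two_state_signal(
            np.arange(278.0, 351.0, 2.0), tm, dH_vH, (1.0, -0.002), (0.1, 0.001)
        )
        T = np.arange(278.0, 351.0, 2.0)
        curves.append(
            _melts.ProbeSignalCurve(
                T=T, signal=noise.apply(y, rng), probe=probe
            )
        )
    return curves


def gen_spectral_matrix(
    wavelengths=None,
    T_grid=None,
    shift_midpoint: float = 301.0,
    shift_amplitude: float = 0.3,
    dH_vH: float = 150.0,
    noise: NoiseSpec = NOISELESS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-2 emission matrix: average band plus red-shift difference band.

    Returns ``(matrix, wavelengths, temperatures)`` with the matrix built
    as u1*a1(T) + u2*a2(T); the second amplitude crosses zero at
    ``shift_midpoint`` so the SVD second component changes sign there.
    At zero noise the third singular value is exactly zero.
    """
    if wavelengths is None:
        wavelengths = np.arange(280.0, 401.0, 2.0)
    if T_grid is None:
        T_grid = np.arange(278.0, 351.0, 2.0)
    wl = np.asarray(wavelengths, dtype=float)
    T = np.asarray(T_grid, dtype=float)
    if T.size == 0 or wl.size == 0:
        raise ValueError("wavelength and temperature grids must be non-empty")
    # mean emission band and its red-shift derivative-like difference band
    u1 = np.exp(-((wl - 303.0) ** 2) / (2.0 * 18.0**2))
    u2 = (wl - 303.0) / 18.0 * u1
    p_e = _melts.two_state_population(T, shift_midpoint, dH_vH)
    a1 = 1.0 - 0.2 * (T - T[0]) / (T[-1] - T[0])  # mild thermal quenching
    a2 = shift_amplitude * (0.5 - p_e) * 2.0  # crosses zero at the midpoint
    M = np.outer(u1, a1) + np.outer(u2, a2)
    M = noise.apply(M)
    return M, wl, T
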
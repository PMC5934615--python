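"""Two-state analysis of single-probe melting curves and spectral SVD.

Each spectroscopic probe (far-UV CD, near-UV CD, DLS-derived radius,
fluorescence red-shift) is fitted independently to a two-state equilibrium
between the expanded coil (U_E) and the collapsed globule (U_C):

    signal(T) = [S_E(T) + S_C(T) * K(T)] / [1 + K(T)],
    K(T) = exp(-dG(T)/(R*T)),   dG(T) = dH_vH * (1 - T/T_m),

with linear baselines S_E, S_C for the pure states (van't Hoff form,
dCp = 0 unless supplied).  Differences between per-probe apparent
midpoints T_m quantify how thermodynamically decoupled the structural
transitions are.  Wavelength x temperature emission matrices are reduced
by an uncentered SVD whose second component tracks the spectral red shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

R_KJ_PER_MOL_K = 8.314e-3

__all__ = [
    "ProbeSignalCurve",
    "TwoStateFit",
    "SVDResult",
    "NoTransitionError",
    "two_state_population",
    "two_state_signal",
    "two_state_fit",
    "collapse_summary",
    "svd_spectra",
]


class NoTransitionError(ValueError):
    """Raised when a melt curve shows no detectable sigmoidal transition."""


@dataclass(frozen=True)
class ProbeSignalCurve:
    """Probe signal vs temperature for one melt."""

    T: np.ndarray
    signal: np.ndarray
    probe: str = "probe"

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if T.size < 8:
            raise ValueError("melt curve needs >= 8 points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if T.shape != s.shape:
            raise ValueError("T and signal must have the same shape")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters and the expanded-state population."""

    probe: str
    T_m: float
    dH_vH: float
    baseline_E: tuple[float, float]  # intercept, slope (at T_m reference)
    baseline_C: tuple[float, float]
    T: np.ndarray
    P_UE: np.ndarray
    residual_norm: float


@dataclass(frozen=True)
class SVDResult:
    """Retained components of an uncentered spectral SVD."""

    wavelengths: np.ndarray
    temperatures: np.ndarray
    basis: np.ndarray  # (n_wavelengths, k) oriented mean >= 0
    singular_values: np.ndarray  # all values, non-increasing
    amplitudes: np.ndarray  # (n_temperatures, k) incl. singular values


def two_state_population(T, T_m: float, dH_vH: float, dCp: float = 0.0):
    """Population of the expanded state U_E at each temperature.

    P_UE = 1/(1 + K) with K the U_E -> U_C equilibrium constant; equals
    0.5 at T_m by construction and decreases with T for dH_vH > 0.
    """
    T = np.asarray(T, dtype=float)
    dG = dH_vH * (1.0 - T / T_m)
    if dCp != 0.0:
        dG = dG + dCp * (T - T_m - T * np.log(T / T_m))
    K = np.exp(-dG / (R_KJ_PER_MOL_K * T))
    return 1.0 / (1.0 + K)


def two_state_signal(
    T,
    T_m: float,
    dH_vH: float,
    baseline_E: tuple[float, float],
    baseline_C: tuple[float, float],
    dCp: float = 0.0,
):
    """Population-weighted two-state signal with linear state baselines.

    Baselines are parameterized about T_m: S(T) = intercept + slope*(T-T_m),
    which decorrelates intercepts from slopes in the fit.
    """
    T = np.asarray(T, dtype=float)
    p = two_state_population(T, T_m, dH_vH, dCp)
    s_e = baseline_E[0] + baseline_E[1] * (T - T_m)
    s_c = baseline_C[0] + baseline_C[1] * (T - T_m)
    return p * s_e + (1.0 - p) * s_c


def two_state_fit(
    curve: ProbeSignalCurve, dCp: float = 0.0, init_Tm: float | None = None
) -> TwoStateFit:
    """Fit the two-state model to one probe's melt.

    The midpoint is initialized at the steepest point of the baseline-
    detrended signal; raises :class:`NoTransitionError` when the fitted
    transition amplitude is indistinguishable from the baselines (monotone
    drift within noise).
    """
    T, y = curve.T, curve.signal
    if init_Tm is None:
        # steepest point of the signal after removing the global trend,
        # plus grid quartiles as fallback starts against local optima
        trend = np.polyval(np.polyfit(T, y, 1), T)
        resid = y - trend
        detected = float(T[np.argmax(np.abs(np.gradient(resid, T)))])
        candidates = [
            float(np.clip(detected, T[2], T[-3])),
            *np.quantile(T, [0.25, 0.5, 0.75]).tolist(),
        ]
    else:
        candidates = [float(init_Tm)]

    n_edge = max(2, T.size // 5)
    pe = np.polyfit(T[:n_edge], y[:n_edge], 1)
    pc = np.polyfit(T[-n_edge:], y[-n_edge:], 1)

    def resid_fn(p):
        return (
            two_state_signal(
                T,
                p["T_m"].value,
                p["dH"].value,
                (p["bE0"].value, p["bE1"].value),
                (p["bC0"].value, p["bC1"].value),
                dCp,
            )
            - y
        )

    out = None
    for tm0 in candidates:
        params = lmfit.Parameters()
        params.add("T_m", value=tm0, min=T[0] - 50, max=T[-1] + 50)
        params.add("dH", value=150.0, min=1.0, max=5000.0)
        params.add("bE0", value=float(np.polyval(pe, tm0)))
        params.add("bE1", value=float(pe[0]))
        params.add("bC0", value=float(np.polyval(pc, tm0)))
        params.add("bC1", value=float(pc[0]))
        trial = lmfit.minimize(resid_fn, params, method="leastsq")
        if out is None or trial.chisqr < out.chisqr:
            out = trial
    p = out.params
    amp = abs(p["bE0"].value - p["bC0"].value)
    noise = float(np.std(np.diff(y, 2)) / np.sqrt(6.0)) if y.size > 2 else 0.0
    if amp < 3.0 * max(noise, 1e-12) or not (T[0] - 20 < p["T_m"] < T[-1] + 20):
        raise NoTransitionError(
            f"no transition detected for probe {curve.probe!r}: amplitude "
            f"{amp:.3g} vs noise {noise:.3g}, T_m {p['T_m'].value:.1f} K"
        )
    return TwoStateFit(
        probe=curve.probe,
        T_m=float(p["T_m"].value),
        dH_vH=float(p["dH"].value),
        baseline_E=(float(p["bE0"].value), float(p["bE1"].value)),
        baseline_C=(float(p["bC0"].value), float(p["bC1"].value)),
        T=T,
        P_UE=two_state_population(T, float(p["T_m"].value), float(p["dH"].value), dCp),
        residual_norm=float(np.linalg.norm(out.residual)),
    )


def collapse_summary(fits: list[TwoStateFit]) -> pd.DataFrame:
    """Probe-vs-midpoint table with the midpoint spread as decoupling stat.

    Returns a DataFrame sorted by T_m with columns probe, T_m_K, dH_vH;
    the max-min spread is stored in ``df.attrs['midpoint_spread_K']``.
    """
    if not fits:
        raise ValueError("need at least one fit")
    df = pd.DataFrame(
        {
            "probe": [f.probe for f in fits],
            "T_m_K": [f.T_m for f in fits],
            "dH_vH_kJ_mol": [f.dH_vH for f in fits],
        }
    ).sort_values("T_m_K", ignore_index=True)
    df.attrs["midpoint_spread_K"] = float(df.T_m_K.max() - df.T_m_K.min())
    return df


def svd_spectra(
    matrix: np.ndarray,
    wavelengths,
    temperatures,
    n_components: int = 2,
) -> SVDResult:
    """Uncentered SVD of a wavelength x temperature spectral matrix.

    The matrix is decomposed as ``M = U S V^T`` without mean-centering so
    the first basis spectrum reports the average emission spectrum; each
    retained basis spectrum is oriented so its mean is non-negative, and
    the per-temperature amplitudes carry the singular values.  Missing
    cells are an error (no imputation).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D (wavelength x temperature)")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains missing or non-finite cells")
    wl = np.asarray(wavelengths, dtype=float)
    Tt = np.asarray(temperatures, dtype=float)
    if M.shape != (wl.size, Tt.size):
        raise ValueError("matrix shape must match (wavelengths, temperatures)")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(n_components, s.size)
    signs = np.where(U[:, :k].mean(axis=0) >= 0, 1.0, -1.0)
    basis = U[:, :k] * signs
    amps = (Vt[:k, :].T * signs) * s[:k]
    return SVDResult(
        wavelengths=wl,
        temperatures=Tt,
        basis=basis,
        singular_values=s,
        amplitudes=amps,
    )
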
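"""CSV interchange formats shared by all stages.

One dialect per instrument class, each with a header row of SI-annotated
column names.  Floats are written with Python repr precision so re-reading
a file reproduces the in-memory values exactly.

Formats
-------
DLS:      temperature_K, concentration_mg_per_ml, diffusion_m2_per_s
DSC:      temperature_K, cp_apparent_kJ_per_K, concentration_uM, scan_id
Isotherm: temperature_K, cytr_conc_M, anisotropy
Melt:     temperature_K, signal, probe
Spectra:  wavelength_nm, then one column per temperature (header in K)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding as _binding
from . import calorimetry as _cal
from . import hydro as _hydro
from . import melts as _melts

__all__ = [
    "write_dls_csv", "read_dls_csv",
    "write_dsc_csv", "read_dsc_csv",
    "write_isotherm_csv", "read_isotherm_csv",
    "write_melt_csv", "read_melt_csv",
    "write_spectra_csv", "read_spectra_csv",
    "write_provenance",
]


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_dls_csv(series_list: list[_hydro.DiffusionSeries], path) -> None:
    rows = []
    for s in series_list:
        for c, d in zip(s.concentrations, s.D):
            rows.append(
                {
                    "temperature_K": s.T,
                    "concentration_mg_per_ml": c,
                    "diffusion_m2_per_s": d,
                }
            )
    _write(pd.DataFrame(rows), path)


def read_dls_csv(path) -> list[_hydro.DiffusionSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for T, grp in df.groupby("temperature_K", sort=True):
        out.append(
            _hydro.DiffusionSeries(
                T=float(T),
                concentrations=grp["concentration_mg_per_ml"].to_numpy(),
                D=grp["diffusion_m2_per_s"].to_numpy(),
            )
        )
    return out


def write_dsc_csv(thermograms: list[_cal.CpThermogram], path) -> None:
    frames = []
    for t in thermograms:
        frames.append(
            pd.DataFrame(
                {
                    "temperature_K": t.T,
                    "cp_apparent_kJ_per_K": t.cp_app,
                    "concentration_uM": t.concentration_uM,
                    "scan_id": t.scan_id,
                }
            )
        )
    _write(pd.concat(frames, ignore_index=True), path)


def read_dsc_csv(path) -> list[_cal.CpThermogram]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (scan, conc), grp in df.groupby(
        ["scan_id", "concentration_uM"], sort=False
    ):
        grp = grp.sort_values("temperature_K")
        out.append(
            _cal.CpThermogram(
                T=grp["temperature_K"].to_numpy(),
                cp_app=grp["cp_apparent_kJ_per_K"].to_numpy(),
                concentration_uM=float(conc),
                scan_id=str(scan),
            )
        )
    return out


def write_isotherm_csv(iso: _binding.BindingIsotherm, path) -> None:
    _write(
        pd.DataFrame(
            {
                "temperature_K": iso.T,
                "cytr_conc_M": iso.ligand,
                "anisotropy": iso.signal,
            }
        ),
        path,
    )


def read_isotherm_csv(path) -> _binding.BindingIsotherm:
    df = pd.read_csv(path, float_precision="round_trip").sort_values("cytr_conc_M")
    return _binding.BindingIsotherm(
        T=float(df["temperature_K"].iloc[0]),
        ligand=df["cytr_conc_M"].to_numpy(),
        signal=df["anisotropy"].to_numpy(),
        signal_kind="anisotropy",
    )


def write_melt_csv(curves: list[_melts.ProbeSignalCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {"temperature_K": c.T, "signal": c.signal, "probe": c.probe}
        )
        for c in curves
    ]
    _write(pd.concat(frames, ignore_index=True), path)


def read_melt_csv(path) -> list[_melts.ProbeSignalCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for probe, grp in df.groupby("probe", sort=False):
        grp = grp.sort_values("temperature_K")
        out.append(
            _melts.ProbeSignalCurve(
                T=grp["temperature_K"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                probe=str(probe),
            )
        )
    return out


def write_spectra_csv(matrix, wavelengths, temperatures, path) -> None:
    df = pd.DataFrame(
        np.asarray(matrix), columns=[str(t) for t in np.asarray(temperatures)]
    )
    df.insert(0, "wavelength_nm", np.asarray(wavelengths))
    _write(df, path)


def read_spectra_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    wl = df["wavelength_nm"].to_numpy()
    temps = np.array([float(c) for c in df.columns[1:]])
    return df.iloc[:, 1:].to_numpy(), wl, temps


def write_provenance(path, config: dict) -> None:
    """JSON sidecar echoing the run configuration (deterministic content)."""
    from . import __version__

    record = {"package": "cytrcollapse", "version": __version__, **config}
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
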
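#!/usr/bin/env python
"""Generate one synthetic dataset of every instrument class.

Writes the five CSV inputs the later stages analyse (DLS concentration
series, DSC thermograms, binding isotherms at 278/308 K, three probe
melts, and a fluorescence spectral matrix) under results/synthetic/.
All stages use a small amount of measurement noise and fixed seeds so the
downstream numbers are reproducible.
"""

from pathlib import Path

from cytrcollapse import binding, calorimetry, io, synthgen

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260922

VB = calorimetry.VBParams(sum_alpha=1554.9, beta=-173.7, T0=291.7, f=0.535)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    scen = synthgen.CollapseScenario()
    io.write_dls_csv(
        synthgen.gen_dls_series(
            scen, noise=synthgen.NoiseSpec(sd=2e-13, seed=SEED)
        ),
        OUT / "dls.csv",
    )

    io.write_dsc_csv(
        synthgen.gen_thermograms(
            VB, concentrations_uM=(52.0, 80.0, 110.0),
            noise=synthgen.NoiseSpec(sd=1e-9, seed=SEED + 1),
        ),
        OUT / "dsc.csv",
    )

    for label, (khalf, sigma, temp) in {
        "278K": (23e-6, 5.1, 278.0),
        "308K": (9e-6, 4.5, 308.0),
    }.items():
        model = binding.HeterogeneityModel.from_median_kd(
            khalf, sigma, temp, mode="monte-carlo", n_molecules=1000,
            seed=SEED + 2,
        )
        io.write_isotherm_csv(
            synthgen.gen_binding_isotherm(
                model, noise=synthgen.NoiseSpec(sd=5e-4, seed=SEED + 3)
            ),
            OUT / f"isotherm_{label}.csv",
        )

    io.write_melt_csv(
        synthgen.default_melt_set(
            noise=synthgen.NoiseSpec(sd=5e-3, seed=SEED + 4)
        ),
        OUT / "melts.csv",
    )

    M, wl, T = synthgen.gen_spectral_matrix(
        noise=synthgen.NoiseSpec(sd=2e-3, seed=SEED + 5)
    )
    io.write_spectra_csv(M, wl, T, OUT / "spectra.csv")

    print(f"wrote 6 synthetic instrument files to {OUT}")


if __name__ == "__main__":
    main()
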
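# cytrcollapse

Quantitative analyses of the temperature-driven coil-to-globule collapse
and heterogeneous DNA binding of the disordered CytR DNA-binding domain —
packaged as a tested Python library with a small set of narrative analysis
drivers.

The CytR DNA-binding domain is a 66-residue intrinsically disordered
protein (IDP) that folds only upon binding its operator DNA. Two linked
phenomena make it an unusually rich model system:

1. **A continuous coil-to-globule collapse.** With increasing temperature
   the chain contracts from an expanded coil (R_h ≈ 24 Å) to a compact
   globule (R_h ≈ 17 Å) with a collapse midpoint near 312 K, where the
   chain passes through ideal (Θ-state) dimensions and its enthalpic
   fluctuations are large — the signature of a second-order-like,
   barrier-free transition rather than cooperative two-state folding.
2. **Negatively cooperative 1:1 DNA binding.** Bulk titrations fit the
   Hill equation with n_H < 1 even though each molecule binds a single
   site. The package implements the quenched-heterogeneity explanation:
   per-molecule binding free energies ΔG drawn from a normal distribution
   N(μ, σ²) broaden the ensemble-averaged isotherm, and the width σ can be
   inferred from the observed (n_H, K_1/2).

## What the library computes

| module | analysis |
|---|---|
| `hydro` | D = D₀(1+aC) fits, Stokes–Einstein R_h = k_B·T/(6πη(T)D₀), the empirical disordered-chain R_G↔R_h conversion, Flory scaling R_G = ρ₀N^ν |
| `calorimetry` | absolute molar heat capacity from DSC concentration series (displaced-buffer regression), folded/unfolded baselines, excess enthalpy fluctuations δH² = RT²·Cp_exc, and the variable-barrier (Landau) model: G₀(H) = −2β(H/α)² + \|β\|(H/α)⁴ with asymmetric lobes α₁+α₂ = Σα, f = min/max |
| `melts` | independent two-state U_E↔U_C fits per spectroscopic probe (van't Hoff ΔG = ΔH(1−T/T_m), linear baselines) and uncentered SVD of wavelength×temperature emission matrices |
| `binding` | Hill fits, deterministic Gauss–Hermite / Monte-Carlo ensemble isotherms over Gaussian ΔG distributions, a midpoint-slope n_H oracle (4·E[f(1−f)]), and σ inference by root finding |
| `synthgen` | seeded synthetic instrument data that each analysis inverts exactly at zero noise |
| `io`, `cli` | CSV interchange formats and a `cytrcollapse` command with `synth`, `dls`, `dsc`, `vbfit`, `bind`, `infer-sigma`, `melt`, `svd` subcommands |

## Worked example

Infer the binding-free-energy distribution width from an observed Hill
coefficient:

```python
from cytrcollapse import binding

model = binding.infer_sigma(target_nH=0.60, target_Khalf=23e-6, T=278.0)
print(round(model.sigma, 2), round(model.mu_dG, 2))
# 5.07 -24.68
```

A Hill coefficient of 0.60 with a 23 μM midpoint at 278 K requires a
σ ≈ 5.1 kJ mol⁻¹ spread of per-molecule binding free energies around
μ ≈ −24.7 kJ mol⁻¹ — more than twice thermal energy, i.e. substantial
molecule-to-molecule binding heterogeneity.

The numbered drivers under `analysis/` run the full story on synthetic
data (`python analysis/01_generate_datasets.py`, then 02–05 in order) and
write their tables under `results/`. For example, `02_chain_dimensions.py`
prints:

```
R_h contracts 24.2 -> 17.0 A over 283-333 K
R_G spans 25.9 -> 12.2 A (coil -> globule)
theta-state expectation 2.2*N^0.5 = 17.9 A (coil limit 27.2 A, globule limit 8.9 A)
collapsed state sits 11.6% above the folded-state radius of 15 A
```

i.e. the chain collapses from coil to globule dimensions, crossing the
ideal-chain expectation near the fluctuation maximum, and the final
globule is only ~12% larger than the folded DNA-bound state.

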
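# Methods

This note records the models implemented in `cytrcollapse`, the default
parameters and why they were chosen, the numerical choices that matter,
and what the synthetic-data generators do and do not emulate.

## Hydrodynamics (`hydro`)

Diffusion coefficients measured at finite protein concentration are
extrapolated to infinite dilution with the linear non-ideality model
D = D₀(1 + aC), fitted by ordinary least squares in (intercept, slope).
A single-concentration series degenerates to D₀ = D with a warning.

The Stokes–Einstein relation R_h = k_B·T/(6πη(T)D₀) uses
k_B = 1.380649×10⁻²³ J K⁻¹ and the empirical Vogel-type water viscosity
η(T) = 2.414×10⁻⁵ · 10^{247.8/(T−140)} Pa·s (valid 273–373 K, ~1% of
steam-table values; isolated in one function so another correlation can be
substituted). When both D₀ and the lowest-concentration D are available,
the pipeline defaults to D₀ — the less biased estimator — and exposes the
alternative via `hydro_pipeline(use="lowest")`.

R_G↔R_h interconversion for disordered chains uses the published
empirical ratio α = R_G/R_h, linear in R_G between the globule and coil
size-scaling limits:

    α(R_G, N) = a1·(R_G − a2·N^0.33)/(N^0.60 − N^0.33) + a3,

with a1 = 0.216 Å⁻¹, a2 = 4.06 Å, a3 = 0.821 (exponents are the literal
calibration constants, not 1/3 and 3/5). The forward map R_G → R_h is
strictly increasing over the physical bracket [2, 5·N^0.6] Å, so the
inverse is obtained by bracketed Brent root finding (xtol 10⁻¹²). For the
66-residue chain this maps R_h = 24 Å → R_G ≈ 25.4 Å and
R_h = 17 Å → R_G ≈ 12.2 Å. Flory scaling R_G = ρ₀N^ν is evaluated
literally; exponents outside [1/3, 3/5] are allowed with a warning.

## Calorimetry (`calorimetry`)

**Absolute heat capacity.** Apparent (buffer-displaced) heat capacities
of a cell of volume V (default 0.137 mL, a capillary-cell instrument) at
protein masses m obey ΔCp_app = m·(c_p − v̄·ρ_w·c_p,w). Regressing
ΔCp_app against m at each temperature and adding back the displaced-water
term v̄·ρ_w(T)·c_p,w(T) (partial specific volume v̄ = 0.73 mL g⁻¹ default;
Kell density and steam-table specific-heat correlations) yields the
absolute specific heat, scaled to molar units by the molar mass.
Thermograms on different grids are interpolated onto their overlap with a
warning; extrapolation is refused.

**Baselines.** The folded baseline is linear in temperature,
1.25 J g⁻¹ K⁻¹ at 298 K with slope 5×10⁻³ J g⁻¹ K⁻² — typical folded-
protein values. The unfolded baseline is a composition-weighted sum of
per-residue unfolded-state heat capacities interpolated in temperature
from an editable package data table
(`data/unfolded_residue_cp.csv`); the shipped coefficients are an
approximate transcription of the standard additive scheme and are meant to
be replaced with sequence-specific literature values when precision
matters. No quantitative result in the package depends on their exact
values. The excess heat capacity subtracts the *folded* baseline (the
choice of native reference is a documented assumption), and the
fluctuation curve is δH²(T) = R·T²·Cp_exc(T) with
R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹.

**Variable-barrier (Landau) model.** Enthalpy H is the order parameter of
the asymmetric quartic free-energy functional at the characteristic
temperature T₀:

    G₀(H) = −2β(H/α)² + |β|(H/α)⁴,  α = α₁ (H<0) or α₂ (H≥0),
    α₁ + α₂ = Σα,  f = min(α₁,α₂)/max(α₁,α₂),

with the larger lobe on the high-enthalpy side by default (matching
positively skewed densities; switchable). β < 0 gives a single-minimum
(downhill) profile, β > 0 a barrier of height β. The functional defines a
microcanonical entropy S₀(H) = (H − G₀(H))/T₀, and densities at any
temperature follow the Boltzmann form

    P(H, T) ∝ exp[S₀(H)/R − H/(R·T)],

which reduces to exp[−G₀(H)/(R·T₀)] at T = T₀. This form was chosen over
a naive "tilt the free energy and divide by RT" construction because it
makes the model thermodynamically self-consistent: the excess heat
capacity computed as the enthalpy variance, Cp_exc = var(H)/(R·T²),
*exactly* equals d⟨H⟩/dT (fluctuation–dissipation), and the package tests
both code paths against each other. The H grid uses 2001 points spanning
±2.5·Σα, auto-widened once (×2) if more than 10⁻⁶ probability mass sits in
the edge bins, then erroring.

**Fitting.** `vb_fit` minimizes the residual of Cp_exc(T) with
`scipy.optimize.least_squares`, Σα log-parameterized, f bounded in
(0, 1], from the supplied initialization plus seeded multistart
perturbations of ±20%. On the noiseless forward curve from
(Σα, β, T₀, f) = (1554.9 kJ mol⁻¹, −173.7 kJ mol⁻¹, 291.7 K, 0.535) all
five starts recover the generating parameters to machine precision; the
sign/side convention of f is degenerate with the sign of the H axis, so
round-trip identifiability holds under any fixed convention.

With these parameters the model fluctuation curve δH²(T) peaks near
322 K. The experimentally derived fluctuation maximum of the real protein
(~312 K) is a feature of the measured absolute heat capacity, which the
synthetic generator does not attempt to reproduce — passing round-trip
tests demonstrate correctness of the extraction pipeline, not agreement
with the unavailable instrument data.

## Melts and SVD (`melts`)

Each probe is fitted independently to the two-state mixture
signal(T) = [S_E + S_C·K]/(1+K), K = exp(−ΔG/RT),
ΔG = ΔH_vH(1 − T/T_m), with linear baselines parameterized about T_m and
ΔCp fixed at 0 (van't Hoff form; a nonzero ΔCp is accepted as an option).
Initialization takes the steepest detrended point plus grid quartiles as
midpoint candidates and keeps the lowest-cost local fit; a fit whose
amplitude is below three noise standard deviations (noise estimated from
second differences) or whose midpoint leaves the measured range raises a
"no transition" error. At a signal-to-noise ratio of 20 the single-melt
precision of T_m is about 1 K (1σ); the replicate test therefore checks
that the *mean* over 100 seeded replicates recovers T_m within 1 K and
ΔH_vH within 10% (estimator bias, not per-curve scatter).

Spectral matrices are decomposed by uncentered SVD (the first component
then reports the average spectrum); basis spectra are sign-oriented to
non-negative mean, amplitudes carry the singular values, and missing cells
are an error rather than imputed.

## Binding (`binding`)

Per-molecule 1:1 binding with Kd = exp(ΔG/RT)·1 M, ΔG ~ N(μ, σ²)
(quenched: one draw per molecule for the whole titration). The bulk
isotherm is the ensemble mean of f = L/(L+Kd), computed either by
Monte-Carlo over n molecules (default 1000) or deterministically by
80-node Gauss–Hermite quadrature; the two agree within sampling error and
σ = 0 reduces both to the single-site curve. Total titrant is used as
free concentration: the fitted midpoints (9–23 μM) sit two orders of
magnitude above the 300 nM labelled-DNA trace, so depletion is negligible.

Hill fits use uniform-weight least squares with K_1/2 log-parameterized;
anisotropy amplitudes (r_free, r_bound) are fitted jointly when the signal
is raw anisotropy. The default titration grid is 24 log-spaced points over
1 nM–100 μM (the experimental span); the fitted n_H depends weakly on the
grid, so the grid is part of a result's provenance. An independent
midpoint-slope oracle computes n_H = 4·E[f(1−f)] at L = median Kd — the
analytic log-slope of the bulk isotherm at its midpoint — and sits
~0.03 below the full-curve fit because the fit averages the slightly
steeper wings.

σ inference bisects the strictly decreasing map σ → fitted n_H over
[0, 12] kJ mol⁻¹ (tolerance 0.01 kJ mol⁻¹), then sets μ = RT·ln(K_1/2/1 M)
so the bulk midpoint matches — matching n_H by σ and K_1/2 by μ
sequentially, which is exact because the fitted midpoint of the quadrature
ensemble equals the median Kd (log-symmetry) to within 2%.

## Synthetic data (`synthgen`)

Generators are the exact forward models of the analysis stages, so every
analysis inverts its generator to machine precision at zero noise; this is
the backbone of the test suite. Defaults encode the study conditions:
radii 24 → 16.8 Å mixed through a two-state equilibrium with T_c = 312 K,
DLS concentrations 0.45/0.90/1.35 mg mL⁻¹ at 283–333 K every 10 K, DSC
loadings spanning 52–110 μM, probe midpoints 301/307/312 K, titrations
over 1 nM–100 μM, and anisotropy amplitudes r_free = 0.06,
r_bound = 0.16. Values the source experiments do not constrain are package
defaults chosen at realistic magnitudes and documented as assumptions:
the collapse van't Hoff enthalpy dH_c = 150 kJ mol⁻¹ (a gradual,
IDP-like transition), DLS non-ideality a = 0.01 mL mg⁻¹, and additive
Gaussian noise with per-instrument scales (no noise magnitudes were
reported; the additive-Gaussian choice matches the least-squares fitting
downstream). All randomness in a generator call flows from a single
integer seed; identical parameters and seed give bitwise-identical data.

What the generators deliberately do **not** emulate: raw DLS
autocorrelation functions and DSC power traces (generation starts at
derived per-scan quantities), instrument baseline drift, scan-rate
effects, temperature-dependent noise, and the detailed shape of the real
CytR thermogram (see the δH² peak note above). Passing tests therefore
validate the estimators and their inverses, not instrument physics.

## Known limitations

- The R_G↔R_h conversion constants are a global IDP calibration; applied
  to the 24 Å coil state they give 25.4 Å, slightly under the ~26 Å
  obtained when rounding to the nearest Ångström.
- The unfolded-baseline coefficient table is approximate; swap in
  sequence-specific literature values for quantitative baseline work.
- Hill-fit standard errors come from the least-squares covariance and
  ignore correlated residuals.
- The two-state melt model assumes linear baselines and ΔCp = 0; strongly
  curved baselines require passing an explicit ΔCp or trimming the range.
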
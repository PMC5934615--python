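"""Absolute heat capacity extraction and the variable-barrier model."""

import numpy as np
import pytest

from cytrcollapse import calorimetry as cal
from cytrcollapse import synthgen

MOLAR_MASS = 7500.0


class TestAbsoluteCp:
    def test_round_trips_generator_exactly(self, vb_params, dsc_T_grid):
        thermos = synthgen.gen_thermograms(vb_params, T_grid=dsc_T_grid)
        curve = cal.absolute_cp(thermos, molar_mass=MOLAR_MASS)
        truth = cal.folded_baseline(dsc_T_grid, MOLAR_MASS) + cal.vb_cp(
            vb_params, dsc_T_grid
        )
        assert np.max(np.abs(curve.cp_abs - truth) / truth) < 1e-9

    def test_zero_slope_gives_displaced_buffer_value(self):
        T = np.array([290.0, 300.0, 310.0])
        thermos = [
            cal.CpThermogram(T=T, cp_app=np.zeros(3), concentration_uM=c,
                             scan_id=str(c))
            for c in (52.0, 110.0)
        ]
        curve = cal.absolute_cp(thermos, molar_mass=MOLAR_MASS)
        expected = (
            0.73 * cal.water_density(T) * cal.water_specific_heat(T)
            * MOLAR_MASS
        )
        np.testing.assert_allclose(curve.cp_abs, expected, rtol=1e-12)

    def test_absolute_curve_bounded_by_baselines(self, vb_params, dsc_T_grid):
        thermos = synthgen.gen_thermograms(vb_params, T_grid=dsc_T_grid)
        curve = cal.absolute_cp(thermos, molar_mass=MOLAR_MASS)
        assert np.all(curve.cp_abs > curve.baseline_folded)
        assert np.all(curve.cp_abs < curve.baseline_unfolded)

    def test_mismatched_grids_regridded_with_warning(self, vb_params):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            t_lo = synthgen.gen_thermograms(
                vb_params, concentrations_uM=[52.0],
                T_grid=np.arange(278.0, 370.0, 1.0))[0]
            t_hi = synthgen.gen_thermograms(
                vb_params, concentrations_uM=[110.0],
                T_grid=np.arange(280.0, 374.0, 1.0))[0]
        with pytest.warns(UserWarning, match="regridding"):
            curve = cal.absolute_cp([t_lo, t_hi], molar_mass=MOLAR_MASS)
        assert curve.T[0] >= 280.0 and curve.T[-1] <= 369.0

    def test_single_concentration_rejected(self, vb_params, dsc_T_grid):
        thermos = synthgen.gen_thermograms(
            vb_params, concentrations_uM=[80.0, 80.0], T_grid=dsc_T_grid
        )
        with pytest.raises(ValueError, match="distinct concentrations"):
            cal.absolute_cp(thermos, molar_mass=MOLAR_MASS)


class TestBaselines:
    def test_single_residue_composition_identity(self):
        T = np.array([298.15])
        one = cal.unfolded_baseline(T, {"G": 1})
        many = cal.unfolded_baseline(T, {"G": 66})
        assert many[0] == pytest.approx(66 * one[0], rel=1e-12)

    def test_folded_baseline_is_linear(self):
        T = np.linspace(278.0, 373.0, 40)
        b = cal.folded_baseline(T, MOLAR_MASS)
        assert np.allclose(np.diff(b, 2), 0.0, atol=1e-9)

    def test_unfolded_exceeds_folded_at_298(self):
        T = np.array([298.15])
        comp = cal.uniform_composition(66)
        assert cal.unfolded_baseline(T, comp)[0] > cal.folded_baseline(
            T, 66 * 110.0
        )[0]

    def test_unknown_residue_code_named_in_error(self):
        with pytest.raises(KeyError, match="X"):
            cal.unfolded_baseline(np.array([298.0]), {"X": 3})


class TestExcessFluctuations:
    def test_zero_excess_gives_zero_variance(self):
        T = np.linspace(278.0, 373.0, 10)
        assert np.all(cal.excess_fluctuations(T, np.zeros(10)) == 0.0)

    def test_matches_density_variance(self, vb_params):
        # dH2 = R*T^2*Cp_excess must equal the second central moment of the
        # enthalpy density: two code paths, one thermodynamic identity
        T = np.linspace(280.0, 370.0, 7)
        cp = cal.vb_cp(vb_params, T)
        dh2 = cal.excess_fluctuations(T, cp)
        var = np.array([cal.vb_density(vb_params, t).variance() for t in T])
        np.testing.assert_allclose(dh2, var, rtol=1e-6)

    def test_fluctuation_curve_single_peaked(self, vb_params, dsc_T_grid):
        dh2 = cal.excess_fluctuations(
            dsc_T_grid, cal.vb_cp(vb_params, dsc_T_grid)
        )
        peaks = (dh2[1:-1] > dh2[:-2]) & (dh2[1:-1] > dh2[2:])
        assert peaks.sum() == 1


class TestVBDensity:
    def test_symmetric_at_T0_when_f_is_one(self):
        params = cal.VBParams(sum_alpha=1500.0, beta=-170.0, T0=300.0, f=1.0)
        dens = cal.vb_density(params, 300.0)
        # mode at zero and mirror-symmetric density
        assert abs(dens.H[np.argmax(dens.P)]) <= dens.H[1] - dens.H[0]
        np.testing.assert_allclose(dens.P, dens.P[::-1], rtol=1e-10)

    def test_unimodal_at_all_temperatures(self, vb_params, dsc_T_grid):
        for T in dsc_T_grid:
            assert cal.vb_density(vb_params, T).n_modes() == 1

    def test_normalized_for_random_parameter_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            params = cal.VBParams(
                sum_alpha=float(rng.uniform(200, 4000)),
                beta=float(rng.uniform(-400, 100)),
                T0=float(rng.uniform(270, 330)),
                f=float(rng.uniform(0.2, 1.0)),
            )
            dens = cal.vb_density(params, float(rng.uniform(278, 373)))
            assert np.trapezoid(dens.P, dens.H) == pytest.approx(1.0, abs=1e-6)

    def test_too_narrow_grid_widens_then_errors(self):
        params = cal.VBParams(
            sum_alpha=1500.0, beta=-170.0, T0=300.0, f=1.0, span_mult=0.01
        )
        with pytest.raises(ValueError, match="grid too narrow"):
            cal.vb_density(params, 300.0)


class TestVBCp:
    def test_fluctuation_dissipation_against_dHdT(self, vb_params):
        # independent oracle: Cp must equal the temperature derivative of
        # the mean enthalpy (central differences, 0.1 K step)
        T = np.linspace(285.0, 365.0, 9)
        h = 0.1
        dHdT = (
            cal.vb_mean_enthalpy(vb_params, T + h)
            - cal.vb_mean_enthalpy(vb_params, T - h)
        ) / (2 * h)
        cp = cal.vb_cp(vb_params, T)
        np.testing.assert_allclose(cp, dHdT, rtol=1e-4)

    def test_enthalpy_scale_doubles_at_matched_reduced_temperature(self):
        base = cal.VBParams(sum_alpha=1554.9, beta=-173.7, T0=291.7, f=0.535)
        doubled = cal.VBParams(
            sum_alpha=2 * 1554.9, beta=-173.7, T0=291.7, f=0.535
        )
        T = 310.0
        # H -> 2H maps the doubled system at T onto the base system at T'
        # with 1/T' = 2/T - 1/T0
        T_match = 1.0 / (2.0 / T - 1.0 / base.T0)
        h2 = cal.vb_mean_enthalpy(doubled, [T])[0]
        h1 = cal.vb_mean_enthalpy(base, [T_match])[0]
        assert h2 == pytest.approx(2 * h1, rel=1e-6)

    def test_nonnegative_everywhere(self, vb_params, dsc_T_grid):
        assert np.all(cal.vb_cp(vb_params, dsc_T_grid) >= 0.0)


class TestVBFit:
    def test_round_trip_recovers_parameters(self, vb_params, dsc_T_grid):
        y = cal.vb_cp(vb_params, dsc_T_grid)
        res = cal.vb_fit(dsc_T_grid, y, init=vb_params, multistart=5, seed=1)
        assert res.params.T0 == pytest.approx(291.7, abs=0.2)
        assert res.params.f == pytest.approx(0.535, abs=0.01)
        assert res.params.sum_alpha == pytest.approx(1554.9, rel=1e-3)
        assert res.params.beta == pytest.approx(-173.7, rel=1e-3)
        # most perturbed starts must land on the same optimum at zero noise
        good = [d for d in res.per_start
                if d["success"] and d["cost"] < 1e-6]
        assert len(good) >= 3

    def test_grid_decimation_leaves_parameters_unchanged(
        self, vb_params, dsc_T_grid
    ):
        y = cal.vb_cp(vb_params, dsc_T_grid)
        full = cal.vb_fit(dsc_T_grid, y, init=vb_params, multistart=1)
        half = cal.vb_fit(
            dsc_T_grid[::2], y[::2], init=vb_params, multistart=1
        )
        for attr in ("sum_alpha", "beta", "T0", "f"):
            a, b = getattr(full.params, attr), getattr(half.params, attr)
            assert abs(a - b) / abs(a) < 1e-3
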
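"""Hill analysis and the quenched binding-heterogeneity ensemble."""

import numpy as np
import pytest

from cytrcollapse import binding as b


GRID = b.default_titration_grid()


def quad_model(khalf, sigma, T):
    return b.HeterogeneityModel.from_median_kd(khalf, sigma, T)


class TestSingleSite:
    def test_midpoint_and_limits(self):
        assert b.single_site_fraction(1e-5, 1e-5) == pytest.approx(0.5)
        assert b.single_site_fraction(1e-12, 1e-5) < 1e-6
        assert b.single_site_fraction(10.0, 1e-5) > 0.999

    def test_hill_fit_of_single_site_curve_gives_unity(self):
        curve = b.single_site_fraction(GRID, 1e-5)
        fit = b.hill_fit(b.BindingIsotherm(T=298.0, ligand=GRID, signal=curve))
        assert fit.n_H == pytest.approx(1.0, abs=1e-6)
        assert fit.K_half == pytest.approx(1e-5, rel=1e-6)


class TestEnsembleIsotherm:
    def test_sigma_zero_degenerates_to_single_site(self):
        m = quad_model(1e-5, 0.0, 298.0)
        np.testing.assert_allclose(
            b.ensemble_isotherm(m, GRID),
            b.single_site_fraction(GRID, 1e-5),
            rtol=1e-12,
        )

    def test_half_bound_at_median_kd(self):
        m = quad_model(2e-5, 5.0, 298.0)
        f = b.ensemble_isotherm(m, np.array([1e-6, 2e-5, 1e-3]))
        # log-symmetry of the Gaussian about its median dissociation constant
        assert f[1] == pytest.approx(0.5, abs=1e-10)

    def test_monte_carlo_matches_quadrature_within_sampling_error(self):
        n = 1000
        mc_model = b.HeterogeneityModel.from_median_kd(
            23e-6, 5.1, 278.0, mode="monte-carlo", n_molecules=n, seed=7
        )
        q = b.ensemble_isotherm(quad_model(23e-6, 5.1, 278.0), GRID)
        mc = b.ensemble_isotherm(mc_model, GRID)
        # per-point sampling SE of a mean of n bounded fractions
        se = 0.5 / np.sqrt(n)
        assert np.max(np.abs(mc - q)) < 3 * se

    def test_bad_grid_rejected(self):
        m = quad_model(1e-5, 2.0, 298.0)
        with pytest.raises(ValueError):
            b.ensemble_isotherm(m, np.array([1e-5, 1e-6]))


class TestHillFit:
    def test_exact_hill_data_recovered(self):
        true = b.HillFit(K_half=1e-5, n_H=1.0)
        fit = b.hill_fit(
            b.BindingIsotherm(T=298.0, ligand=GRID, signal=true.fraction(GRID))
        )
        assert fit.K_half == pytest.approx(1e-5, rel=1e-8)
        assert fit.n_H == pytest.approx(1.0, abs=1e-8)

    def test_flat_signal_raises(self):
        # signal range below three noise standard deviations: nothing to fit
        flat = np.full(GRID.size, 0.08)
        with pytest.raises(ValueError, match="no binding"):
            b.hill_fit(
                b.BindingIsotherm(T=298.0, ligand=GRID, signal=flat,
                                  signal_kind="anisotropy")
            )

    def test_anisotropy_amplitudes_fitted_jointly(self):
        f = b.HillFit(K_half=1e-5, n_H=0.8).fraction(GRID)
        r = b.anisotropy_from_fraction(f, 0.06, 0.16)
        fit = b.hill_fit(
            b.BindingIsotherm(T=298.0, ligand=GRID, signal=r,
                              signal_kind="anisotropy")
        )
        assert fit.r_free == pytest.approx(0.06, abs=1e-8)
        assert fit.r_bound == pytest.approx(0.16, abs=1e-8)
        assert fit.n_H == pytest.approx(0.8, abs=1e-8)

    @pytest.mark.parametrize(
        "sigma,T,khalf,nh_expected",
        [(5.1, 278.0, 23e-6, 0.60), (4.5, 308.0, 9e-6, 0.69)],
    )
    def test_heterogeneous_ensembles_give_observed_hill_coefficients(
        self, sigma, T, khalf, nh_expected
    ):
        curve = b.ensemble_isotherm(quad_model(khalf, sigma, T), GRID)
        fit = b.hill_fit(b.BindingIsotherm(T=T, ligand=GRID, signal=curve))
        assert fit.n_H == pytest.approx(nh_expected, abs=0.05)

    def test_fitted_midpoint_equals_median_kd_within_two_percent(self):
        m = quad_model(23e-6, 5.1, 278.0)
        curve = b.ensemble_isotherm(m, GRID)
        fit = b.hill_fit(b.BindingIsotherm(T=278.0, ligand=GRID, signal=curve))
        assert fit.K_half == pytest.approx(m.median_Kd, rel=0.02)


class TestMidpointSlope:
    def test_homogeneous_limit_is_exactly_one(self):
        assert b.midpoint_slope_nH(quad_model(1e-5, 0.0, 298.0)) == 1.0

    def test_matches_quadrature_oracle_and_full_fit(self):
        m = quad_model(23e-6, 5.1, 278.0)
        slope_nh = b.midpoint_slope_nH(m)
        assert slope_nh == pytest.approx(0.57, abs=0.01)
        curve = b.ensemble_isotherm(m, GRID)
        fit = b.hill_fit(b.BindingIsotherm(T=278.0, ligand=GRID, signal=curve))
        assert abs(slope_nh - fit.n_H) < 0.05

    def test_strictly_decreasing_in_sigma(self):
        sigmas = np.linspace(0.0, 8.0, 17)
        vals = [
            b.midpoint_slope_nH(quad_model(1e-5, s, 298.0)) for s in sigmas
        ]
        assert np.all(np.diff(vals) < 0)

    def test_fitted_nH_invariant_under_log_concentration_shift(self):
        # shifting mu and the titration window together must not change n_H
        shift = 3.0
        m1 = quad_model(1e-5, 3.0, 298.0)
        m2 = quad_model(1e-5 * shift, 3.0, 298.0)
        f1 = b.hill_fit(b.BindingIsotherm(
            T=298.0, ligand=GRID, signal=b.ensemble_isotherm(m1, GRID)))
        f2 = b.hill_fit(b.BindingIsotherm(
            T=298.0, ligand=GRID * shift,
            signal=b.ensemble_isotherm(m2, GRID * shift)))
        assert abs(f1.n_H - f2.n_H) < 1e-3


class TestInferSigma:
    @pytest.mark.parametrize("sigma", [2.0, 3.0, 4.5, 5.1])
    def test_identity_on_sigma(self, sigma):
        # forward: ensemble + Hill fit; inverse must return the same width
        m = quad_model(23e-6, sigma, 278.0)
        curve = b.ensemble_isotherm(m, GRID)
        fit = b.hill_fit(b.BindingIsotherm(T=278.0, ligand=GRID, signal=curve))
        inferred = b.infer_sigma(fit.n_H, fit.K_half, 278.0, grid=GRID)
        assert inferred.sigma == pytest.approx(sigma, abs=0.1)

    def test_unit_target_gives_zero_width(self):
        m = b.infer_sigma(1.0, 23e-6, 278.0)
        assert m.sigma == 0.0
        assert m.median_Kd == pytest.approx(23e-6, rel=1e-9)

    def test_target_above_one_rejected(self):
        with pytest.raises(ValueError):
            b.infer_sigma(1.2, 23e-6, 278.0)

    def test_unreachable_target_reports_missing_bracket(self):
        with pytest.raises(ValueError, match="no bracket"):
            b.infer_sigma(0.2, 23e-6, 278.0, sigma_max=3.0)


class TestAnisotropy:
    def test_endpoints_and_linearity(self):
        f = np.array([0.0, 0.5, 1.0])
        r = b.anisotropy_from_fraction(f, 0.06, 0.16)
        assert r[0] == 0.06 and r[2] == 0.16
        assert r[1] == pytest.approx((r[0] + r[2]) / 2)

    def test_inverted_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            b.anisotropy_from_fraction(np.array([0.5]), 0.16, 0.06)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            b.anisotropy_from_fraction(np.array([1.5]), 0.06, 0.16)
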
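"""Leaf-level optimality and FvCB kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eeogpp as e
from eeogpp.photo import assimilation_rates


# tabulated dynamic viscosity of liquid water, mPa s (CRC handbook values)
WATER_VISCOSITY_TABLE = {5.0: 1.5182, 25.0: 0.8900, 35.0: 0.7191}


class TestKinetics:
    def test_eta_star_unity_at_reference(self):
        assert e.eta_star(25.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("ta,mu", WATER_VISCOSITY_TABLE.items())
    def test_viscosity_matches_tabulated_within_1pct(self, ta, mu):
        assert e.water_viscosity(ta + 273.15) * 1e3 == pytest.approx(mu, rel=0.01)

    def test_eta_star_monotone_decreasing_in_temperature(self):
        assert e.eta_star(35.0) < 1.0 < e.eta_star(5.0)

    def test_arrhenius_kinetics_increase_with_temperature(self):
        k25 = e.kinetics_at(25.0, 101325.0)
        k35 = e.kinetics_at(35.0, 101325.0)
        assert k35.gamma_star > k25.gamma_star
        assert k35.K > k25.K

    def test_capacities_scale_from_reference(self):
        kin = e.kinetics_at(25.0, 101325.0, vcmax25=60.0, jmax25=120.0)
        assert kin.vcmax == pytest.approx(60.0)
        assert kin.jmax == pytest.approx(120.0)

    def test_out_of_range_temperature_names_field(self):
        with pytest.raises(e.DomainError, match="ta"):
            e.kinetics_at(80.0, 101325.0)


class TestOptimalChi:
    def test_high_vpd_limit_approaches_gammastar_over_ca(self):
        kin = e.kinetics_at(25.0, 101325.0)
        chi, _ = e.optimal_chi_values(40.0, 1e16, kin.K, kin.gamma_star,
                                      kin.eta_star, 146.0)
        assert chi == pytest.approx(kin.gamma_star / 40.0, rel=1e-4)

    def test_ci_doubles_with_ca_when_gammastar_negligible(self):
        kin = e.kinetics_at(25.0, 101325.0)
        # make the Gamma*/ca correction negligible by shrinking Gamma*
        gs = 1e-9
        _, ci1 = e.optimal_chi_values(40.0, 800.0, kin.K, gs, kin.eta_star, 146.0)
        _, ci2 = e.optimal_chi_values(80.0, 800.0, kin.K, gs, kin.eta_star, 146.0)
        assert ci2 == pytest.approx(2.0 * ci1, rel=1e-10)

    def test_chi_decreasing_in_vpd_increasing_in_beta(self):
        kin = e.kinetics_at(20.0, 101325.0)
        d = np.array([200.0, 800.0, 2400.0])
        chi, _ = e.optimal_chi_values(40.0, d, kin.K, kin.gamma_star,
                                      kin.eta_star, 146.0)
        assert np.all(np.diff(chi) < 0)
        betas = np.array([30.0, 146.0, 500.0])
        chib, _ = e.optimal_chi_values(40.0, 800.0, kin.K, kin.gamma_star,
                                       kin.eta_star, betas)
        assert np.all(np.diff(chib) > 0)

    def test_closed_form_is_brute_force_cost_minimum(self):
        """Least-cost chi equals the dense-grid argmin of the unit cost."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            kin = e.kinetics_at(rng.uniform(2, 35), rng.uniform(9e4, 1.02e5))
            ca = rng.uniform(35.0, 45.0)
            d = rng.uniform(50.0, 3000.0)
            beta = rng.uniform(20.0, 400.0)
            _, ci = e.optimal_chi_values(ca, d, kin.K, kin.gamma_star,
                                         kin.eta_star, beta)
            grid = np.linspace(kin.gamma_star * 1.001, ca * 0.999, 4000)
            cost = e.chi_cost(grid, ca, d, kin.K, kin.gamma_star, kin.eta_star, beta)
            j = int(np.argmin(cost))
            fine = np.linspace(grid[max(j - 2, 0)], grid[min(j + 2, 3999)], 4000)
            cost_f = e.chi_cost(fine, ca, d, kin.K, kin.gamma_star, kin.eta_star, beta)
            ci_brute = fine[np.argmin(cost_f)]
            assert ci == pytest.approx(ci_brute, rel=1e-4)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(ta=st.floats(0.0, 40.0), d=st.floats(10.0, 5000.0),
           ca=st.floats(30.0, 50.0), beta=st.floats(5.0, 800.0),
           pa=st.floats(7e4, 1.05e5))
    def test_chi_bounds_hold_everywhere(self, ta, d, ca, beta, pa):
        """For any admissible environment the optimum satisfies
        Gamma*/ca < chi < 1 and ci < ca (a positive Fick gradient)."""
        kin = e.kinetics_at(ta, pa)
        chi, ci = e.optimal_chi_values(ca, d, kin.K, kin.gamma_star,
                                       kin.eta_star, beta)
        assert kin.gamma_star / ca < chi < 1.0
        assert 0.0 < ci < ca

    def test_nonpositive_beta_raises(self):
        kin = e.kinetics_at(25.0, 101325.0)
        with pytest.raises(e.ParameterError):
            e.optimal_chi_values(40.0, 800.0, kin.K, kin.gamma_star,
                                 kin.eta_star, -1.0)


class TestMwueBeta:
    def test_logistic_saturates_at_high_swc(self):
        b = e.mwue_beta(0.5, 146.0)
        assert b == pytest.approx(146.0, rel=0.01)

    def test_monotone_nondecreasing_in_swc(self):
        swc = np.linspace(0.0, 0.6, 40)
        b = e.mwue_beta(swc, 146.0)
        assert np.all(np.diff(b) >= 0)

    def test_gpp_monotone_in_swc_sweep(self, site_and_forcing):
        """Drier soil -> lower mWUE cost ratio -> lower chi -> lower GPP."""
        sf, site = site_and_forcing
        met = sf.met.mean()
        swc = np.arange(0.05, 0.46, 0.05)
        m = e.MeteoMonth(ta=np.full_like(swc, float(met.ta)),
                         swin=np.full_like(swc, float(met.swin)),
                         pa=np.full_like(swc, float(met.pa)),
                         qa=np.full_like(swc, float(met.qa)), swc=swc,
                         ca=np.full_like(swc, float(met.ca)),
                         lai=np.full_like(swc, float(met.lai)),
                         month=np.full(swc.shape, int(met.month)),
                         daytime_seconds=np.full_like(swc, float(met.daytime_seconds)))
        gpp = e.monthly_gpp(m, site).gpp
        assert np.all(np.diff(gpp) >= -1e-12)


class TestAssimilation:
    def test_zero_at_compensation_point(self):
        kin = e.kinetics_at(25.0, 101325.0, 60.0, 120.0)
        a, _ = e.assimilate_c3(kin.gamma_star, 800.0, kin)
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_dark_is_rubp_limited_and_nonpositive(self):
        kin = e.kinetics_at(25.0, 101325.0, 60.0, 120.0)
        a, lim = e.assimilate_c3(25.0, 0.0, kin)
        assert a <= 0
        assert lim == e.RUBP

    def test_min_of_independent_branch_evaluations(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            kin = e.kinetics_at(rng.uniform(5, 35), 101325.0,
                                rng.uniform(20, 120), rng.uniform(40, 240))
            ci = rng.uniform(5.0, 35.0)
            iabs = rng.uniform(0.0, 2000.0)
            a, lim = e.assimilate_c3(ci, iabs, kin)
            ac = kin.vcmax * (ci - kin.gamma_star) / (ci + kin.K)
            j = e.electron_transport(iabs, kin.jmax)
            aj = (j / 4.0) * (ci - kin.gamma_star) / (ci + 2 * kin.gamma_star)
            assert a == pytest.approx(min(ac, aj), rel=1e-12)
            assert lim == (e.RUBISCO if ac <= aj else e.RUBP)

    def test_c4_saturates_in_ci(self):
        kin = e.kinetics_at(28.0, 101325.0, 40.0, 80.0)
        a1, _ = e.assimilate_c4(30.0, 1500.0, kin)
        a2, _ = e.assimilate_c4(35.0, 1500.0, kin)  # +50 ppm at ~1e5 Pa
        assert abs(a2 - a1) < 0.01 * a1

    def test_c4_dark_nonpositive(self):
        kin = e.kinetics_at(28.0, 101325.0, 40.0, 80.0)
        a, _ = e.assimilate_c4(20.0, 0.0, kin)
        assert a <= 0


class TestStomatalG:
    def test_fick_identity_and_linearity(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0.0, 30.0, 50)
        ca_pp = rng.uniform(30.0, 45.0, 50)
        ci = ca_pp * rng.uniform(0.4, 0.9, 50)
        g = e.stomatal_g(a, ca_pp, ci)
        assert np.allclose(g * (ca_pp - ci), a, rtol=1e-12)
        assert np.allclose(e.stomatal_g(2 * a, ca_pp, ci), 2 * g, rtol=1e-12)

    def test_zero_assimilation_zero_conductance(self):
        assert e.stomatal_g(0.0, 40.0, 28.0) == 0.0

    def test_degenerate_gradient_raises(self):
        with pytest.raises(e.DomainError):
            e.stomatal_g(5.0, 30.0, 30.0)


class TestLeafState:
    def test_fick_consistency_across_random_environments(self, env_sweep):
        """Every solved leaf state satisfies A = g (ca - ci) to 1e-10."""
        kin = e.kinetics_at(env_sweep.ta, env_sweep.pa, 60.0, 110.0)
        iabs = env_sweep.swin * 0.45 * 4.57
        st = e.solve_leaf(env_sweep, kin, 146.0, iabs)
        resid = np.abs(st.A - st.g * (env_sweep.ca_pp - st.ci))
        assert np.all(resid / np.maximum(np.abs(st.A), 1e-12) < 1e-10)
        inside = (st.chi > kin.gamma_star / env_sweep.ca_pp) & (st.chi < 1)
        assert inside.all()

    def test_params_yaml_roundtrip(self, tmp_path):
        p = e.PhotoParams(phi_j=0.27)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        back = e.PhotoParams.from_yaml(path)
        assert back == p


class TestCoordination:
    def test_colimitation_residual_below_tolerance(self, site_and_forcing):
        sf, _ = site_and_forcing
        v25, j25, ref = e.coordinate_site(sf.met, 146.0)
        kin = e.kinetics_at(ref.ta, ref.pa, v25, j25)
        beta = e.mwue_beta(ref.swc, 146.0)
        _, ci = e.optimal_chi(ref, kin, beta)
        iabs = float(ref.swin) * 0.45 * 4.57
        ac, aj = assimilation_rates(ci, iabs, kin)
        assert abs(ac - aj) / ac < 1e-6

    def test_more_reference_light_more_rubisco(self, site_and_forcing):
        sf, _ = site_and_forcing
        ref = e.reference_environment(sf.met)
        iabs = float(ref.swin) * 0.45 * 4.57
        v_lo, _ = e.coordinate_capacity(ref, iabs, 146.0)
        v_hi, _ = e.coordinate_capacity(ref, 2 * iabs, 146.0)
        assert v_hi > v_lo

    def test_matches_bisection_oracle(self, site_and_forcing):
        """Independent bracketing bisection on the colimitation residual."""
        sf, _ = site_and_forcing
        ref = e.reference_environment(sf.met)
        iabs = float(ref.swin) * 0.45 * 4.57
        v25, j25 = e.coordinate_capacity(ref, iabs, 146.0)
        rjv = j25 / v25
        beta = e.mwue_beta(ref.swc, 146.0)

        def resid(v):
            kin = e.kinetics_at(ref.ta, ref.pa, v, rjv * v)
            _, ci = e.optimal_chi(ref, kin, beta)
            ac, aj = assimilation_rates(ci, iabs, kin)
            return float(ac - aj)

        lo, hi = 1e-3, 500.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if resid(lo) * resid(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert v25 == pytest.approx(0.5 * (lo + hi), abs=1e-8 * max(1.0, v25))

    def test_zero_light_raises_calibration_error(self, site_and_forcing):
        sf, _ = site_and_forcing
        ref = e.reference_environment(sf.met)
        with pytest.raises(e.CalibrationError):
            e.coordinate_capacity(ref, 0.0, 146.0)
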
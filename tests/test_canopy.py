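"""Canopy upscaling, monthly GPP chain, calibration, annual aggregation."""

import warnings

import numpy as np
import pytest

import eeogpp as e


class TestAbsorbedLight:
    def test_zero_lai_zero_absorption(self):
        assert e.absorbed_light(300.0, 0.0, 0.6) == 0.0

    def test_saturates_at_high_lai(self):
        full = 300.0 * 0.45 * 4.57
        assert e.absorbed_light(300.0, 50.0, 0.6) == pytest.approx(full, rel=1e-9)

    def test_marginal_light_gain_declines_with_lai(self):
        d = 1e-4
        g_low = (e.absorbed_light(300.0, 0.5 + d, 0.6)
                 - e.absorbed_light(300.0, 0.5 - d, 0.6)) / (2 * d)
        g_high = (e.absorbed_light(300.0, 6.0 + d, 0.6)
                  - e.absorbed_light(300.0, 6.0 - d, 0.6)) / (2 * d)
        assert g_high < 0.1 * g_low


class TestMonthlyGpp:
    def test_no_light_no_gpp(self, site_and_forcing):
        sf, site = site_and_forcing
        met = sf.met.replace(swin=np.zeros_like(sf.met.swin))
        res = e.monthly_gpp(met, site)
        assert np.all(res.gpp == 0.0)

    def test_co2_increment_raises_c3_gpp(self, site_and_forcing):
        sf, site = site_and_forcing
        g0 = e.monthly_gpp(sf.met, site).gpp
        g1 = e.monthly_gpp(sf.met.replace(ca=sf.met.ca + 1.0), site).gpp
        assert np.all(g1 > g0)

    def test_finite_difference_matches_analytic_beta(self, site_and_forcing):
        """The +-0.5 ppm difference quotient of the full model matches the
        analytic beta_CO2 to 1e-5 wherever the limitation branch is stable
        across the stencil; months straddling the Ac=Aj crossover have a
        branch-conditional derivative, checked by the pinned FD oracle."""
        sf, site = site_and_forcing
        dca = 0.5
        rp = e.monthly_gpp(sf.met.replace(ca=sf.met.ca + dca), site)
        rm = e.monthly_gpp(sf.met.replace(ca=sf.met.ca - dca), site)
        fd = (rp.gpp - rm.gpp) / (2 * dca)
        ana = e.partials(sf.met, site).d_ca
        stable = rp.limitation == rm.limitation
        assert stable.sum() >= 0.8 * stable.size
        assert np.allclose(ana[stable], fd[stable], rtol=1e-5)
        pinned = e.partials(sf.met, site, mode="finite_difference").d_ca
        assert np.allclose(ana, pinned, rtol=1e-5)

    def test_monotone_in_lai_and_swin(self, site_and_forcing):
        sf, site = site_and_forcing
        g0 = e.monthly_gpp(sf.met, site).gpp
        g_lai = e.monthly_gpp(sf.met.replace(lai=sf.met.lai * 1.2), site).gpp
        g_sw = e.monthly_gpp(sf.met.replace(swin=sf.met.swin * 1.2), site).gpp
        assert np.all(g_lai >= g0 - 1e-12)
        assert np.all(g_sw >= g0 - 1e-12)

    def test_missing_driver_flags_month(self, site_and_forcing):
        sf, site = site_and_forcing
        ta = sf.met.ta.copy()
        ta[3] = np.nan
        res = e.monthly_gpp(sf.met.replace(ta=ta), site)
        assert res.missing[3] and np.isnan(res.gpp[3])
        assert np.isfinite(res.gpp[np.arange(len(ta)) != 3]).all()

    def test_light_saturated_fraction_bright_sparse_vs_dim_dense(self, site_and_forcing):
        sf, site = site_and_forcing
        bright = sf.met.replace(swin=np.full_like(sf.met.swin, 330.0),
                                lai=np.full_like(sf.met.lai, 0.8))
        dim = sf.met.replace(swin=np.full_like(sf.met.swin, 90.0),
                             lai=np.full_like(sf.met.lai, 5.0))
        f_bright = e.light_saturated_fraction(e.monthly_gpp(bright, site))
        f_dim = e.light_saturated_fraction(e.monthly_gpp(dim, site))
        assert 0.0 <= f_dim <= f_bright <= 1.0


class TestCalibration:
    @pytest.fixture(scope="class")
    def recovery_site(self):
        cfg = e.SynthConfig(n_sites=1, n_years=12, seed=5, lai_max=1.8,
                            swc_mean=0.14, swc_seasonal_amp=0.07, swc_sd=0.04)
        sf = e.gen_forcing(cfg)[0]
        site = e.gen_truth_sites(cfg, [sf])[0]
        return sf, site

    def test_noise_free_parameter_recovery(self, recovery_site):
        sf, truth = recovery_site
        fit = e.calibrate(sf.met, e.truth_gpp(sf, truth))
        assert fit.zeta0 == pytest.approx(truth.zeta0, rel=1e-6)
        assert np.allclose(fit.extinction, truth.extinction, rtol=1e-6)

    @staticmethod
    def _beta_and_gpp(sf, site):
        """Mean annual beta_CO2 and GPP over the observed monthly series
        (observed states sit generically off the colimitation kink, unlike
        the exact coordination reference)."""
        beta = e.partials(sf.met, site).d_ca.reshape(-1, 12).sum(1).mean()
        gpp = e.monthly_gpp(sf.met, site).gpp.reshape(-1, 12).sum(1).mean()
        return float(beta), float(gpp)

    def test_scaled_reference_scales_modelled_gpp(self, recovery_site):
        """Doubling the reference doubles the fitted GPP magnitude while the
        relative CO2 sensitivity (per unit GPP) is essentially unchanged."""
        sf, _ = recovery_site
        # sparse canopy so a doubled absorbed fraction stays inside the
        # extinction bounds
        truth = e.build_site(sf.met, 0.2, 140.0)
        g = e.monthly_gpp(sf.met, truth).gpp
        fit1 = e.calibrate(sf.met, g)
        fit2 = e.calibrate(sf.met, 2.0 * g)
        b1, g1 = self._beta_and_gpp(sf, fit1)
        b2, g2 = self._beta_and_gpp(sf, fit2)
        assert g2 == pytest.approx(2.0 * g1, rel=0.02)
        assert b2 / g2 == pytest.approx(b1 / g1, rel=0.02)

    def test_calibration_leaves_beta_co2_nearly_unchanged(self, recovery_site):
        """The analytic CO2 sensitivity is insensitive to the GPP uncertainty
        used for calibration: <5% shift against the pre-calibration truth
        parameters when fitting noisy or rescaled references."""
        sf, truth = recovery_site
        b0, g0 = self._beta_and_gpp(sf, truth)
        g = e.truth_gpp(sf, truth, noise_sd=0.05, seed=21)
        fit = e.calibrate(sf.met, g)
        b_fit, _ = self._beta_and_gpp(sf, fit)
        assert b_fit == pytest.approx(b0, rel=0.05)
        scaled_fit = e.calibrate(sf.met, 0.85 * e.truth_gpp(sf, truth))
        b_s, g_s = self._beta_and_gpp(sf, scaled_fit)
        assert b_s / g_s == pytest.approx(b0 / g0, rel=0.01)

    def test_zero_variance_reference_warns_flat_fit(self, recovery_site):
        sf, _ = recovery_site
        flat = np.full(len(sf.years), 80.0)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            fit = e.calibrate(sf.met, flat)
        assert any("zero variance" in str(x.message) for x in w)
        assert np.all(np.isfinite(fit.extinction))

    def test_too_few_months_raise(self, recovery_site):
        sf, truth = recovery_site
        g = e.truth_gpp(sf, truth)
        short = sf.met.replace(**{k: getattr(sf.met, k)[:6] for k in
                                  ("ta", "swin", "pa", "qa", "swc", "ca", "lai")},
                               month=sf.met.month[:6],
                               daytime_seconds=sf.met.daytime_seconds[:6])
        with pytest.raises(e.CalibrationError):
            e.calibrate(short, g[:6])


def _clim12(met):
    """Calendar-month climatology of a monthly forcing record."""
    fields = {}
    for k in ("ta", "swin", "pa", "qa", "swc", "ca", "lai", "daytime_seconds"):
        x = getattr(met, k)
        fields[k] = np.array([np.mean(x[met.month == m]) for m in range(1, 13)])
    ds = fields.pop("daytime_seconds")
    return e.MeteoMonth(**fields, month=np.arange(1, 13), daytime_seconds=ds)


class TestCoordinationTimescales:
    def test_alternative_timescales_vary_capacity(self, site_and_forcing):
        """The decadal default gives one fixed capacity; shorter acclimation
        timescales track CO2 (and climate) and so vary across records while
        staying near the decadal value."""
        sf, site = site_and_forcing
        v_dec, _ = e.coordinate_series(sf.met, sf.years, site.zeta0, "decadal")
        assert np.ptp(v_dec) == 0.0
        for ts in ("annual_ca", "annual_all", "monthly_ca", "monthly_all"):
            v, j = e.coordinate_series(sf.met, sf.years, site.zeta0, ts)
            assert np.ptp(v) > 0.0, ts
            assert np.all(j > v * 1.2), ts
        # peak-month-based alternatives stay close to the decadal solution;
        # full monthly acclimation departs strongly in the dim cold months
        for ts in ("annual_ca", "annual_all", "monthly_ca"):
            v, _ = e.coordinate_series(sf.met, sf.years, site.zeta0, ts)
            assert np.median(np.abs(v / v_dec - 1)) < 0.2, ts

    def test_monthly_ca_only_responds_to_co2(self, site_and_forcing):
        """With CO2 constant the monthly-CO2 timescale collapses onto the
        decadal solution."""
        sf, site = site_and_forcing
        met = sf.met.replace(ca=np.full_like(sf.met.ca, 400.0))
        v_dec, _ = e.coordinate_series(met, sf.years, site.zeta0, "decadal")
        v_mca, _ = e.coordinate_series(met, sf.years, site.zeta0, "monthly_ca")
        assert np.allclose(v_mca, v_dec, rtol=1e-10)


class TestAnnualAggregate:
    def test_twelve_valid_months_sum(self):
        months = np.arange(1, 13)
        res = e.annual_aggregate(np.full(12, 100.0), np.full(12, 2001), months,
                                 growing_mask=np.ones(12, bool))
        assert res.gpp[0] == pytest.approx(1200.0)
        assert res.qualified[0]

    def test_single_growing_gap_backfilled(self):
        months = np.tile(np.arange(1, 13), 2)
        years = np.repeat([2001, 2002], 12)
        g = np.where(np.isin(months, range(4, 10)), 100.0, 10.0).astype(float)
        backup = g.copy()
        g[(years == 2002) & (months == 6)] = np.nan
        gm = np.isin(np.arange(1, 13), range(4, 10))
        res = e.annual_aggregate(g, years, months, growing_mask=gm, backup=backup)
        assert res.qualified.all()
        assert res.gpp[1] == pytest.approx(res.gpp[0])
        assert any(r[1] == "backfilled" for r in res.reasons)

    def test_two_growing_gaps_exclude_year(self):
        months = np.arange(1, 13)
        g = np.where(np.isin(months, range(4, 10)), 100.0, 10.0).astype(float)
        g[[5, 6]] = np.nan
        gm = np.isin(np.arange(1, 13), range(4, 10))
        res = e.annual_aggregate(g, np.full(12, 2001), months, growing_mask=gm,
                                 backup=g)
        assert not res.qualified[0]
        assert np.isnan(res.gpp[0])
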
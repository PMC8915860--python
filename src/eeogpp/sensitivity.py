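"""Partial derivatives of GPP, attribution machinery and beta metrics.

The closed-form GPP chain is differentiated in two independent ways:

* ``analytic`` — complex-step differentiation of the holomorphic chain with
  every branch (FvCB min, VPD floor, positivity clip) pinned at the
  evaluation point.  This is algorithmic differentiation of the closed form
  and is exact to machine precision; there is no subtractive cancellation.
* ``finite_difference`` — the central-difference oracle with per-driver
  steps, the same branch pinning.  Derivatives of the piecewise model are
  branch-conditional by definition (the capacity pathway swaps Vcmax for
  Jmax under light limitation), so both modes differentiate the active
  branch.

Coordination is frozen during differentiation: reference capacities are a
decadal property and respond to temperature only through the instantaneous
kinetics.

Attribution follows the composite linear decomposition
``dGPP = sum_i (dGPP/dx_i) dx_i`` over the seven drivers, the univariate
factorial recipe (one driver time-varying, the others at their monthly
climatology), the five-pathway chain-rule split of the temperature
sensitivity, and the logarithmic CO2 response ratio
``beta_ln = ln(GPP_e/GPP_s) / ln(ca_e/ca_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .canopy import (PinState, SiteModel, gpp_drivers,
                     gpp_given_intermediates, monthly_gpp)
from .errors import AttributionError, DomainError
from .meteo import MeteoMonth, vpd_from_q
from .params import DEFAULT_PARAMS, PhotoParams
from .photo import eta_star, kinetics_at
from . import trends

#: driver order used throughout
DRIVERS = ("ca", "lai", "ta", "swc", "qa", "swin", "pa")

_CSTEP = 1e-30


@dataclass
class SensitivityVector:
    """Partial derivatives of GPP to the seven drivers.

    Units are GPP units per driver unit: for monthly inputs
    gC m-2 mo-1 ppmv-1 etc.; summed over a climatological year,
    gC m-2 yr-1 ppmv-1 (d_ca is then beta_CO2).
    """

    d_ca: np.ndarray
    d_lai: np.ndarray
    d_ta: np.ndarray
    d_swc: np.ndarray
    d_qa: np.ndarray
    d_swin: np.ndarray
    d_pa: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, f"d_{name}") for name in DRIVERS}

    def sum(self) -> "SensitivityVector":
        return SensitivityVector(**{f"d_{k}": np.sum(v) for k, v in self.as_dict().items()})


@dataclass
class TaPathways:
    """Chain-rule split of dGPP/dTa into its five physiological pathways."""

    via_d: np.ndarray
    via_capacity: np.ndarray
    via_k: np.ndarray
    via_gamma_star: np.ndarray
    via_eta_star: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return (self.via_d + self.via_capacity + self.via_k
                + self.via_gamma_star + self.via_eta_star)


def _driver_arrays(met: MeteoMonth) -> Dict[str, np.ndarray]:
    return {"ca": np.asarray(met.ca, dtype=float),
            "lai": np.asarray(met.lai, dtype=float),
            "ta": np.asarray(met.ta, dtype=float),
            "swc": np.asarray(met.swc, dtype=float),
            "qa": np.asarray(met.qa, dtype=float),
            "swin": np.asarray(met.swin, dtype=float),
            "pa": np.asarray(met.pa, dtype=float)}


def _chain(dr: Dict[str, np.ndarray], met: MeteoMonth, site: SiteModel,
           params: PhotoParams, state: Optional[PinState]):
    return gpp_drivers(dr["ca"], dr["lai"], dr["ta"], dr["swc"], dr["qa"],
                       dr["swin"], dr["pa"], met.month, met.daytime_seconds,
                       site, params, state=state)


def partials(met: MeteoMonth, site: SiteModel,
             params: PhotoParams = DEFAULT_PARAMS,
             mode: str = "analytic") -> SensitivityVector:
    """Per-record partial derivatives of monthly GPP to the seven drivers."""
    if mode not in ("analytic", "finite_difference"):
        raise ValueError(f"unknown mode {mode!r}")
    dr0 = _driver_arrays(met)
    _, state = _chain(dr0, met, site, params, None)
    out = {}
    for name in DRIVERS:
        x = dr0[name]
        if mode == "analytic":
            h = _CSTEP * np.maximum(np.abs(x), 1.0)
            dr = dict(dr0)
            dr[name] = x.astype(complex) + 1j * h
            g, _ = _chain(dr, met, site, params, state)
            d = np.imag(g) / h
        else:
            h = params.fd_steps[name]
            dr_p, dr_m = dict(dr0), dict(dr0)
            dr_p[name] = x + h
            dr_m[name] = x - h
            gp, _ = _chain(dr_p, met, site, params, state)
            gm, _ = _chain(dr_m, met, site, params, state)
            d = (gp - gm) / (2.0 * h)
        if not np.all(np.isfinite(np.atleast_1d(d))):
            raise ArithmeticError(f"non-finite derivative for driver '{name}'")
        out[f"d_{name}"] = d
    return SensitivityVector(**out)


def climatological_sensitivity(met_clim: MeteoMonth, site: SiteModel,
                               params: PhotoParams = DEFAULT_PARAMS,
                               mode: str = "analytic") -> SensitivityVector:
    """Annual-scale sensitivities (gC m-2 yr-1 per driver unit): the sum of
    monthly partials over a 12-month climatological year, each driver
    perturbed coherently in all months."""
    return partials(met_clim, site, params, mode).sum()


def ta_pathways(met: MeteoMonth, site: SiteModel,
                params: PhotoParams = DEFAULT_PARAMS,
                dd_dta=None) -> TaPathways:
    """Five-pathway decomposition of dGPP/dTa (per record).

    Air temperature reaches GPP only through D, K, Gamma*, eta* and the
    instantaneous capacity response, so the pathway terms close exactly on
    the total temperature partial.  The capacity branch follows the
    limitation flag (Vcmax when Rubisco-limited, Jmax when light-limited).

    ``dd_dta`` overrides the D-vs-Ta path derivative (default: dD/dTa at
    fixed specific humidity).  Pass 0 for constructions that co-vary qa with
    Ta so that D is held constant, making the D pathway vanish exactly.
    """
    dr = _driver_arrays(met)
    gpp0, state, ex = gpp_drivers(dr["ca"], dr["lai"], dr["ta"], dr["swc"],
                                  dr["qa"], dr["swin"], dr["pa"], met.month,
                                  met.daytime_seconds, site, params,
                                  return_extras=True)
    kin = ex["kin"]
    base = dict(d=ex["d"], K=kin.K, gamma_star=kin.gamma_star,
                eta_st=kin.eta_star, vcmax=ex["vcmax"], jmax=ex["jmax"])

    def dgpp_wrt(arg: str) -> np.ndarray:
        x = np.asarray(base[arg], dtype=float)
        h = _CSTEP * np.maximum(np.abs(x), 1.0)
        kw = dict(base)
        kw[arg] = x.astype(complex) + 1j * h
        g, _ = gpp_given_intermediates(
            kw["d"], kw["K"], kw["gamma_star"], kw["eta_st"], kw["vcmax"],
            kw["jmax"], ex["ca_pp"], ex["beta"], ex["iabs"],
            met.daytime_seconds, site.pathway, params,
            rubisco=state.rubisco, positive=state.positive)
        return np.imag(g) / h

    ta = dr["ta"]
    h_t = _CSTEP * np.maximum(np.abs(ta), 1.0)
    ta_c = ta.astype(complex) + 1j * h_t

    if dd_dta is None:
        dd_dta = np.imag(vpd_from_q(ta_c, dr["qa"], dr["pa"])) / h_t
        dd_dta = np.where(state.d_clamped, 0.0, dd_dta)
    else:
        dd_dta = np.broadcast_to(np.asarray(dd_dta, dtype=float), ta.shape)
    kin_c = kinetics_at(ta_c, dr["pa"], site.vcmax25_ref, site.jmax25_ref, params)
    dk_dta = np.imag(kin_c.K) / h_t
    dgs_dta = np.imag(kin_c.gamma_star) / h_t
    deta_dta = np.imag(eta_star(ta_c)) / h_t
    dvc_dta = np.imag(kin_c.vcmax) / h_t * ex["f_l"]
    djm_dta = np.imag(kin_c.jmax) / h_t * ex["f_l"]

    return TaPathways(
        via_d=dgpp_wrt("d") * dd_dta,
        via_capacity=dgpp_wrt("vcmax") * dvc_dta + dgpp_wrt("jmax") * djm_dta,
        via_k=dgpp_wrt("K") * dk_dta,
        via_gamma_star=dgpp_wrt("gamma_star") * dgs_dta,
        via_eta_star=dgpp_wrt("eta_st") * deta_dta,
    )


def composite_change(sens: SensitivityVector, deltas: Dict[str, float]
                     ) -> Tuple[float, float]:
    """Composite GPP change from per-driver deltas (trend or IAV), and the
    direct CO2-fertilization term beta_CO2 * dca separately."""
    s = sens.as_dict()
    total = sum(float(np.sum(s[k])) * deltas.get(k, 0.0) for k in DRIVERS)
    return total, float(np.sum(s["ca"])) * deltas.get("ca", 0.0)


def beta_ln(gpp_s, gpp_e, ca_s, ca_e) -> float:
    """Logarithmic GPP-to-CO2 response ratio ln(GPPe/GPPs)/ln(ca_e/ca_s).

    Unity indicates direct proportionality of GPP to CO2.  The caller tags
    the result apparent (all drivers varying) or direct (CO2-only runs).
    """
    for name, v in (("gpp_s", gpp_s), ("gpp_e", gpp_e), ("ca_s", ca_s), ("ca_e", ca_e)):
        if not v > 0:
            raise DomainError(name, "beta_ln requires positive inputs")
    if ca_e == ca_s:
        raise DomainError("ca_e", "beta_ln requires ca_e != ca_s")
    return float(np.log(gpp_e / gpp_s) / np.log(ca_e / ca_s))


# --------------------------------------------------------------------------
# univariate factorial attribution
# --------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-factor trend and IAV attribution for one site (or a network).

    contributions: per-factor GPP trend (gC m-2 yr-2) from univariate runs;
    aggregated: their exact sum; model_trend: trend of the all-varying run;
    ca_partial_trend: beta_CO2 * dca/dt from the partial-derivative route;
    beta_app_ln / beta_dir_ln: Eq.-style log response ratios from the
    all-varying and CO2-only runs; iav: per-factor |dGPP/dx| * IAV(x).
    """

    contributions: Dict[str, float]
    pvalues: Dict[str, float]
    aggregated: float
    model_trend: float
    model_p: float
    ca_partial_trend: float
    beta_co2: float
    beta_app_ln: float
    beta_dir_ln: float
    iav: Dict[str, float]
    years: np.ndarray = field(default_factory=lambda: np.array([]))
    factor_annual: Dict[str, np.ndarray] = field(default_factory=dict)
    model_annual: np.ndarray = field(default_factory=lambda: np.array([]))
    ca_annual: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self, site: str = "site") -> pd.DataFrame:
        rows = [{"site": site, "factor": k, "contribution": v,
                 "p_value": self.pvalues.get(k, np.nan), "method": "univariate"}
                for k, v in self.contributions.items()]
        rows.append({"site": site, "factor": "ca", "contribution": self.ca_partial_trend,
                     "p_value": np.nan, "method": "partial_derivative"})
        return pd.DataFrame(rows)


def _monthly_climatology(x: np.ndarray, months: np.ndarray) -> np.ndarray:
    clim = np.empty_like(x)
    for m in range(1, 13):
        sel = months == m
        clim[sel] = np.mean(x[sel])
    return clim


def _annual_sum(x: np.ndarray, years: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    uy = np.unique(years)
    return uy, np.array([np.sum(x[years == y]) for y in uy])


def _annual_mean(x: np.ndarray, years: np.ndarray) -> np.ndarray:
    uy = np.unique(years)
    return np.array([np.mean(x[years == y]) for y in uy])


def _sen_endpoints(y: np.ndarray, x: np.ndarray) -> Tuple[float, float]:
    """First/last-year values of the Sen trend line (noise-robust endpoints)."""
    r = trends.mann_kendall_sen(y, x)
    return r.intercept + r.slope * x[0], r.intercept + r.slope * x[-1]


def univariate_attribution(met: MeteoMonth, years, site: SiteModel,
                           params: PhotoParams = DEFAULT_PARAMS,
                           min_years: int = 5,
                           endpoints: str = "sen_fit") -> AttributionResult:
    """Factorial attribution of the GPP trend and IAV for one site.

    For each driver, the model is rerun with that driver time-varying and all
    others held at their calendar-month climatology; the Sen trend of the
    resulting annual GPP is that factor's contribution.  ``aggregated`` is
    the exact sum over factors.  The CO2 contribution is also estimated by
    the partial-derivative route (beta_CO2 times the CO2 trend) as a
    cross-check, and the log response ratios beta_app/beta_dir are computed
    from trend-line endpoints (``endpoints='raw'`` uses the raw first/last
    annual values).
    """
    years = np.asarray(years)
    uy = np.unique(years)
    if uy.size < min_years:
        raise AttributionError(f"attribution needs >= {min_years} years, got {uy.size}")
    months = np.broadcast_to(met.month, years.shape)
    dr = _driver_arrays(met)
    dr = {k: np.broadcast_to(v, years.shape).astype(float) for k, v in dr.items()}
    clim = {k: _monthly_climatology(v, months) for k, v in dr.items()}

    def run(drivers: Dict[str, np.ndarray]) -> np.ndarray:
        m = met.replace(**{k: drivers[k] for k in DRIVERS})
        res = monthly_gpp(m, site, params)
        _, annual = _annual_sum(res.gpp, years)
        return annual

    contributions, pvalues, factor_annual = {}, {}, {}
    for name in DRIVERS:
        drivers = dict(clim)
        drivers[name] = dr[name]
        annual = run(drivers)
        r = trends.mann_kendall_sen(annual, uy.astype(float))
        contributions[name] = r.slope
        pvalues[name] = r.p_value
        factor_annual[name] = annual

    model_annual = run(dr)
    rm = trends.mann_kendall_sen(model_annual, uy.astype(float))

    # partial-derivative CO2 estimate at the climatological state
    clim12 = MeteoMonth(
        **{k: np.array([np.mean(clim[k][months == m]) for m in range(1, 13)])
           for k in DRIVERS},
        month=np.arange(1, 13),
        daytime_seconds=np.array([np.mean(np.broadcast_to(met.daytime_seconds, years.shape)[months == m])
                                  for m in range(1, 13)]))
    sens = climatological_sensitivity(clim12, site, params)
    ca_annual = _annual_mean(dr["ca"], years)
    ca_trend = trends.mann_kendall_sen(ca_annual, uy.astype(float)).slope
    beta_co2 = float(sens.d_ca)
    ca_partial_trend = beta_co2 * ca_trend

    # log response ratios
    if endpoints == "sen_fit":
        g_s, g_e = _sen_endpoints(model_annual, uy.astype(float))
        gd_s, gd_e = _sen_endpoints(factor_annual["ca"], uy.astype(float))
        c_s, c_e = _sen_endpoints(ca_annual, uy.astype(float))
    else:
        g_s, g_e = model_annual[0], model_annual[-1]
        gd_s, gd_e = factor_annual["ca"][0], factor_annual["ca"][-1]
        c_s, c_e = ca_annual[0], ca_annual[-1]
    if c_s == c_e:  # no CO2 change over the period: the log ratio is undefined
        b_app = b_dir = float("nan")
    else:
        b_app = beta_ln(g_s, g_e, c_s, c_e)
        b_dir = beta_ln(gd_s, gd_e, c_s, c_e)

    # IAV proxy: |annual partial| x 1 SD of the detrended annual driver
    iav = {}
    svec = sens.as_dict()
    for name in DRIVERS:
        x_annual = _annual_mean(dr[name], years)
        iav[name] = abs(float(svec[name])) * trends.iav(x_annual, uy.astype(float))

    return AttributionResult(
        contributions=contributions, pvalues=pvalues,
        aggregated=float(sum(contributions.values())),
        model_trend=rm.slope, model_p=rm.p_value,
        ca_partial_trend=ca_partial_trend, beta_co2=beta_co2,
        beta_app_ln=b_app, beta_dir_ln=b_dir, iav=iav,
        years=uy, factor_annual=factor_annual, model_annual=model_annual,
        ca_annual=ca_annual)


def network_attribution(results: Sequence[AttributionResult],
                        endpoints: str = "sen_fit") -> AttributionResult:
    """Combine per-site attributions into a network result.

    Per-factor network series are cross-site means of per-site annual
    anomalies (deviation from each site's study-period mean), and the
    network contribution is the Sen trend of that series — the same
    construction as the network GPP anomaly plot.  beta metrics use the
    cross-site mean absolute GPP.
    """
    if not results:
        raise AttributionError("network attribution needs at least one site")
    years = results[0].years.astype(float)
    for r in results:
        if not np.array_equal(r.years, results[0].years):
            raise AttributionError("sites must share the same study years")

    def anom_mean(series_list: List[np.ndarray]) -> np.ndarray:
        a = np.stack([s - np.mean(s) for s in series_list])
        return np.mean(a, axis=0)

    contributions, pvalues, factor_series = {}, {}, {}
    for name in DRIVERS:
        net = anom_mean([r.factor_annual[name] for r in results])
        t = trends.mann_kendall_sen(net, years)
        contributions[name] = t.slope
        pvalues[name] = t.p_value
        factor_series[name] = net

    model_net = anom_mean([r.model_annual for r in results])
    tm = trends.mann_kendall_sen(model_net, years)

    mean_abs = np.mean(np.stack([r.model_annual for r in results]), axis=0)
    mean_dir = np.mean(np.stack([r.factor_annual["ca"] for r in results]), axis=0)
    ca_mean = np.mean(np.stack([r.ca_annual for r in results]), axis=0)
    if endpoints == "sen_fit":
        g_s, g_e = _sen_endpoints(mean_abs, years)
        gd_s, gd_e = _sen_endpoints(mean_dir, years)
        c_s, c_e = _sen_endpoints(ca_mean, years)
    else:
        g_s, g_e = mean_abs[0], mean_abs[-1]
        gd_s, gd_e = mean_dir[0], mean_dir[-1]
        c_s, c_e = ca_mean[0], ca_mean[-1]

    beta_co2 = float(np.mean([r.beta_co2 for r in results]))
    ca_trend = trends.mann_kendall_sen(ca_mean, years).slope
    iav = {name: float(np.median([r.iav[name] for r in results])) for name in DRIVERS}
    if c_s == c_e:
        b_app = b_dir = float("nan")
    else:
        b_app = beta_ln(g_s, g_e, c_s, c_e)
        b_dir = beta_ln(gd_s, gd_e, c_s, c_e)

    return AttributionResult(
        contributions=contributions, pvalues=pvalues,
        aggregated=float(sum(contributions.values())),
        model_trend=tm.slope, model_p=tm.p_value,
        ca_partial_trend=beta_co2 * ca_trend, beta_co2=beta_co2,
        beta_app_ln=b_app, beta_dir_ln=b_dir,
        iav=iav, years=results[0].years, factor_annual=factor_series,
        model_annual=model_net, ca_annual=ca_mean)
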
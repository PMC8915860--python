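"""Big-leaf canopy upscaling, site calibration and annual aggregation.

Monthly canopy GPP is the full optimality chain integrated over the month:

    kinetics -> mWUE(SWC) -> optimal chi -> capacities (coordinated decadally,
    adjusted instantaneously with temperature) -> FvCB assimilation ->
    Beer-Lambert light absorption -> daytime-seconds integration.

The canopy is a single big leaf: the monthly extinction factor k_m (the
calibrated climatology of |G(mu)/mu|) sets the absorbed fraction
f_L = 1 - exp(-k_m LAI), which scales both absorbed light and canopy
photosynthetic capacity.  Because the electron-transport hyperbola is
homogeneous of degree one in (absorbed light, Jmax), canopy assimilation
equals f_L times the leaf rate at top-of-canopy light, which keeps the
framework analytic.

Calibration fits the 12 monthly extinction values (pooled across years by
calendar month) and the site soil-moisture constant zeta0 against a reference
monthly GPP series; it sets the GPP magnitude but leaves the relative CO2
sensitivity essentially unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import minimize_scalar

from .errors import CalibrationError
from .meteo import MeteoMonth, vpd_from_q
from .params import DEFAULT_PARAMS, PhotoParams, M_CARBON
from .photo import (Kinetics, Pathway, RUBISCO, RUBP, assimilation_rates,
                    coordinate_capacity, kinetics_at, mwue_beta,
                    optimal_chi_values)


@dataclass
class SiteModel:
    """Calibrated per-site (or per-grid-cell) constants.

    extinction: 12 monthly values of the light-extinction climatology, kept
    constant across years; zeta0: mWUE soil-moisture constant; pathway: C3 or
    C4; vcmax25_ref/jmax25_ref: coordinated reference capacities
    (umol m-2 s-1 at 25 degC); peak_month: calendar month of maximum
    climatological LAI used as the coordination reference.
    """

    extinction: np.ndarray
    zeta0: float
    pathway: Pathway = Pathway.C3
    vcmax25_ref: float = 50.0
    jmax25_ref: float = 85.0
    peak_month: int = 7
    ref_met: Optional[MeteoMonth] = None

    def __post_init__(self):
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (12,):
            self.extinction = np.broadcast_to(self.extinction, (12,)).copy()
        if np.any(self.extinction <= 0):
            raise CalibrationError("extinction climatology must be > 0")
        self.pathway = Pathway(self.pathway)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "extinction": [float(v) for v in self.extinction],
            "zeta0": float(self.zeta0),
            "pathway": self.pathway.value,
            "vcmax25_ref": float(self.vcmax25_ref),
            "jmax25_ref": float(self.jmax25_ref),
            "peak_month": int(self.peak_month),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteModel":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PinState:
    """Branch decisions frozen at an evaluation point.

    Derivatives of the piecewise chain are branch-conditional: the FvCB min,
    the VPD floor and the GPP positivity clip are decided once on real parts
    and pinned while perturbed (complex or finite-difference) evaluations run.
    """

    d_clamped: np.ndarray
    rubisco: np.ndarray
    positive: np.ndarray


def absorbed_light(swin, lai, extinction_m, params: PhotoParams = DEFAULT_PARAMS):
    """Absorbed photon flux (umol photons m-2 s-1, ground basis).

    Beer-Lambert absorption of the PAR fraction of shortwave:
    Iabs = SWin * par_frac * umol_per_j * (1 - exp(-k_m LAI)).
    """
    frac = 1.0 - np.exp(-np.asarray(extinction_m) * np.asarray(lai))
    return np.asarray(swin) * params.par_frac * params.umol_per_j * frac


def gpp_given_intermediates(d, K, gamma_star, eta_st, vcmax, jmax, ca_pp,
                            beta_cost, iabs, daytime_seconds,
                            pathway: Pathway = Pathway.C3,
                            params: PhotoParams = DEFAULT_PARAMS,
                            rubisco=None, positive=None):
    """Monthly GPP (gC m-2 mo-1) from the model's intermediate quantities.

    This is the inner closed form behind both the driver-level chain and the
    temperature-pathway decomposition: air temperature reaches GPP only
    through (D, K, Gamma*, eta*, Vcmax/Jmax), so differentiating this
    function in each argument yields the chain-rule pathways exactly.

    ``rubisco``/``positive`` pin the FvCB branch and the positivity clip;
    when None they are decided from real parts.  Returns (gpp, state_dict).
    """
    chi, ci = optimal_chi_values(ca_pp, d, K, gamma_star, eta_st, beta_cost,
                                 params, floor=False)
    kin = Kinetics(K=K, gamma_star=gamma_star, eta_star=eta_st, vcmax=vcmax, jmax=jmax)
    ac, aj = assimilation_rates(ci, iabs, kin, pathway, params)
    rub = (np.real(ac) <= np.real(aj)) if rubisco is None else rubisco
    a = np.where(rub, ac, aj)
    pos = (np.real(a) > 0) if positive is None else positive
    gpp = np.where(pos, a, np.zeros_like(a)) * daytime_seconds * (M_CARBON * 1e-6)
    return gpp, {"chi": chi, "ci": ci, "a": a, "rubisco": rub, "positive": pos}


def gpp_drivers(ca, lai, ta, swc, qa, swin, pa, month, daytime_seconds,
                site: SiteModel, params: PhotoParams = DEFAULT_PARAMS,
                state: Optional[PinState] = None, return_extras: bool = False):
    """Monthly GPP from the seven drivers (holomorphic in all of them).

    The workhorse behind :func:`monthly_gpp` and the sensitivity module.
    ``state`` pins all branch decisions; pass the state recorded at the
    unperturbed point when evaluating perturbed inputs.
    """
    ca = np.asarray(ca); lai = np.asarray(lai); ta = np.asarray(ta)
    swc = np.asarray(swc); qa = np.asarray(qa); swin = np.asarray(swin)
    pa = np.asarray(pa); month = np.asarray(month, dtype=int)

    d_raw = vpd_from_q(ta, qa, pa)
    clamp = (np.real(d_raw) < params.d_floor) if state is None else state.d_clamped
    d = np.where(clamp, params.d_floor, d_raw)

    kin = kinetics_at(ta, pa, site.vcmax25_ref, site.jmax25_ref, params)
    k_m = site.extinction[month - 1]
    f_l = 1.0 - np.exp(-k_m * lai)
    iabs = swin * params.par_frac * params.umol_per_j * f_l
    vcmax = kin.vcmax * f_l
    jmax = kin.jmax * f_l
    beta = mwue_beta(swc, site.zeta0, params)
    ca_pp = ca * 1e-6 * pa

    gpp, st = gpp_given_intermediates(
        d, kin.K, kin.gamma_star, kin.eta_star, vcmax, jmax, ca_pp, beta, iabs,
        daytime_seconds, site.pathway, params,
        rubisco=None if state is None else state.rubisco,
        positive=None if state is None else state.positive)
    pin = PinState(d_clamped=clamp, rubisco=st["rubisco"], positive=st["positive"])
    if return_extras:
        extras = {"chi": st["chi"], "ci": st["ci"], "a": st["a"], "d": d,
                  "kin": kin, "beta": beta, "ca_pp": ca_pp, "f_l": f_l,
                  "iabs": iabs, "vcmax": vcmax, "jmax": jmax}
        return gpp, pin, extras
    return gpp, pin


@dataclass
class GppResult:
    """Monthly GPP with diagnostics; missing-driver months are NaN-flagged."""

    gpp: np.ndarray
    limitation: np.ndarray
    missing: np.ndarray
    chi: np.ndarray
    ci: np.ndarray
    a: np.ndarray
    g: np.ndarray


def monthly_gpp(met: MeteoMonth, site: SiteModel,
                params: PhotoParams = DEFAULT_PARAMS) -> GppResult:
    """Monthly canopy GPP (gC m-2 mo-1) for a forcing record (array) series.

    Months with any missing (NaN) driver are returned as NaN with the missing
    flag set, never raised.
    """
    drivers = (met.ca, met.lai, met.ta, met.swc, met.qa, met.swin, met.pa)
    missing = np.zeros(np.broadcast(*drivers).shape, dtype=bool)
    for x in drivers:
        missing |= ~np.isfinite(np.broadcast_to(x, missing.shape))
    # NaNs flow through the chain; keep temperature NaNs from tripping the
    # domain check by substituting the reference temperature on masked months.
    ta = np.where(missing, 25.0, met.ta)
    gpp, pin, extras = gpp_drivers(
        met.ca, met.lai, ta, np.where(missing, 0.3, met.swc),
        np.where(missing, 0.008, met.qa), met.swin, met.pa, met.month,
        met.daytime_seconds, site, params, return_extras=True)
    gpp = np.where(missing, np.nan, gpp)
    limitation = np.where(pin.rubisco, RUBISCO, RUBP)
    with np.errstate(invalid="ignore"):
        g = np.where(extras["ca_pp"] > extras["ci"],
                     extras["a"] / (extras["ca_pp"] - extras["ci"]), np.nan)
    return GppResult(gpp=gpp, limitation=limitation, missing=missing,
                     chi=np.where(missing, np.nan, extras["chi"]),
                     ci=np.where(missing, np.nan, extras["ci"]),
                     a=np.where(missing, np.nan, extras["a"]), g=g)


def light_saturated_fraction(result: GppResult) -> float:
    """Fraction of summed canopy GPP produced under Rubisco (light-saturated)
    limitation; lies in [0, 1]."""
    ok = ~result.missing & np.isfinite(result.gpp) & (result.gpp > 0)
    total = float(np.sum(result.gpp[ok]))
    if total <= 0:
        return 0.0
    rub = ok & (result.limitation == RUBISCO)
    return float(np.sum(result.gpp[rub])) / total


# --------------------------------------------------------------------------
# coordination helpers and calibration
# --------------------------------------------------------------------------

def reference_environment(met: MeteoMonth, peak_month: Optional[int] = None) -> MeteoMonth:
    """Decadal-average daytime environment of the peak-LAI calendar month."""
    month = np.broadcast_to(met.month, np.broadcast(met.month, met.lai).shape)
    if peak_month is None:
        lai = np.broadcast_to(met.lai, month.shape)
        clim = [np.nanmean(lai[month == m]) if np.any(month == m) else -np.inf
                for m in range(1, 13)]
        peak_month = int(np.argmax(clim)) + 1
    sel = month == peak_month
    sub = MeteoMonth(
        ta=np.broadcast_to(met.ta, month.shape)[sel],
        swin=np.broadcast_to(met.swin, month.shape)[sel],
        pa=np.broadcast_to(met.pa, month.shape)[sel],
        qa=np.broadcast_to(met.qa, month.shape)[sel],
        swc=np.broadcast_to(met.swc, month.shape)[sel],
        ca=np.broadcast_to(met.ca, month.shape)[sel],
        lai=np.broadcast_to(met.lai, month.shape)[sel],
        month=np.full(int(np.sum(sel)), peak_month),
        daytime_seconds=np.broadcast_to(met.daytime_seconds, month.shape)[sel],
    )
    return sub.mean()


def coordinate_site(met: MeteoMonth, zeta0: float,
                    pathway: Pathway = Pathway.C3,
                    params: PhotoParams = DEFAULT_PARAMS,
                    peak_month: Optional[int] = None):
    """Coordinate reference capacities for a site from its forcing record.

    Returns (vcmax25, jmax25, ref_met).  The reference light is the
    top-of-canopy PPFD of the reference month (extinction cancels from the
    colimitation condition).
    """
    ref = reference_environment(met, peak_month)
    ppfd_top = float(ref.swin) * params.par_frac * params.umol_per_j
    v25, j25 = coordinate_capacity(ref, ppfd_top, zeta0, pathway, params)
    return v25, j25, ref


def _leaf_monthly_gpp(met: MeteoMonth, zeta0: float, v25: float, j25: float,
                      pathway: Pathway, params: PhotoParams):
    """Leaf-level monthly GPP Q (gC m-2 mo-1 at f_L = 1, top-of-canopy light).

    Canopy GPP factorizes as f_L * Q because the chain is homogeneous in
    (absorbed light, capacity)."""
    d_raw = vpd_from_q(met.ta, met.qa, met.pa)
    d = np.maximum(d_raw, params.d_floor)
    kin = kinetics_at(met.ta, met.pa, v25, j25, params)
    beta = mwue_beta(met.swc, zeta0, params)
    iabs = met.swin * params.par_frac * params.umol_per_j
    gpp, st = gpp_given_intermediates(d, kin.K, kin.gamma_star, kin.eta_star,
                                      kin.vcmax, kin.jmax, met.ca_pp, beta, iabs,
                                      met.daytime_seconds, pathway, params)
    return gpp, st


def calibrate(met: MeteoMonth, reference_gpp, pathway: Pathway = Pathway.C3,
              params: PhotoParams = DEFAULT_PARAMS,
              zeta0_bounds=(5.0, 2000.0), extinction_bounds=(1e-6, 2.0),
              n_zeta_grid: int = 25, loss: str = "relative") -> SiteModel:
    """Fit the 12-month extinction climatology and zeta0 to reference GPP.

    Least squares on monthly GPP, pooled across years by calendar month.  The
    default ``loss='relative'`` weights residuals by the inverse reference
    (the maximum-likelihood choice under multiplicative flux-partitioning
    noise, and the one that lets dry low-GPP months constrain the
    soil-moisture constant); ``loss='absolute'`` is plain squared residuals.

    The problem separates: given zeta0 (which fixes coordination and
    leaf-level GPP), each calendar month's extinction is an independent 1-D
    fit of f_L(k_m) = 1 - exp(-k_m LAI) against reference/leaf GPP ratios.
    zeta0 is then found by a deterministic coarse log-grid search refined by
    bounded Brent — a global strategy on the same bounded objective the
    joint fit would use.  Calendar months with no usable reference data fall
    back to the annual mean extinction.

    Requires >= 12 months of overlapping data; raises
    :class:`CalibrationError` otherwise.
    """
    ref_gpp = np.asarray(reference_gpp, dtype=float)
    month = np.broadcast_to(met.month, ref_gpp.shape)
    valid = np.isfinite(ref_gpp) & (ref_gpp >= 0)
    if int(valid.sum()) < 12:
        raise CalibrationError(
            f"calibration needs >= 12 overlapping months, got {int(valid.sum())}")
    if np.nanvar(ref_gpp[valid]) == 0:
        warnings.warn("reference GPP has zero variance; extinction seasonality "
                      "is degenerate (flat fit)", stacklevel=2)
    lai = np.broadcast_to(met.lai, ref_gpp.shape)

    lo_k, hi_k = extinction_bounds
    if loss not in ("relative", "absolute"):
        raise ValueError(f"unknown loss {loss!r}")

    def fit_month(q, g, lai_m):
        """1-D (weighted) least squares for one calendar month's extinction."""
        w = 1.0 / np.maximum(g, 1e-3) if loss == "relative" else np.ones_like(g)

        def sse(k):
            f_l = 1.0 - np.exp(-k * lai_m)
            return float(np.sum((w * (f_l * q - g)) ** 2))
        res = minimize_scalar(sse, bounds=(lo_k, hi_k), method="bounded",
                              options={"xatol": 1e-12})
        return float(res.x), float(res.fun)

    def eval_zeta(log_z):
        zeta0 = float(np.exp(log_z))
        v25, j25, ref = coordinate_site(met, zeta0, pathway, params)
        q, _ = _leaf_monthly_gpp(met, zeta0, v25, j25, pathway, params)
        q = np.broadcast_to(q, ref_gpp.shape)
        ks = np.full(12, np.nan)
        total = 0.0
        for m in range(1, 13):
            sel = valid & (month == m)
            if not np.any(sel):
                continue
            ks[m - 1], fun = fit_month(q[sel], ref_gpp[sel], lai[sel])
            total += fun
        return total, ks, v25, j25, ref

    log_lo, log_hi = np.log(zeta0_bounds[0]), np.log(zeta0_bounds[1])
    grid = np.linspace(log_lo, log_hi, n_zeta_grid)
    sses = np.array([eval_zeta(lz)[0] for lz in grid])
    i = int(np.argmin(sses))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, n_zeta_grid - 1)]
    res = minimize_scalar(lambda lz: eval_zeta(lz)[0], bounds=(blo, bhi),
                          method="bounded", options={"xatol": 1e-11})
    if not np.isfinite(res.fun):
        raise CalibrationError(f"calibration did not converge (residual {res.fun!r})")
    total, ks, v25, j25, ref = eval_zeta(res.x)
    if np.all(np.isnan(ks)):
        raise CalibrationError("no calendar month had usable reference data")
    ks = np.where(np.isnan(ks), np.nanmean(ks), ks)
    return SiteModel(extinction=ks, zeta0=float(np.exp(res.x)), pathway=pathway,
                     vcmax25_ref=v25, jmax25_ref=j25,
                     peak_month=int(ref.month), ref_met=ref)


class CoordinationTimescale(str, Enum):
    """Acclimation timescale of the reference capacities.

    DECADAL (the adopted default): one coordination to the decadal-average
    environment of the peak-LAI month.  The alternatives re-coordinate with
    year-to-year peak-month CO2 (ANNUAL_CA), the full year-to-year
    peak-month environment (ANNUAL_ALL), month-to-month CO2 against the
    decadal peak-month climate (MONTHLY_CA), or the full month-to-month
    environment (MONTHLY_ALL).
    """

    DECADAL = "decadal"
    ANNUAL_CA = "annual_ca"
    ANNUAL_ALL = "annual_all"
    MONTHLY_CA = "monthly_ca"
    MONTHLY_ALL = "monthly_all"


def coordinate_series(met: MeteoMonth, years, zeta0: float,
                      timescale: CoordinationTimescale = CoordinationTimescale.DECADAL,
                      pathway: Pathway = Pathway.C3,
                      params: PhotoParams = DEFAULT_PARAMS):
    """Per-record reference capacities under a chosen acclimation timescale.

    Returns (vcmax25, jmax25) arrays aligned with the forcing records.
    Records whose environment admits no colimitation root (e.g. dark winter
    months under MONTHLY_ALL) fall back to the decadal solution.
    """
    timescale = CoordinationTimescale(timescale)
    years = np.asarray(years)
    n = len(years)
    ref = reference_environment(met)
    ppfd = params.par_frac * params.umol_per_j

    def solve(env: MeteoMonth):
        return coordinate_capacity(env, float(env.swin) * ppfd, zeta0,
                                   pathway, params)

    v_dec, j_dec = solve(ref)
    v = np.full(n, v_dec)
    j = np.full(n, j_dec)
    if timescale == CoordinationTimescale.DECADAL:
        return v, j

    month = np.broadcast_to(met.month, years.shape)
    ca = np.broadcast_to(met.ca, years.shape)
    peak = int(ref.month)
    for i in range(n):
        if timescale == CoordinationTimescale.ANNUAL_CA:
            sel = (years == years[i]) & (month == peak)
            if not np.any(sel):
                continue
            env = ref.replace(ca=np.mean(ca[sel]))
        elif timescale == CoordinationTimescale.ANNUAL_ALL:
            sub = _subset(met, (years == years[i]) & (month == peak))
            if sub is None:
                continue
            env = sub.mean()
        elif timescale == CoordinationTimescale.MONTHLY_CA:
            env = ref.replace(ca=ca[i])
        else:  # MONTHLY_ALL
            sub = _subset(met, np.arange(n) == i)
            env = sub.mean()
        try:
            v[i], j[i] = solve(env)
        except CalibrationError:
            pass  # keep the decadal fallback
    return v, j


def _subset(met: MeteoMonth, sel) -> Optional[MeteoMonth]:
    if not np.any(sel):
        return None
    shape = np.broadcast(met.month, met.lai, met.ta).shape
    kw = {}
    for k in ("ta", "swin", "pa", "qa", "swc", "ca", "lai", "month",
              "daytime_seconds"):
        kw[k] = np.broadcast_to(getattr(met, k), shape)[sel]
    return MeteoMonth(**kw)


def build_site(met: MeteoMonth, extinction, zeta0: float,
               pathway: Pathway = Pathway.C3,
               params: PhotoParams = DEFAULT_PARAMS) -> SiteModel:
    """Assemble an uncalibrated SiteModel with known extinction/zeta0,
    coordinating capacities from the forcing (used by the synthetic truth)."""
    v25, j25, ref = coordinate_site(met, zeta0, pathway, params)
    return SiteModel(extinction=np.asarray(extinction, dtype=float), zeta0=zeta0,
                     pathway=pathway, vcmax25_ref=v25, jmax25_ref=j25,
                     peak_month=int(ref.month), ref_met=ref)


# --------------------------------------------------------------------------
# annual aggregation
# --------------------------------------------------------------------------

@dataclass
class AnnualAggregate:
    years: np.ndarray
    gpp: np.ndarray          # gC m-2 yr-1; NaN for excluded years
    qualified: np.ndarray    # bool
    reasons: list = field(default_factory=list)


def annual_aggregate(gpp_monthly, years, months, growing_mask=None,
                     backup=None, max_growing_gaps: int = 1,
                     growing_threshold: float = 30.0) -> AnnualAggregate:
    """Aggregate monthly GPP (gC m-2 mo-1) to annual sums with gap rules.

    A growing-season month (climatological mean GPP > growing_threshold when
    growing_mask is not given) may be missing at most once per year; the
    single gap is backfilled from ``backup`` (the unfiltered low-quality
    series) when available, otherwise the year is excluded.  Two or more
    growing-season gaps exclude the year.  Missing non-growing-season months
    are filled with their calendar-month climatology.
    """
    g = np.asarray(gpp_monthly, dtype=float)
    years = np.asarray(years)
    months = np.asarray(months)
    uyears = np.unique(years)
    clim = np.full(12, np.nan)
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(g)
        if np.any(sel):
            clim[m - 1] = np.mean(g[sel])
    if growing_mask is None:
        growing_mask = clim > growing_threshold
    growing_mask = np.asarray(growing_mask, dtype=bool)

    out = np.full(uyears.shape, np.nan)
    qual = np.zeros(uyears.shape, dtype=bool)
    reasons = []
    for k, y in enumerate(uyears):
        vals = np.full(12, np.nan)
        for m in range(1, 13):
            sel = (years == y) & (months == m)
            if np.any(sel):
                vals[m - 1] = g[sel][0]
        gaps = np.flatnonzero(growing_mask & ~np.isfinite(vals))
        if gaps.size > max_growing_gaps:
            reasons.append((int(y), "excluded", f"{gaps.size} growing-season gaps"))
            continue
        if gaps.size > 0:
            filled = False
            if backup is not None:
                b = np.asarray(backup, dtype=float)
                m0 = gaps[0]
                sel = (years == y) & (months == m0 + 1)
                if np.any(sel) and np.isfinite(b[sel][0]):
                    vals[m0] = b[sel][0]
                    filled = True
                    reasons.append((int(y), "backfilled", f"month {m0 + 1} from low-quality data"))
            if not filled:
                reasons.append((int(y), "excluded", "growing-season gap without backup"))
                continue
        nong = ~growing_mask & ~np.isfinite(vals)
        vals[nong] = clim[nong]
        if np.any(~np.isfinite(vals)):
            reasons.append((int(y), "excluded", "unfillable months"))
            continue
        out[k] = np.sum(vals)
        qual[k] = True
    return AnnualAggregate(years=uyears, gpp=out, qualified=qual, reasons=reasons)
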
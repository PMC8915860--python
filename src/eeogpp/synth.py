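"""Synthetic forcing, flux-record and grid generators.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes: seasonal cycles, a secular CO2 ramp (shared
across sites — CO2 is well mixed), optional warming/greening trends, AR(1)
interannual anomalies per driver, FLUXNET-style half-hourly records with
quality-flag corruption and four GPP partitioning variants built from the
model's own truth, and a small latitude-gradient grid with a C4 mask.

Every stochastic operation is a pure function of (config, seed).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .canopy import SiteModel, build_site, monthly_gpp
from .meteo import MeteoMonth, saturation_vapour_pressure, q_from_vpd, vpd_from_q
from .params import DEFAULT_PARAMS, PhotoParams, M_CARBON
from .photo import Pathway

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic network.

    Defaults describe a mid-latitude, mesic, C3-dominated network over a
    FLUXNET2015-era study period with a rising CO2 ramp and trend-free,
    AR(1)-correlated interannual variability in the other drivers.
    """

    n_sites: int = 20
    start_year: int = 2001
    n_years: int = 14
    seed: int = 0

    # CO2 (shared, deterministic ramp + seasonal cycle)
    ca_start: float = 370.0        # ppm at the centre of the first year
    ca_trend: float = 2.0          # ppm yr-1
    ca_seasonal_amp: float = 2.5   # ppm

    # site geography
    lat_range: Tuple[float, float] = (35.0, 55.0)
    alt_range: Tuple[float, float] = (0.0, 800.0)

    # temperature (degC)
    ta_at_equator: float = 24.0
    ta_lat_slope: float = 0.35     # degC per degree latitude
    ta_seasonal_amp: float = 9.0
    ta_trend: float = 0.0          # K yr-1
    ta_sd: float = 0.4             # monthly AR(1) anomaly SD, K
    ta_ar1: float = 0.4

    # shortwave (W m-2, daytime mean)
    swin_mean: float = 190.0
    swin_seasonal_frac: float = 0.45
    swin_trend: float = 0.0
    swin_rel_sd: float = 0.03
    swin_ar1: float = 0.2

    # humidity
    rh_mean: float = 0.65
    qa_rel_sd: float = 0.03
    qa_ar1: float = 0.3
    qa_trend: float = 0.0          # relative yr-1

    # soil moisture (m3 m-3)
    swc_mean: float = 0.30
    swc_seasonal_amp: float = 0.04
    swc_sd: float = 0.02
    swc_ar1: float = 0.5
    swc_trend: float = 0.0

    # leaf area
    lai_max: float = 3.0
    lai_min_frac: float = 0.25
    lai_rel_sd: float = 0.02
    lai_trend: float = 0.0         # relative yr-1

    # daytime duration
    daylength_amp: float = 5.0     # hours, scaled by lat/60

    # truth site constants
    extinction_base: float = 0.55
    extinction_jitter: float = 0.10
    extinction_seasonal: float = 0.08
    zeta0_base: float = 146.0
    zeta0_jitter: float = 0.20
    c4_fraction: float = 0.0

    # fixture noise
    gpp_noise_sd: float = 0.05     # lognormal SD of monthly reference GPP
    variant_sd: float = 0.03       # lognormal spread of the four GPP variants
    qc_corrupt_rate: float = 0.02
    cadence_minutes: int = 30

    # grid mode
    grid_nlat: int = 10
    grid_nlon: int = 10
    grid_c4_fraction: float = 0.15


@dataclass
class SiteForcing:
    site_id: str
    lat: float
    years: np.ndarray           # per monthly record
    met: MeteoMonth


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) anomalies with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def _seasonality(month: np.ndarray, lat: float) -> np.ndarray:
    """+1 at the warm-season peak (July in the north, January in the south)."""
    phase = 7 if lat >= 0 else 1
    return np.cos(2.0 * np.pi * (month - phase) / 12.0)


def ca_series(cfg: SynthConfig, years: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Well-mixed monthly CO2: deterministic ramp plus a seasonal cycle whose
    annual mean cancels exactly, so the annual-mean trend is the configured
    ramp to machine precision."""
    yi = years - cfg.start_year
    t = yi + (months - 0.5) / 12.0
    seas = cfg.ca_seasonal_amp * np.cos(2.0 * np.pi * (months - 5) / 12.0)
    return cfg.ca_start + cfg.ca_trend * t + seas


def gen_forcing(cfg: SynthConfig, seed: Optional[int] = None) -> List[SiteForcing]:
    """Monthly daytime forcing for every site of the network."""
    seed = cfg.seed if seed is None else seed
    n = cfg.n_years * 12
    months = np.tile(np.arange(1, 13), cfg.n_years)
    years = np.repeat(np.arange(cfg.start_year, cfg.start_year + cfg.n_years), 12)
    yi = years - cfg.start_year + (months - 0.5) / 12.0
    ca = ca_series(cfg, years, months)

    out = []
    for i in range(cfg.n_sites):
        rng = np.random.default_rng([seed, i])
        lat = rng.uniform(*cfg.lat_range)
        alt = rng.uniform(*cfg.alt_range)
        pa = 101325.0 * np.exp(-alt / 8400.0)
        seas = _seasonality(months, lat)

        ta_clim = (cfg.ta_at_equator - cfg.ta_lat_slope * abs(lat)
                   + cfg.ta_seasonal_amp * seas)
        ta = ta_clim + cfg.ta_trend * yi + _ar1(rng, n, cfg.ta_ar1, cfg.ta_sd)

        swin = (cfg.swin_mean * (1.0 + cfg.swin_seasonal_frac * seas)
                * (1.0 + cfg.swin_trend * yi)
                * (1.0 + _ar1(rng, n, cfg.swin_ar1, cfg.swin_rel_sd)))
        swin = np.clip(swin, 5.0, None)

        qa_clim = 0.622 * cfg.rh_mean * saturation_vapour_pressure(ta_clim) / pa
        qa = qa_clim * (1.0 + cfg.qa_trend * yi) \
            * (1.0 + _ar1(rng, n, cfg.qa_ar1, cfg.qa_rel_sd))

        swc = np.clip(cfg.swc_mean - cfg.swc_seasonal_amp * seas
                      + cfg.swc_trend * yi + _ar1(rng, n, cfg.swc_ar1, cfg.swc_sd),
                      0.05, 0.60)

        lai_shape = cfg.lai_min_frac + (1 - cfg.lai_min_frac) * (0.5 * (1 + seas)) ** 1.5
        lai_max_i = cfg.lai_max * (1.0 + 0.15 * rng.uniform(-1, 1))
        lai = (lai_max_i * lai_shape * (1.0 + cfg.lai_trend * yi)
               * (1.0 + _ar1(rng, n, 0.3, cfg.lai_rel_sd)))
        lai = np.clip(lai, 0.05, None)

        daylength = 12.0 + cfg.daylength_amp * (lat / 60.0) * seas
        daytime_seconds = daylength * 3600.0 * DAYS_IN_MONTH[months - 1]

        met = MeteoMonth(ta=ta, swin=swin, pa=np.full(n, pa), qa=qa, swc=swc,
                         ca=ca, lai=lai, month=months,
                         daytime_seconds=daytime_seconds)
        out.append(SiteForcing(site_id=f"SY-{i:03d}", lat=float(lat),
                               years=years, met=met))
    return out


def gen_truth_sites(cfg: SynthConfig, forcing: Sequence[SiteForcing],
                    params: PhotoParams = DEFAULT_PARAMS,
                    seed: Optional[int] = None) -> List[SiteModel]:
    """True site constants (extinction climatology, zeta0, pathway) with
    capacities coordinated from each site's own forcing."""
    seed = cfg.seed if seed is None else seed
    n_c4 = int(round(cfg.c4_fraction * cfg.n_sites))
    sites = []
    for i, sf in enumerate(forcing):
        rng = np.random.default_rng([seed, 1000 + i])
        base = cfg.extinction_base * (1.0 + cfg.extinction_jitter * rng.uniform(-1, 1))
        k = base + cfg.extinction_seasonal * np.cos(2 * np.pi * (np.arange(12)) / 12.0)
        k = np.clip(k, 0.05, 2.0)
        zeta0 = cfg.zeta0_base * (1.0 + cfg.zeta0_jitter * rng.uniform(-1, 1))
        pathway = Pathway.C4 if i >= cfg.n_sites - n_c4 else Pathway.C3
        sites.append(build_site(sf.met, k, zeta0, pathway, params))
    return sites


def truth_gpp(sf: SiteForcing, site: SiteModel,
              params: PhotoParams = DEFAULT_PARAMS,
              noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Model-truth monthly GPP, optionally with multiplicative lognormal
    observation noise (the flux-partitioning spread)."""
    g = monthly_gpp(sf.met, site, params).gpp
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 2000])
        g = g * rng.lognormal(0.0, noise_sd, size=g.shape)
    return g


# --------------------------------------------------------------------------
# FLUXNET-style half-hourly fixture
# --------------------------------------------------------------------------

FLUX_COLUMNS = ["TIMESTAMP_START", "TA_F", "TA_F_QC", "SW_IN_F", "SW_IN_F_QC",
                "PA_F", "PA_F_QC", "VPD_F", "VPD_F_QC", "SWC_F_MDS_1",
                "SWC_F_MDS_1_QC", "NIGHT", "GPP_NT_VUT_MEAN", "GPP_DT_VUT_MEAN",
                "GPP_NT_CUT_MEAN", "GPP_DT_CUT_MEAN"]


@dataclass
class FluxFixture:
    records: pd.DataFrame          # FLUXNET FULLSET-style half-hourly table
    met: MeteoMonth                # monthly daytime truth driving the records
    years: np.ndarray
    site: SiteModel
    gpp_truth: np.ndarray          # gC m-2 mo-1, noise-free model truth


def gen_flux_fixture(cfg: SynthConfig, site_index: int = 0,
                     params: PhotoParams = DEFAULT_PARAMS,
                     corrupt_months: Optional[Dict[Tuple[int, int], float]] = None,
                     negative_gpp_months: Sequence[Tuple[int, int]] = (),
                     seed: Optional[int] = None) -> FluxFixture:
    """Half-hourly FLUXNET-style records whose monthly daytime aggregation
    reproduces the generating MeteoMonth and whose GPP variants are the
    model's own truth with partitioning spread.

    Driver units follow FLUXNET conventions: TA_F degC, SW_IN_F W m-2,
    PA_F kPa, VPD_F hPa, SWC_F_MDS_1 percent.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 3000 + site_index])
    sf = gen_forcing(cfg, seed)[site_index]
    step = cfg.cadence_minutes
    slots = np.arange(0, 24 * 60, step) / 60.0  # hours
    shape = np.sin(np.pi * (slots - 6.0) / 12.0)
    shape[(slots < 6.0) | (slots >= 18.0)] = 0.0
    night = (shape <= 0.0).astype(int)
    day_slots = shape > 0.0
    shape_mean = shape[day_slots].mean()
    slots_per_day = len(slots)

    # fixture daytime duration comes from the slot grid itself
    ds_per_day = day_slots.sum() * step * 60.0
    n = len(sf.years)
    months = sf.met.month
    ndays = np.array([calendar.monthrange(int(y), int(m))[1]
                      for y, m in zip(sf.years, months)])
    met = sf.met.replace(daytime_seconds=ds_per_day * ndays)
    rng_site = np.random.default_rng([seed, 1000 + site_index])
    base = cfg.extinction_base * (1.0 + cfg.extinction_jitter * rng_site.uniform(-1, 1))
    k_clim = np.clip(base + cfg.extinction_seasonal
                     * np.cos(2 * np.pi * np.arange(12) / 12.0), 0.05, 2.0)
    zeta0 = cfg.zeta0_base * (1.0 + cfg.zeta0_jitter * rng_site.uniform(-1, 1))
    site = build_site(met, k_clim, zeta0, Pathway.C3, params)
    gpp = monthly_gpp(met, site, params).gpp

    corrupt_months = corrupt_months or {}
    frames = []
    for r in range(n):
        y, m = int(sf.years[r]), int(months[r])
        nd = int(ndays[r])
        nrow = nd * slots_per_day
        t0 = pd.Timestamp(year=y, month=m, day=1)
        ts = t0 + pd.to_timedelta(np.arange(nrow) * step, unit="m")
        sl = np.tile(shape, nd)
        rate = gpp[r] / (met.daytime_seconds[r] * M_CARBON * 1e-6)  # umol m-2 s-1
        month_noise = rng.lognormal(0.0, cfg.gpp_noise_sd)
        variants = {}
        for v in ("GPP_NT_VUT_MEAN", "GPP_DT_VUT_MEAN", "GPP_NT_CUT_MEAN", "GPP_DT_CUT_MEAN"):
            mult = month_noise * rng.lognormal(0.0, cfg.variant_sd)
            variants[v] = rate * mult * sl / shape_mean
            if (y, m) in negative_gpp_months:
                variants[v] = np.full(nrow, -0.5)
        vpd_hpa = float(np.maximum(vpd_from_q(met.ta[r], met.qa[r], met.pa[r]), 0.0)) / 100.0
        df = pd.DataFrame({
            "TIMESTAMP_START": ts.strftime("%Y%m%d%H%M"),
            "TA_F": met.ta[r], "TA_F_QC": 0,
            "SW_IN_F": met.swin[r] * sl / shape_mean, "SW_IN_F_QC": 0,
            "PA_F": met.pa[r] / 1000.0, "PA_F_QC": 0,
            "VPD_F": vpd_hpa, "VPD_F_QC": 0,
            "SWC_F_MDS_1": met.swc[r] * 100.0, "SWC_F_MDS_1_QC": 0,
            "NIGHT": np.tile(night, nd),
            **variants,
        })
        rate_bad = corrupt_months.get((y, m), cfg.qc_corrupt_rate)
        if rate_bad > 0:
            bad = rng.random(nrow) < rate_bad
            which = rng.integers(0, 3, size=nrow)
            for j, col in enumerate(("TA_F_QC", "SW_IN_F_QC", "VPD_F_QC")):
                df.loc[bad & (which == j), col] = 2
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)[FLUX_COLUMNS]
    return FluxFixture(records=records, met=met, years=sf.years, site=site,
                       gpp_truth=gpp)


def meteo_from_monthly(monthly: pd.DataFrame, ca, lai) -> Tuple[MeteoMonth, np.ndarray]:
    """Bridge a fluxprep monthly table (FLUXNET units) plus external CO2 and
    LAI series to a MeteoMonth; returns (met, years)."""
    years = monthly.index.get_level_values("year").to_numpy()
    months = monthly.index.get_level_values("month").to_numpy()
    ta = monthly["TA_F"].to_numpy(dtype=float)
    pa = monthly["PA_F"].to_numpy(dtype=float) * 1000.0
    vpd = monthly["VPD_F"].to_numpy(dtype=float) * 100.0
    qa = q_from_vpd(ta, vpd, pa)
    met = MeteoMonth(ta=ta, swin=monthly["SW_IN_F"].to_numpy(dtype=float),
                     pa=pa, qa=qa,
                     swc=monthly["SWC_F_MDS_1"].to_numpy(dtype=float) / 100.0,
                     ca=np.broadcast_to(np.asarray(ca, dtype=float), ta.shape),
                     lai=np.broadcast_to(np.asarray(lai, dtype=float), ta.shape),
                     month=months,
                     daytime_seconds=monthly["daytime_seconds"].to_numpy(dtype=float))
    return met, years


# --------------------------------------------------------------------------
# gridded forcing
# --------------------------------------------------------------------------

def gen_grid(cfg: SynthConfig, seed: Optional[int] = None) -> xr.Dataset:
    """Small gridded monthly climatology spanning a latitudinal climate
    gradient (warm-wet at low lat/lon index, cold at high lat) with a C4 mask
    covering exactly the configured fraction of cells."""
    seed = cfg.seed if seed is None else seed
    nlat, nlon = cfg.grid_nlat, cfg.grid_nlon
    lat = np.linspace(0.0, 60.0, nlat)
    lon = np.linspace(0.0, 30.0, nlon)
    month = np.arange(1, 13)
    L, _ = np.meshgrid(lat, lon, indexing="ij")
    lon_frac = np.meshgrid(lat, np.linspace(0, 1, nlon), indexing="ij")[1]

    seas = np.cos(2 * np.pi * (month - 7) / 12.0)[:, None, None]
    ta = 27.0 - 0.40 * L + 7.0 * (L / 60.0) * seas
    swin = np.clip(250.0 - 1.3 * L + 60.0 * (L / 60.0) * seas, 20.0, None)
    rh = 0.80 - 0.35 * lon_frac
    pa = np.full((nlat, nlon), 101325.0)
    qa = 0.622 * rh * saturation_vapour_pressure(ta) / pa
    swc = np.clip(0.38 - 0.25 * lon_frac + 0.0 * seas, 0.08, None) * np.ones_like(ta)
    lai = np.clip((1.0 + 4.5 * (rh - 0.35)) * (0.45 + 0.55 * np.clip(seas, 0, 1))
                  * (1.0 - 0.3 * L / 90.0), 0.2, 6.0)
    daylength = 12.0 + 5.0 * (L / 60.0) * seas
    dts = daylength * 3600.0 * DAYS_IN_MONTH[:, None, None]

    ta_ann = ta.mean(axis=0)
    score = ta_ann - 25.0 * rh
    k = int(round(cfg.grid_c4_fraction * nlat * nlon))
    c4 = np.zeros((nlat, nlon), dtype=bool)
    if k > 0:
        idx = np.argsort(score.ravel())[::-1][:k]
        c4.ravel()[idx] = True

    biome = np.where(c4, 5, np.where(lai.max(axis=0) > 4.5, 0,
                     np.where(lai.max(axis=0) > 2.5, 1,
                     np.where(lai.max(axis=0) > 1.2, 2, 3))))

    return xr.Dataset(
        data_vars={
            "ta": (("month", "lat", "lon"), ta),
            "swin": (("month", "lat", "lon"), swin),
            "qa": (("month", "lat", "lon"), qa),
            "swc": (("month", "lat", "lon"), swc),
            "lai": (("month", "lat", "lon"), lai),
            "daytime_seconds": (("month", "lat", "lon"), dts),
            "pa": (("lat", "lon"), pa),
            "c4_mask": (("lat", "lon"), c4),
            "biome": (("lat", "lon"), biome),
        },
        coords={"month": month, "lat": lat, "lon": lon},
        attrs={"description": "synthetic latitude-gradient monthly climatology",
               "biome_codes": "0=EBF 1=OF 2=SW 3=GRA/CRO 5=C4"},
    )


def grid_cell_met(ds: xr.Dataset, i: int, j: int, ca: float = 400.0) -> MeteoMonth:
    """Extract one grid cell's 12-month climatology as a MeteoMonth."""
    return MeteoMonth(
        ta=ds["ta"][:, i, j].values, swin=ds["swin"][:, i, j].values,
        pa=np.full(12, float(ds["pa"][i, j])), qa=ds["qa"][:, i, j].values,
        swc=ds["swc"][:, i, j].values, ca=np.full(12, ca),
        lai=ds["lai"][:, i, j].values, month=np.arange(1, 13),
        daytime_seconds=ds["daytime_seconds"][:, i, j].values)


# --------------------------------------------------------------------------
# writers (plain-text formats plus NetCDF for grids)
# --------------------------------------------------------------------------

def write_fluxnet_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_fluxnet_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_co2_csv(years: np.ndarray, months: np.ndarray, ppm: np.ndarray,
                  path: str | Path) -> None:
    """Two-column monthly CO2 text file: 'YYYY-MM, ppm'."""
    with open(path, "w") as fh:
        fh.write("date,co2_ppm\n")
        for y, m, c in zip(years, months, ppm):
            fh.write(f"{int(y):04d}-{int(m):02d},{c:.3f}\n")


def read_co2_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    dt = pd.to_datetime(df["date"], format="%Y-%m")
    return pd.DataFrame({"year": dt.dt.year, "month": dt.dt.month,
                         "co2_ppm": df["co2_ppm"]})


def write_grid_netcdf(ds: xr.Dataset, path: str | Path) -> None:
    """NetCDF3 via the scipy backend (bools stored as int8)."""
    enc = ds.copy()
    enc["c4_mask"] = enc["c4_mask"].astype("i1")
    enc.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")
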
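"""Shared fixtures: small synthetic networks, random environment sweeps and a
hand-built flux-record builder with exactly controlled QC properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import eeogpp as e


@pytest.fixture(scope="session")
def small_cfg():
    return e.SynthConfig(n_sites=2, n_years=6, seed=3)


@pytest.fixture(scope="session")
def small_network(small_cfg):
    forcing = e.gen_forcing(small_cfg)
    sites = e.gen_truth_sites(small_cfg, forcing)
    return forcing, sites


@pytest.fixture(scope="session")
def site_and_forcing(small_network):
    forcing, sites = small_network
    return forcing[0], sites[0]


def random_environments(seed: int, n: int) -> e.MeteoMonth:
    """Broad, physically plausible random monthly environments."""
    rng = np.random.default_rng(seed)
    return e.MeteoMonth(
        ta=rng.uniform(2.0, 35.0, n),
        swin=rng.uniform(50.0, 350.0, n),
        pa=rng.uniform(9.0e4, 1.02e5, n),
        qa=rng.uniform(0.002, 0.015, n),
        swc=rng.uniform(0.08, 0.45, n),
        ca=rng.uniform(360.0, 430.0, n),
        lai=rng.uniform(0.3, 6.0, n),
        month=rng.integers(1, 13, n),
        daytime_seconds=np.full(n, 12 * 3600.0 * 30.4),
    )


@pytest.fixture(scope="session")
def env_sweep():
    return random_environments(11, 400)


# ---------------------------------------------------------------------------
# hand-built FLUXNET-style records with exact QC structure
# ---------------------------------------------------------------------------

def build_flux_records(year_months, gpp_rate=8.0, winter_rate=1.0,
                       bad_day_fraction=None, negative_months=(),
                       growing=range(4, 10)):
    """Half-hourly records with a square-wave day (06:00-17:30, 24 daytime
    slots/day) so good-quality fractions are exact rationals.

    bad_day_fraction: {(year, month): fraction of daytime slots with TA QC=2},
    applied to the first round(fraction * n_daytime_slots) daytime timestamps
    of the month so the achieved good-quality fraction is exact to 1/720.
    negative_months force all GPP variants negative.  Growing months carry
    ``gpp_rate`` umol m-2 s-1, non-growing ``winter_rate``.
    """
    bad_day_fraction = bad_day_fraction or {}
    frames = []
    for (y, m) in year_months:
        ndays = pd.Period(f"{y}-{m:02d}").days_in_month
        slots = np.arange(0, 48) * 30          # minutes of day
        hours = slots / 60.0
        day = (hours >= 6.0) & (hours < 18.0)  # 24 slots
        night = (~day).astype(int)
        nrow = ndays * 48
        ts = pd.Timestamp(year=y, month=m, day=1) + pd.to_timedelta(
            np.arange(nrow) * 30, unit="m")
        day_full = np.tile(day, ndays)
        rate = gpp_rate if m in growing else winter_rate
        if (y, m) in negative_months:
            rate = -0.5
        sw = np.where(day_full, 400.0, 0.0)
        qc = np.zeros(nrow, dtype=int)
        frac = bad_day_fraction.get((y, m), 0.0)
        if frac > 0:
            day_idx = np.flatnonzero(day_full)
            n_bad = int(round(frac * day_idx.size))
            qc[day_idx[:n_bad]] = 2
        gpp = np.where(day_full, rate, 0.0)
        frames.append(pd.DataFrame({
            "TIMESTAMP_START": ts.strftime("%Y%m%d%H%M"),
            "TA_F": 15.0, "TA_F_QC": qc,
            "SW_IN_F": sw, "SW_IN_F_QC": 0,
            "PA_F": 101.325, "PA_F_QC": 0,
            "VPD_F": 8.0, "VPD_F_QC": 0,
            "SWC_F_MDS_1": 25.0, "SWC_F_MDS_1_QC": 0,
            "NIGHT": np.tile(night, ndays),
            "GPP_NT_VUT_MEAN": gpp, "GPP_DT_VUT_MEAN": gpp,
            "GPP_NT_CUT_MEAN": gpp, "GPP_DT_CUT_MEAN": gpp,
        }))
    return pd.concat(frames, ignore_index=True)


def all_months(years):
    return [(y, m) for y in years for m in range(1, 13)]
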
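"""Seven-step preprocessing of FLUXNET2015-style half-hourly/hourly records.

The pipeline mirrors the standard eddy-covariance workflow for monthly
optimality modelling:

1. quality filtering — keep timestamps where TA_F, SW_IN_F and VPD_F are
   measured or gap-filled with good quality (QC flag 0 or 1); the same mask
   is applied to the GPP variants;
2. monthly daytime averaging — two-stage: average each time-of-day slot
   across the days of the month, then average across daytime slots (daytime
   = nighttime flag 0 and SW_IN > 0 W m-2);
3. reference GPP — the mean of the four partitioning/friction-velocity
   variants (NT/DT x VUT/CUT); individual variants are retained for
   uncertainty propagation;
4. month exclusion — months with < 50% good-quality daytime timestamps
   (exactly 50% is retained) or negative reference GPP are dropped;
5. annual aggregation — at most one missing growing-season month per year
   (growing season: climatological reference GPP > 30 gC m-2 mo-1), the
   single gap backfilled from the unfiltered series, otherwise the year is
   excluded;
6. annual anomalies — deviation from the site's study-period mean;
7. site screening — keep sites with more than 5 qualified years (>= 6).

Every exclusion carries a machine-readable reason code, and a no-filter
pathway (steps 1, 2-QC and 4 skipped) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .params import M_CARBON

#: FLUXNET FULLSET-style column names consumed by the pipeline
QC_DRIVERS = ("TA_F", "SW_IN_F", "VPD_F")
DRIVER_COLS = ("TA_F", "SW_IN_F", "PA_F", "VPD_F", "SWC_F_MDS_1")
GPP_VARIANTS = ("GPP_NT_VUT_MEAN", "GPP_DT_VUT_MEAN",
                "GPP_NT_CUT_MEAN", "GPP_DT_CUT_MEAN")

GOOD_FLAGS = frozenset({0, 1})
VALID_FLAGS = frozenset({0, 1, 2, 3})


@dataclass
class PipelineResult:
    monthly: pd.DataFrame             # per (year, month) daytime means + QC
    monthly_unfiltered: pd.DataFrame  # same without steps 1/4 (backup series)
    annual: pd.DataFrame              # per year: gpp, qualified, reason
    anomalies: pd.Series              # qualified years only
    exclusions: pd.DataFrame          # machine-readable exclusion log
    site_qualified: bool = False
    n_qualified_years: int = 0


def _parse_timestamps(df: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(df["TIMESTAMP_START"].astype(str), format="%Y%m%d%H%M")


def detect_timestep_minutes(df: pd.DataFrame) -> int:
    """Auto-detect half-hourly vs hourly cadence from timestamp spacing."""
    ts = _parse_timestamps(df).sort_values()
    dt = ts.diff().dropna().dt.total_seconds() / 60.0
    step = int(dt.mode().iloc[0])
    if step not in (30, 60):
        raise DomainError("TIMESTAMP_START", f"unsupported cadence {step} min")
    return step


def qc_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Step 1: mask records whose TA/SW_IN/VPD quality flag is not 0 or 1.

    Returns a copy with a boolean ``qc_ok`` column and the driver and GPP
    values of failing rows set to NaN (rows are kept: masked + retained =
    input).  Unknown flag values raise a parse error.
    """
    out = df.copy()
    ok = pd.Series(True, index=df.index)
    for col in QC_DRIVERS:
        flags = df[f"{col}_QC"]
        bad_codes = set(pd.unique(flags.dropna())) - VALID_FLAGS
        if bad_codes:
            raise DomainError(f"{col}_QC", f"unknown quality flag values {sorted(bad_codes)}")
        ok &= flags.isin(GOOD_FLAGS)
    out["qc_ok"] = ok
    masked = ~ok
    for col in list(DRIVER_COLS) + list(GPP_VARIANTS):
        out.loc[masked, col] = np.nan
    return out


def _daytime_mask(df: pd.DataFrame) -> pd.Series:
    """Daytime = nighttime flag 0 AND shortwave > 0 W m-2."""
    return (df["NIGHT"] == 0) & (df["SW_IN_F_RAW"] > 0)


def monthly_daytime_mean(df: pd.DataFrame, apply_qc: bool = True) -> pd.DataFrame:
    """Steps 2+3: two-stage monthly daytime means of drivers and GPP.

    For each calendar (year, month) and each time-of-day slot, values are
    first averaged across days, then the slot means are averaged across
    daytime slots.  ``SW_IN_F_RAW`` (the unmasked shortwave) determines
    daytime so that QC masking cannot change the day/night split.  Also
    reports the good-quality fraction of daytime timestamps, the reference
    GPP (mean of the four variants, converted to gC m-2 mo-1 with the
    month's daytime duration) and daytime seconds.
    """
    step_min = detect_timestep_minutes(df)
    d = df.copy()
    if "SW_IN_F_RAW" not in d.columns:
        d["SW_IN_F_RAW"] = df["SW_IN_F"]
    ts = _parse_timestamps(d)
    d["year"] = ts.dt.year
    d["month"] = ts.dt.month
    d["tod"] = ts.dt.hour * 60 + ts.dt.minute
    d["daytime"] = _daytime_mask(d)
    if "qc_ok" not in d.columns:
        d["qc_ok"] = True
    if not apply_qc:
        d["qc_ok"] = True

    value_cols = list(DRIVER_COLS) + list(GPP_VARIANTS)
    rows = []
    for (y, m), g in d.groupby(["year", "month"]):
        day = g[g["daytime"]]
        n_day = len(day)
        if n_day == 0:
            rows.append({"year": y, "month": m, "empty": True,
                         "good_fraction": np.nan, "daytime_seconds": 0.0,
                         **{c: np.nan for c in value_cols},
                         "GPP_REF": np.nan})
            continue
        good_fraction = float(day["qc_ok"].mean())
        use = day if not apply_qc else day[day["qc_ok"]]
        slot = use.groupby("tod")[value_cols].mean()     # stage 1: across days
        means = slot.mean(axis=0)                        # stage 2: across slots
        n_days = g["TIMESTAMP_START"].astype(str).str[:8].nunique()
        daytime_seconds = n_day * step_min * 60.0
        gpp_rates = means[list(GPP_VARIANTS)]
        to_mass = daytime_seconds * M_CARBON * 1e-6      # umol m-2 s-1 -> gC m-2 mo-1
        rec = {"year": y, "month": m, "empty": False,
               "good_fraction": good_fraction,
               "daytime_seconds": daytime_seconds, "n_days": n_days}
        for c in DRIVER_COLS:
            rec[c] = float(means[c])
        for c in GPP_VARIANTS:
            rec[f"{c}_MONTHLY"] = float(gpp_rates[c]) * to_mass
            rec[c] = float(gpp_rates[c])
        rec["GPP_REF"] = float(np.mean([rec[f"{c}_MONTHLY"] for c in GPP_VARIANTS]))
        rows.append(rec)
    out = pd.DataFrame(rows).set_index(["year", "month"]).sort_index()
    return out


def reference_gpp(monthly: pd.DataFrame) -> pd.Series:
    """Step 3: reference GPP = mean of the four partitioning variants."""
    cols = [f"{c}_MONTHLY" for c in GPP_VARIANTS]
    return monthly[cols].mean(axis=1)


def exclude_months(monthly: pd.DataFrame, min_good_fraction: float = 0.5
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Step 4: drop months with < min_good_fraction good daytime timestamps
    (the boundary is retained) or negative reference GPP.

    Returns (retained, exclusion_log); retained months keep their values,
    excluded months appear in the log with a reason code.
    """
    log = []
    keep = pd.Series(True, index=monthly.index)
    for idx, row in monthly.iterrows():
        if bool(row.get("empty", False)):
            keep[idx] = False
            log.append({"year": idx[0], "month": idx[1], "reason": "no_daytime_data"})
        elif row["good_fraction"] < min_good_fraction:
            keep[idx] = False
            log.append({"year": idx[0], "month": idx[1], "reason": "low_quality_fraction",
                        "good_fraction": row["good_fraction"]})
        elif row["GPP_REF"] < 0:
            keep[idx] = False
            log.append({"year": idx[0], "month": idx[1], "reason": "negative_gpp",
                        "gpp": row["GPP_REF"]})
    return monthly[keep], pd.DataFrame(log, columns=["year", "month", "reason",
                                                     "good_fraction", "gpp"])


def growing_season_mask(monthly: pd.DataFrame,
                        threshold: float = 30.0) -> np.ndarray:
    """Growing season: calendar months whose climatological mean reference
    GPP (computed after step 4) exceeds the threshold (gC m-2 mo-1)."""
    clim = np.full(12, np.nan)
    ref = monthly["GPP_REF"]
    for m in range(1, 13):
        vals = ref[ref.index.get_level_values("month") == m]
        if len(vals):
            clim[m - 1] = vals.mean()
    with np.errstate(invalid="ignore"):
        return clim > threshold


def annual_screen(monthly: pd.DataFrame, unfiltered: pd.DataFrame,
                  growing_threshold: float = 30.0,
                  min_years: int = 5) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Steps 5+7: annual aggregation with growing-season gap rules and the
    more-than-``min_years``-qualified-years site screen (strict: > 5 means
    >= 6 years qualify).

    Returns (annual table, exclusion log, site_qualified).
    """
    gmask = growing_season_mask(monthly, growing_threshold)
    years = sorted(set(monthly.index.get_level_values("year"))
                   | set(unfiltered.index.get_level_values("year")))
    rows, log = [], []
    for y in years:
        vals = np.full(12, np.nan)
        for m in range(1, 13):
            if (y, m) in monthly.index:
                vals[m - 1] = monthly.loc[(y, m), "GPP_REF"]
        gaps = np.flatnonzero(gmask & ~np.isfinite(vals))
        status, reason = "qualified", ""
        if gaps.size > 1:
            status, reason = "excluded", f"{gaps.size}_growing_season_gaps"
        elif gaps.size == 1:
            m0 = int(gaps[0]) + 1
            if (y, m0) in unfiltered.index and np.isfinite(unfiltered.loc[(y, m0), "GPP_REF"]):
                vals[gaps[0]] = unfiltered.loc[(y, m0), "GPP_REF"]
                reason = f"backfilled_month_{m0}"
                log.append({"year": y, "month": m0, "reason": "backfilled_low_quality"})
            else:
                status, reason = "excluded", "growing_season_gap_no_backup"
        if status == "qualified":
            # fill non-growing-season gaps with the month's climatology
            for m in range(1, 13):
                if not np.isfinite(vals[m - 1]) and not gmask[m - 1]:
                    mm = monthly[monthly.index.get_level_values("month") == m]["GPP_REF"]
                    vals[m - 1] = mm.mean() if len(mm) else 0.0
            if np.any(~np.isfinite(vals)):
                status, reason = "excluded", "unfillable_months"
        if status == "excluded":
            log.append({"year": y, "month": np.nan, "reason": reason})
        rows.append({"year": y, "gpp": float(np.nansum(vals)) if status == "qualified" else np.nan,
                     "qualified": status == "qualified", "note": reason})
    annual = pd.DataFrame(rows).set_index("year")
    n_qual = int(annual["qualified"].sum())
    return annual, pd.DataFrame(log, columns=["year", "month", "reason"]), n_qual > min_years


def anomalies(annual: pd.DataFrame) -> pd.Series:
    """Step 6: deviation of qualified annual GPP from the study-period mean."""
    g = annual.loc[annual["qualified"], "gpp"]
    return g - g.mean()


def run_pipeline(df: pd.DataFrame, apply_filters: bool = True,
                 min_good_fraction: float = 0.5,
                 growing_threshold: float = 30.0,
                 min_years: int = 5) -> PipelineResult:
    """Run the full seven-step chain on one site's records.

    ``apply_filters=False`` selects the no-filter pathway (steps 1, the QC
    part of 2, and 4 skipped), which retains a superset of months.  SWC
    carries no quality filter (not part of the step-1 list); this is noted
    in the exclusion log.
    """
    d = df.copy()
    d["SW_IN_F_RAW"] = d["SW_IN_F"]

    unfiltered_monthly = monthly_daytime_mean(d, apply_qc=False)
    unfiltered_monthly = unfiltered_monthly[~unfiltered_monthly["empty"].astype(bool)]

    logs = [pd.DataFrame([{"year": np.nan, "month": np.nan,
                           "reason": "swc_no_qc_filter_applied"}])]
    if apply_filters:
        filt = qc_filter(d)
        monthly = monthly_daytime_mean(filt, apply_qc=True)
        monthly, excl = exclude_months(monthly, min_good_fraction)
        logs.append(excl[["year", "month", "reason"]])
    else:
        monthly = unfiltered_monthly.copy()

    annual, alog, qualified = annual_screen(monthly, unfiltered_monthly,
                                            growing_threshold, min_years)
    logs.append(alog)
    anom = anomalies(annual)
    exclusions = pd.concat(logs, ignore_index=True)
    return PipelineResult(monthly=monthly, monthly_unfiltered=unfiltered_monthly,
                          annual=annual, anomalies=anom, exclusions=exclusions,
                          site_qualified=qualified,
                          n_qualified_years=int(annual["qualified"].sum()))
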
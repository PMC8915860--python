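"""Monthly daytime forcing container and psychrometric conversions.

The model is driven by seven measurable variables: atmospheric CO2 (ca, ppm),
leaf area index (LAI), air temperature (Ta, degC), volumetric soil water
content (SWC), specific humidity (qa, kg/kg), incident shortwave radiation
(SWin, W m-2) and surface pressure (P, Pa).  Vapour pressure deficit is derived
from (Ta, qa, P); pipelines that carry VPD convert it to qa on ingest so that
the driver list stays the measured seven.

All conversion functions are written to accept numpy arrays and to remain
holomorphic in their arguments (no abs/max on values), which lets the
sensitivity module push complex-step perturbations through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError

#: Magnus coefficients for saturation vapour pressure over water
_MAGNUS_A = 611.2     # Pa
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12    # degC

#: Ratio of molar masses of water vapour and dry air
EPS_WV = 0.622


def saturation_vapour_pressure(ta):
    """Saturation vapour pressure over water (Pa) at air temperature ta (degC)."""
    ta = np.asarray(ta)
    return _MAGNUS_A * np.exp(_MAGNUS_B * ta / (_MAGNUS_C + ta))


def vapour_pressure_from_q(qa, pa):
    """Actual vapour pressure e (Pa) from specific humidity qa and pressure pa."""
    qa = np.asarray(qa)
    return qa * pa / (EPS_WV + (1.0 - EPS_WV) * qa)


def vpd_from_q(ta, qa, pa):
    """Vapour pressure deficit D = esat(Ta) - e(qa, P), in Pa (can be negative)."""
    return saturation_vapour_pressure(ta) - vapour_pressure_from_q(qa, pa)


def q_from_vpd(ta, vpd, pa):
    """Invert the psychrometric conversion: specific humidity from VPD."""
    e = saturation_vapour_pressure(ta) - np.asarray(vpd)
    return EPS_WV * e / (pa - (1.0 - EPS_WV) * e)


def co2_partial_pressure(ca_ppm, pa):
    """Convert CO2 mole fraction (ppm) to partial pressure (Pa)."""
    return np.asarray(ca_ppm) * 1e-6 * pa


@dataclass
class MeteoMonth:
    """One or more monthly daytime forcing records (fields broadcastable arrays).

    Attributes
    ----------
    ta : air temperature, degC
    swin : daytime incident shortwave radiation, W m-2
    pa : surface pressure, Pa
    qa : specific humidity, kg kg-1
    swc : volumetric soil water content, m3 m-3
    ca : atmospheric CO2, ppm
    lai : leaf area index, m2 m-2
    month : calendar month 1..12 (selects the extinction climatology entry)
    daytime_seconds : seconds of daytime in the month, used to integrate the
        daytime-mean assimilation rate to a monthly carbon mass.
    """

    ta: np.ndarray
    swin: np.ndarray
    pa: np.ndarray
    qa: np.ndarray
    swc: np.ndarray
    ca: np.ndarray
    lai: np.ndarray
    month: np.ndarray = field(default_factory=lambda: np.array(7))
    daytime_seconds: np.ndarray = field(default_factory=lambda: np.array(12 * 3600.0 * 30.4))

    def __post_init__(self):
        for name in ("ta", "swin", "pa", "qa", "swc", "ca", "lai", "month", "daytime_seconds"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)
                    if name != "month" else np.asarray(getattr(self, name)))
        self.month = np.asarray(self.month, dtype=int)
        if np.any(self.swin < 0):
            raise DomainError("swin", "shortwave radiation must be >= 0")
        if np.any((self.swc < 0) | (self.swc > 1)):
            raise DomainError("swc", "volumetric soil water content must lie in [0, 1]")
        if np.any(self.lai < 0):
            raise DomainError("lai", "leaf area index must be >= 0")
        if np.any(self.pa <= 0):
            raise DomainError("pa", "surface pressure must be > 0")

    @classmethod
    def from_vpd(cls, ta, swin, pa, vpd, swc, ca, lai, **kw) -> "MeteoMonth":
        """Build a record from VPD instead of specific humidity."""
        qa = q_from_vpd(np.asarray(ta, dtype=float), vpd, np.asarray(pa, dtype=float))
        return cls(ta=ta, swin=swin, pa=pa, qa=qa, swc=swc, ca=ca, lai=lai, **kw)

    @property
    def vpd(self) -> np.ndarray:
        """Derived vapour pressure deficit, Pa (unfloored)."""
        return vpd_from_q(self.ta, self.qa, self.pa)

    @property
    def ca_pp(self) -> np.ndarray:
        """CO2 partial pressure, Pa."""
        return co2_partial_pressure(self.ca, self.pa)

    def replace(self, **kw) -> "MeteoMonth":
        return replace(self, **kw)

    def mean(self) -> "MeteoMonth":
        """Collapse to a single averaged record (month set to the modal month)."""
        vals, counts = np.unique(self.month, return_counts=True)
        return MeteoMonth(
            ta=np.mean(self.ta), swin=np.mean(self.swin), pa=np.mean(self.pa),
            qa=np.mean(self.qa), swc=np.mean(self.swc), ca=np.mean(self.ca),
            lai=np.mean(self.lai), month=int(vals[np.argmax(counts)]),
            daytime_seconds=np.mean(self.daytime_seconds),
        )
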
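"""Leaf-level photosynthesis under eco-evolutionary optimality.

The model couples Fick's law, A = g (ca - ci), with the Farquhar-von
Caemmerer-Berry (FvCB) scheme, A = min(Ac, Aj), under three optimality
constraints:

* stomatal conductance maximizes net carbon gain against water loss
  (theory 1), which together with
* least-cost optimization of ci (theory 2) yields the closed-form optimal
  ci/ca ratio  chi = G/ca + (1 - G/ca) * xi / (xi + sqrt(D)),
  xi = sqrt(beta (K + G) / (1.6 eta*)),  G = Gamma*;
* coordination of photosynthetic capacity (theory 3): reference Vcmax25 (and
  Jmax25 through a fixed per-site reference ratio) is solved so the Rubisco-
  and RuBP-regeneration-limited rates co-limit under the average daytime
  environment of the reference (peak-LAI) month.

The marginal water-use efficiency entering the cost ratio beta responds to
soil moisture through a logistic in SWC scaled by the site constant zeta0.

All arithmetic is elementwise numpy and holomorphic, so the sensitivity module
can differentiate the chain by complex step; branching (the FvCB min, the VPD
floor) is decided on real parts only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError, ParameterError
from .meteo import MeteoMonth, vpd_from_q
from .params import DEFAULT_PARAMS, PhotoParams, R_GAS, T_REF


class Pathway(str, Enum):
    C3 = "C3"
    C4 = "C4"


#: limitation flag values
RUBISCO = "rubisco_limited"
RUBP = "rubp_limited"


@dataclass
class Kinetics:
    """Temperature-dependent kinetic state of the leaf.

    K and gamma_star in Pa; eta_star dimensionless (=1 at 298.15 K);
    vcmax/jmax in umol m-2 s-1 at the ambient temperature.
    """

    K: np.ndarray
    gamma_star: np.ndarray
    eta_star: np.ndarray
    vcmax: np.ndarray
    jmax: np.ndarray


@dataclass
class LeafState:
    """Solved optimality state at leaf level."""

    chi: np.ndarray
    ci: np.ndarray            # Pa
    g: np.ndarray             # umol m-2 s-1 Pa-1 (conductance per unit pp gradient)
    A: np.ndarray             # umol CO2 m-2 s-1
    limitation: np.ndarray    # RUBISCO or RUBP
    mwue: np.ndarray          # cost-ratio beta, mWUE-related


# --------------------------------------------------------------------------
# temperature responses
# --------------------------------------------------------------------------

#: IAPWS-style correlation for liquid-water dynamic viscosity at 0.1 MPa,
#: sum of a_i * (T/300)^{b_i} in uPa s; accurate to well under 1% over 0-40 degC.
_VISC_TERMS = ((280.68, -1.9), (511.45, -7.7), (61.131, -19.6), (0.45903, -40.0))


def water_viscosity(tk):
    """Dynamic viscosity of liquid water (Pa s) at temperature tk (K)."""
    tau = np.asarray(tk) / 300.0
    mu = sum(a * tau ** b for a, b in _VISC_TERMS)
    return mu * 1e-6


def eta_star(ta):
    """Viscosity of water at Ta (degC) relative to the 298.15 K reference."""
    return water_viscosity(np.asarray(ta) + 273.15) / water_viscosity(T_REF)


def arrhenius(x25, ha, tk):
    """Arrhenius scaling of a rate/constant from its 25 degC value."""
    return x25 * np.exp(ha / R_GAS * (1.0 / T_REF - 1.0 / tk))


def peaked_arrhenius(ha, hd, ds, tk):
    """Peaked Arrhenius factor (=1 at 298.15 K) for Vcmax/Jmax."""
    arr = np.exp(ha / R_GAS * (1.0 / T_REF - 1.0 / tk))
    num = 1.0 + np.exp((T_REF * ds - hd) / (T_REF * R_GAS))
    den = 1.0 + np.exp((tk * ds - hd) / (tk * R_GAS))
    return arr * num / den


def f_vcmax(ta, params: PhotoParams = DEFAULT_PARAMS):
    return peaked_arrhenius(params.ha_vcmax, params.hd_vcmax, params.ds_vcmax,
                            np.asarray(ta) + 273.15)


def f_jmax(ta, params: PhotoParams = DEFAULT_PARAMS):
    return peaked_arrhenius(params.ha_jmax, params.hd_jmax, params.ds_jmax,
                            np.asarray(ta) + 273.15)


def kinetics_at(ta, pa, vcmax25=0.0, jmax25=0.0,
                params: PhotoParams = DEFAULT_PARAMS) -> Kinetics:
    """Kinetic state at air temperature ta (degC) and pressure pa (Pa).

    Raises :class:`DomainError` when the real part of ta is outside the
    supported range.
    """
    ta_r = np.real(np.asarray(ta))
    if np.any(ta_r < params.ta_min) or np.any(ta_r > params.ta_max):
        raise DomainError("ta", f"air temperature outside [{params.ta_min}, {params.ta_max}] degC")
    if np.any(np.real(np.asarray(pa)) <= 0):
        raise DomainError("pa", "surface pressure must be > 0")
    tk = np.asarray(ta) + 273.15
    kc = arrhenius(params.kc25, params.ha_kc, tk)
    ko = arrhenius(params.ko25, params.ha_ko, tk)
    po2 = params.o2_mole_frac * np.asarray(pa)
    K = kc * (1.0 + po2 / ko)
    gs = arrhenius(params.gammastar25, params.ha_gammastar, tk)
    return Kinetics(
        K=K, gamma_star=gs, eta_star=eta_star(ta),
        vcmax=np.asarray(vcmax25) * f_vcmax(ta, params),
        jmax=np.asarray(jmax25) * f_jmax(ta, params),
    )


# --------------------------------------------------------------------------
# optimality: mWUE cost ratio and optimal chi
# --------------------------------------------------------------------------

def mwue_beta(swc, zeta0, params: PhotoParams = DEFAULT_PARAMS):
    """mWUE-related unit-cost ratio as a logistic function of soil moisture.

    beta = zeta0 * sigmoid(steep * (SWC - half)); monotone non-decreasing in
    SWC and saturating at zeta0 for wet soil.
    """
    if np.any(np.real(np.asarray(zeta0)) <= 0):
        raise ParameterError("zeta0 must be > 0")
    swc_r = np.real(np.asarray(swc))
    if np.any((swc_r < 0) | (swc_r > 1)):
        raise DomainError("swc", "SWC must lie in [0, 1]")
    z = params.swc_steep * (np.asarray(swc) - params.swc_half)
    return np.asarray(zeta0) / (1.0 + np.exp(-z))


def optimal_chi_values(ca_pp, d, K, gamma_star, eta_st, beta_cost,
                       params: PhotoParams = DEFAULT_PARAMS, floor: bool = True):
    """Closed-form least-cost chi from partial pressures (all Pa).

    chi = G/ca + (1 - G/ca) * xi / (xi + sqrt(D)),
    xi  = sqrt(beta (K + G) / (1.6 eta*)).

    D is floored at params.d_floor (decided on real parts) unless the caller
    has already applied the floor (``floor=False``, used by the GPP chain so
    the clamp is decided exactly once); beta_cost <= 0 raises
    :class:`ParameterError`.
    """
    if np.any(np.real(np.asarray(beta_cost)) <= 0):
        raise ParameterError("beta_cost must be > 0")
    d = np.asarray(d)
    if floor:
        d = np.where(np.real(d) < params.d_floor, params.d_floor, d)
        if np.any(np.real(d) <= 0):
            raise DomainError("d", "vapour pressure deficit must be > 0 after flooring")
    xi = np.sqrt(beta_cost * (K + gamma_star) / (params.transp_factor * eta_st))
    gfrac = gamma_star / ca_pp
    chi = gfrac + (1.0 - gfrac) * xi / (xi + np.sqrt(d))
    return chi, chi * ca_pp


def optimal_chi(met: MeteoMonth, kin: Kinetics, beta_cost,
                params: PhotoParams = DEFAULT_PARAMS):
    """Optimal ci/ca ratio and ci (Pa) for a forcing record."""
    d = vpd_from_q(met.ta, met.qa, met.pa)
    return optimal_chi_values(met.ca_pp, d, kin.K, kin.gamma_star, kin.eta_star,
                              beta_cost, params)


def chi_cost(ci, ca_pp, d, K, gamma_star, eta_st, beta_cost,
             params: PhotoParams = DEFAULT_PARAMS):
    """Summed unit cost of transpiration and carboxylation per unit assimilation.

    Q(ci) = 1.6 eta* D / (ca - ci) + beta (ci + K) / (ci - Gamma*),
    with beta the carboxylation:transpiration unit-cost ratio (the
    mWUE-related constant).  The closed form in :func:`optimal_chi_values` is
    its argmin; this function exists so tests can verify that by brute force.
    """
    d = np.maximum(d, params.d_floor)
    return (params.transp_factor * eta_st * d / (ca_pp - ci)
            + beta_cost * (ci + K) / (ci - gamma_star))


# --------------------------------------------------------------------------
# FvCB assimilation
# --------------------------------------------------------------------------

def electron_transport(iabs, jmax, params: PhotoParams = DEFAULT_PARAMS):
    """Electron transport rate J from absorbed light via a non-rectangular
    hyperbola with curvature theta and quantum yield phi, capped by jmax."""
    a = params.phi_j * np.asarray(iabs)
    b = np.asarray(jmax)
    th = params.theta_j
    disc = (a + b) ** 2 - 4.0 * th * a * b
    return (a + b - np.sqrt(disc)) / (2.0 * th)


def assimilation_rates(ci, iabs, kin: Kinetics, pathway: Pathway = Pathway.C3,
                       params: PhotoParams = DEFAULT_PARAMS):
    """Rubisco-limited and RuBP-regeneration-limited rates (Ac, Aj)."""
    j = electron_transport(iabs, kin.jmax, params)
    if pathway == Pathway.C4:
        # CO2-concentrating pump: carboxylation saturates at low ci, so both
        # branches share a fast-saturating ci response and no photorespiration
        # term; beta_CO2 stays positive but small.
        s = np.asarray(ci) / (np.asarray(ci) + params.c4_ksat)
        return kin.vcmax * s, (j / 4.0) * s
    ac = kin.vcmax * (ci - kin.gamma_star) / (ci + kin.K)
    aj = (j / 4.0) * (ci - kin.gamma_star) / (ci + 2.0 * kin.gamma_star)
    return ac, aj


def assimilate(ci, iabs, kin: Kinetics, pathway: Pathway = Pathway.C3,
               params: PhotoParams = DEFAULT_PARAMS):
    """A = min(Ac, Aj) with the limitation flag of the active branch.

    ci < Gamma* yields A <= 0 and is flagged, not raised.
    """
    ac, aj = assimilation_rates(ci, iabs, kin, pathway, params)
    rub = np.real(ac) <= np.real(aj)
    a = np.where(rub, ac, aj)
    limitation = np.where(rub, RUBISCO, RUBP)
    return a, limitation


def assimilate_c3(ci, iabs, kin: Kinetics, params: PhotoParams = DEFAULT_PARAMS):
    return assimilate(ci, iabs, kin, Pathway.C3, params)


def assimilate_c4(ci, iabs, kin: Kinetics, params: PhotoParams = DEFAULT_PARAMS):
    return assimilate(ci, iabs, kin, Pathway.C4, params)


def stomatal_g(a, ca_pp, ci):
    """Fick inversion g = A / (ca - ci), partial-pressure basis.

    Raises :class:`DomainError` when the gradient is degenerate (ca <= ci).
    """
    grad = np.asarray(ca_pp) - np.asarray(ci)
    if np.any(np.real(grad) <= 0):
        raise DomainError("ca_pp", "degenerate gradient: ca partial pressure must exceed ci")
    return np.asarray(a) / grad


def solve_leaf(met: MeteoMonth, kin: Kinetics, zeta0: float, iabs,
               pathway: Pathway = Pathway.C3,
               params: PhotoParams = DEFAULT_PARAMS) -> LeafState:
    """Full leaf-level optimality solution for a forcing record.

    Chains the mWUE cost ratio, the least-cost chi, FvCB assimilation and
    the Fick inversion of stomatal conductance; the returned state satisfies
    A = g (ca - ci) identically.
    """
    beta = mwue_beta(met.swc, zeta0, params)
    chi, ci = optimal_chi(met, kin, beta, params)
    a, lim = assimilate(ci, iabs, kin, pathway, params)
    g = stomatal_g(a, met.ca_pp, ci)
    return LeafState(chi=chi, ci=ci, g=g, A=a, limitation=lim, mwue=beta)


# --------------------------------------------------------------------------
# coordination (theory 3)
# --------------------------------------------------------------------------

def reference_rjv(ta_ref, params: PhotoParams = DEFAULT_PARAMS) -> float:
    """Fixed per-site reference Jmax25/Vcmax25 ratio from the growth
    temperature of the reference month."""
    return params.rjv_intercept - params.rjv_slope * float(np.real(ta_ref))


def coordinate_capacity(ref_met: MeteoMonth, iabs_ref, zeta0=None,
                        pathway: Pathway = Pathway.C3,
                        params: PhotoParams = DEFAULT_PARAMS,
                        vmax_bracket: Tuple[float, float] = (1e-3, 2000.0)):
    """Solve reference Vcmax25 (and Jmax25) for colimitation Ac = Aj.

    The reference environment is the decadal average daytime condition of the
    peak-LAI month; iabs_ref is the absorbed photon flux there (umol m-2 s-1).
    Jmax25 = rjv * Vcmax25 with the per-site reference ratio from
    :func:`reference_rjv`.  Returns (vcmax25, jmax25).
    """
    iabs_ref = float(iabs_ref)
    if iabs_ref <= 0:
        raise CalibrationError(
            f"coordination impossible: non-positive reference light (month {int(ref_met.month)})")
    if zeta0 is None:
        zeta0 = params.zeta0_default
    if pathway == Pathway.C4:
        # The CO2-pump form shares one ci response between both branches, so
        # colimitation reduces to Vcmax = J/4 at the reference light.  Size
        # Jmax to the reference photon supply (J at its colimitation point of
        # the hyperbola) and Vcmax from it; Ac = Aj holds by construction and
        # the reference ratio Jmax25/Vcmax25 stays fixed per site.
        fv = float(f_vcmax(ref_met.ta, params))
        fj = float(f_jmax(ref_met.ta, params))
        jmax_ref = params.phi_j * iabs_ref
        jmax25 = jmax_ref / fj
        j_ref = float(electron_transport(iabs_ref, jmax_ref, params))
        vcmax25 = j_ref / 4.0 / fv
        return float(vcmax25), float(jmax25)
    rjv = reference_rjv(ref_met.ta, params)
    kin0 = kinetics_at(ref_met.ta, ref_met.pa, 1.0, rjv, params)
    beta = mwue_beta(ref_met.swc, zeta0, params)
    chi, ci = optimal_chi(ref_met, kin0, beta, params)

    def residual(v25):
        kin = Kinetics(K=kin0.K, gamma_star=kin0.gamma_star, eta_star=kin0.eta_star,
                       vcmax=v25 * kin0.vcmax, jmax=v25 * kin0.jmax)
        ac, aj = assimilation_rates(ci, iabs_ref, kin, pathway, params)
        return float(ac - aj)

    lo, hi = vmax_bracket
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"no colimitation root in [{lo}, {hi}] for reference month {int(ref_met.month)} "
            f"(residuals {flo:.3g}, {fhi:.3g})")
    v25 = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(v25), float(v25 * rjv)
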
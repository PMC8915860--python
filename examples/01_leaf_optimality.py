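"""Leaf-level optimality: kinetics, the least-cost ci/ca ratio, and FvCB
assimilation.

Builds one warm, moderately dry daytime environment, solves the optimal
stomatal state and prints the pieces of the chain.
"""

import numpy as np

import eeogpp as e

ta, pa = 22.0, 101325.0          # degC, Pa
vpd = 900.0                      # Pa
ca_ppm, swc = 400.0, 0.28

kin = e.kinetics_at(ta, pa, vcmax25=60.0, jmax25=110.0)
print(f"Kinetics at {ta} C: K = {float(kin.K):.2f} Pa, "
      f"Gamma* = {float(kin.gamma_star):.2f} Pa, eta* = {float(kin.eta_star):.3f}")
# K and Gamma* rise with temperature (Arrhenius); eta* is the water-viscosity
# ratio scaling the transpiration cost (1 exactly at 25 C).

beta = float(e.mwue_beta(swc, 146.0))
ca_pp = ca_ppm * 1e-6 * pa
chi, ci = e.optimal_chi_values(ca_pp, vpd, kin.K, kin.gamma_star,
                               kin.eta_star, beta)
print(f"mWUE cost ratio beta(SWC={swc}) = {beta:.1f}; "
      f"optimal chi = {float(chi):.3f}, ci = {float(ci):.2f} Pa")
# chi ~0.6-0.8 is the familiar C3 range; drier air (higher VPD) or drier
# soil (lower beta) pushes chi down.

iabs = 1000.0                    # absorbed photons, umol m-2 s-1
a, lim = e.assimilate_c3(ci, iabs, kin)
g = e.stomatal_g(a, ca_pp, ci)
print(f"A = {float(a):.2f} umol m-2 s-1 ({str(lim)}), "
      f"g = {float(g):.3f} umol m-2 s-1 Pa-1")
print(f"Fick check: g*(ca - ci) = {float(g * (ca_pp - ci)):.2f} == A")

for d in (300.0, 900.0, 2700.0):
    chi_d, _ = e.optimal_chi_values(ca_pp, d, kin.K, kin.gamma_star,
                                    kin.eta_star, beta)
    print(f"  VPD = {d:6.0f} Pa -> chi = {float(chi_d):.3f}")
# chi falls monotonically as the air dries: water gets expensive relative
# to carbon.
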
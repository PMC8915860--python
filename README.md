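# eeogpp

Eco-evolutionary optimality (EEO) diagnostics of gross primary production
(GPP) and its CO2-fertilization sensitivity, for ecosystem ecologists and
carbon-cycle modellers who want an *analytic*, calibratable model of canopy
photosynthesis driven entirely by measurable variables — atmospheric CO2
(c_a), leaf area index (LAI), air temperature (T_a), volumetric soil water
content (SWC), specific humidity (q_a), incident shortwave radiation
(SW_in) and surface pressure (P) — plus the attribution and trend machinery
needed to ask: *how much of the observed GPP trend is CO2 fertilization?*

## The model

Leaf gas exchange follows Fick's law coupled to the
Farquhar–von Caemmerer–Berry (FvCB) scheme,

    A = g (c_a − c_i) = min(A_c, A_j),
    A_c = V_cmax (c_i − Γ*)/(c_i + K),
    A_j = (J/4) (c_i − Γ*)/(c_i + 2Γ*),

under three optimality constraints:

1. **Stomatal optimality** — g maximizes carbon gain net of water loss;
   together with
2. **least-cost optimality** of c_i (minimizing transpiration +
   carboxylation cost per unit assimilation) this fixes the marginal
   water-use efficiency and gives the closed-form optimum

       χ = c_i/c_a = Γ*/c_a + (1 − Γ*/c_a) · ξ/(ξ + √D),
       ξ = √( β (K + Γ*) / (1.6 η*) ),

   where D is vapour pressure deficit, η* the water-viscosity ratio
   (T_a-dependent, 1 at 25 °C) and β the unit-cost ratio, made
   soil-moisture dependent through a logistic in SWC scaled by a calibrated
   site constant ζ₀;
3. **coordination** — reference capacities V_cmax25 (and J_max25 through a
   fixed per-site reference ratio) are solved so that A_c = A_j under the
   decadal-average daytime environment of the peak-LAI month, while the
   instantaneous kinetics (K, Γ*, η*, V_cmax, J_max) track monthly
   temperature.

The canopy is a single big leaf: a calibrated monthly extinction
climatology k_m sets the absorbed-light fraction f_L = 1 − exp(−k_m·LAI),
which scales both absorbed photons and canopy capacity, so canopy GPP stays
analytic. Because the chain is closed-form, the partial derivatives of GPP
to all seven drivers are exact; ∂GPP/∂c_a is the CO2-fertilization
sensitivity **β_CO2** (gC m⁻² yr⁻¹ ppm⁻¹). Changes decompose linearly,

    ΔGPP = Σ_i (∂GPP/∂x_i) Δx_i,

the temperature term splits by the chain rule into five pathways (via D,
via V_cmax/J_max, via K, via Γ*, via η*), and GPP–CO2 response ratios are
summarized by β^ln = ln(GPP_e/GPP_s) / ln(c_a,e/c_a,s) (apparent: all
drivers varying; direct: CO2-only).

The package also implements the supporting workflow: seven-step
FLUXNET2015-style preprocessing (QC filtering, two-stage monthly daytime
means, reference-GPP construction, exclusion and gap rules, annual
anomalies), Mann–Kendall/Sen trend statistics with 50% site-year
resampling, IAV (1 SD of the detrended series), and a synthetic-data
generator that produces monthly networks, half-hourly FLUXNET-style
records and small gridded climatologies so every stage is testable without
downloads.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_co2_sensitivity.py` prints:

```
beta_CO2 (C3) = 2.05 gC m-2 yr-1 per ppm (analytic vs finite-difference max rel err 4.2e-08)
beta_CO2 (C4) = 0.35 gC m-2 yr-1 per ppm
dGPP/dTa in the brightest month = 8.82 gC m-2 mo-1 K-1, split:
  via_d             -4.502
  via_capacity     +24.446
  via_k            -10.530
  via_gamma_star    -1.272
  via_eta_star      +0.683
  pathway sum       +8.824  (closes on the total)
```

The C3 sensitivity of ~2 gC m⁻² yr⁻¹ per ppm at a mid-latitude site, the
several-fold weaker C4 response (the CO2-concentrating pump saturates
carboxylation), and a warming response dominated by the capacity pathway
and opposed by the VPD and kinetics pathways are the qualitative signatures
the framework is built to expose. `examples/04_network_attribution.py`
runs a 20-site, 14-year synthetic network with a 2 ppm yr⁻¹ CO2 ramp and
attributes its GPP trend: the CO2 term carries ~+3.9 of the +4.1
gC m⁻² yr⁻² aggregated trend and the factorial and partial-derivative CO2
estimates agree within a few percent, with β_dir^ln ≈ 0.5 (GPP rising
about half as fast, proportionally, as CO2).

## Layout

```
src/eeogpp/
  photo.py        leaf kinetics, least-cost chi, FvCB, coordination
  canopy.py       big-leaf upscaling, monthly GPP, calibration, aggregation
  sensitivity.py  analytic/FD partials, Ta pathways, attribution, beta_ln
  fluxprep.py     FLUXNET-style seven-step preprocessing
  trends.py       Mann-Kendall/Sen, site-year resampling, IAV
  synth.py        synthetic networks, flux records, grids, writers
docs/methods.md   model description, parameter choices, limitations
examples/         one narrative script per capability
tests/            pytest suite (unit, property and acceptance tests)
```
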
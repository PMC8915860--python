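# Methods

This note records the model as implemented, the parameter choices that
matter, the numerical decisions, and what the synthetic experiments do and
do not demonstrate.

## Leaf model

Assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited FvCB rates, with Fick's law `A = g(c_a − c_i)`
closing the diffusion side (boundary-layer and mesophyll resistances are
neglected; CO2 is carried internally as partial pressure, ppm × P × 1e-6,
so surface pressure enters only through partial pressures and humidity
conversions). Kinetics:

* `K = K_c (1 + pO2/K_o)` and `Γ*` follow Arrhenius responses with
  Bernacchi-type constants (25 °C values in Pa: K_c 39.97, K_o 27480,
  Γ* 4.332; activation energies 79.43, 36.38, 37.83 kJ mol⁻¹).
* `V_cmax`, `J_max` use a peaked Arrhenius (H_a 71.5/49.9 kJ mol⁻¹,
  H_d 200 kJ mol⁻¹, ΔS 641.6/640.9 J mol⁻¹ K⁻¹), equal to 1 at 25 °C.
* `η*` is liquid-water dynamic viscosity at T_a divided by its 298.15 K
  value, from the IAPWS-style four-term power-law correlation (accurate to
  well under 1% over 0–40 °C; exactly 1 at 25 °C by construction).
* Electron transport is a non-rectangular hyperbola in absorbed photons
  with curvature θ = 0.85 and quantum yield φ = 0.30 mol e⁻ (mol photon)⁻¹,
  capped by J_max.

The least-cost optimum is the closed form
`χ = Γ*/c_a + (1 − Γ*/c_a)·ξ/(ξ+√D)`, `ξ = √(β(K+Γ*)/(1.6 η*))`, the
argmin of the unit cost `1.6 η* D/(c_a−c_i) + β (c_i+K)/(c_i−Γ*)` — β is
the carboxylation:transpiration unit-cost ratio, i.e. the mWUE-related
constant. D is floored at 10 Pa (monthly daytime means are never truly
saturated; the floor avoids the singular D→0 limit). Soil-moisture stress
enters through `β(SWC) = ζ₀ / (1 + exp(−k(SWC − x₀)))` with k = 20 per
unit SWC and x₀ = 0.15 m³ m⁻³: stress builds below ~0.25, halves the cost
ratio at 0.15 and saturates by field capacity. These two shape constants
are model constants; ζ₀ is the calibrated site parameter (default 146, the
magnitude familiar from least-cost optimality calibrations). The exact
shape is a design choice; its consequences for identifiability are
discussed below.

**C4 (experimental).** A single-enzyme CO2-saturating approximation:
both branches share the fast-saturating factor `c_i/(c_i + K4)`, K4 = 2 Pa,
and no photorespiration term. This guarantees a positive but several-fold
weaker CO2 sensitivity than matched C3 — the qualitative behaviour of the
C4 pump — and is not intended as a mechanistic C4 model.

## Coordination and the reference ratio

Reference capacities acclimate decadally: `V_cmax25` is solved by
bracketed root-finding so that A_c = A_j under the average daytime
environment of the climatological peak-LAI month, with
`J_max25 = r_JV · V_cmax25`. One equation cannot fix two capacities, so
the reference ratio comes from the growth-temperature acclimation
relation `r_JV = 2.59 − 0.035·T_ref` evaluated at the reference month —
fixed per site, spatially varying, and derived from reference conditions
rather than prescribed globally. For C4 the colimitation condition
degenerates (both branches share one c_i factor), so J_max is sized to the
reference photon supply and V_cmax = J_ref/4; A_c = A_j still holds
exactly at the reference state. Colimitation residuals are at machine
precision (the acceptance tolerance is 1e-6).

A consequence worth knowing: at *exactly* the reference climatological
state the model sits on the A_c = A_j kink, where one-sided derivatives
differ. Sensitivities are therefore best evaluated on observed monthly
states (generically off the kink), not on the climatology of the
coordination month itself.

## Canopy upscaling and calibration

Big leaf, one layer: the monthly extinction factor k_m (the calibrated
climatology of canopy shape × zenith angle) gives
`f_L = 1 − exp(−k_m·LAI)`; absorbed photons are
`SW_in × 0.45 (PAR fraction) × 4.57 µmol J⁻¹ × f_L`, and canopy capacity
scales with the same f_L. The electron-transport hyperbola is homogeneous
of degree one in (light, J_max), so canopy assimilation equals f_L times
the leaf rate at top-of-canopy light — the property that keeps the chain
analytic and makes k_m cancel from the colimitation condition. Monthly GPP
integrates the daytime-mean rate over the month's daytime seconds
(supplied by the forcing; the flux-record pipeline derives it from the
data's own daytime timestamps).

Calibration fits the 12 k_m values (pooled across years by calendar month)
and ζ₀ to a monthly reference GPP series. The objective is weighted least
squares with inverse-reference weights — the maximum-likelihood choice
under multiplicative (lognormal) partitioning noise, which also lets dry
low-GPP months inform ζ₀; unweighted least squares is selectable. The
problem separates: given ζ₀ (which fixes coordination and the leaf-level
series), each k_m is an independent bounded 1-D fit (k_m ∈ (0, 2]); ζ₀ is
found by a deterministic coarse grid on log ζ₀ ∈ [log 5, log 2000]
refined by bounded Brent. This is globally robust and reproducible;
a multistart joint optimizer would minimize the same bounded objective.
Calendar months with no usable reference data fall back to the annual
mean extinction; a zero-variance reference triggers a warning and a flat
fit.

**Identifiability.** Noise-free synthetic truth is recovered to ~1e-8.
With 5% multiplicative monthly noise, a 30-year record recovers the
extinction climatology to ~1% mean absolute error (a 14-year record gives
~2–3%: the error is ≈ noise/√n_years ÷ dln f_L/dln k ≈ 0.5). ζ₀ is
fundamentally different: its log-log leverage on GPP,
dlnGPP/dlnζ₀ ≈ 0.1–0.25, is largely collinear with the twelve monthly
extinction scales, so only within-calendar-month interannual SWC variation
identifies it. A numerical Cramér–Rao bound at a 30-year water-limited
site (SWC traversing 0.05–0.30) gives σ(ln ζ₀) ≈ 14% for *any* estimator
at 5% noise — so ζ₀ recoveries scatter by ~2–35% across noise
realizations, and a "2% recovery" of ζ₀ from monthly data of realistic
length is not statistically attainable. This does not propagate to the
CO2 sensitivity: across noisy and rescaled calibration references the
absolute β_CO2 moves <5% and β_CO2 per unit GPP is invariant to ~0.03%
under pure rescaling (the paper-level claim that the analytic sensitivity
is insensitive to the GPP used for calibration). The recovery experiment
uses a water-limited site because at a mesic site SWC never leaves the
logistic plateau and ζ₀ is wholly unidentifiable — an identifiability
requirement of the experiment, not a tuning choice.

## Sensitivities

The analytic mode differentiates the closed-form chain by complex step
(step 1e-30·scale on a holomorphic implementation): exact to machine
precision, with no subtractive cancellation. The finite-difference mode is
an independent central-difference oracle with per-driver steps
(ca 0.1 ppm, T_a 1e-4 K, SWC 1e-4, q_a 1e-7, SW_in 0.05 W m⁻², P 2 Pa,
LAI 1e-3), sized so truncation stays near 1e-6 relative even in low-VPD
months, where the chain's curvature in D is sharpest, while difference
round-off stays ~1e-11. The two modes agree to <1e-5 relative across
broad random-environment sweeps.

Derivatives of the piecewise model are **branch-conditional**: the FvCB
min, the D floor and the GPP positivity clip are decided once at the
evaluation point and pinned during perturbed evaluations. This matches
the convention that the capacity pathway swaps V_cmax for J_max under
light limitation, and it is the only coherent definition at points within
a finite-difference step of the A_c = A_j crossover. Unpinned difference
quotients agree with the analytic values wherever the branch is stable
across the stencil (tests assert both). Coordination is frozen during
differentiation — capacities respond to temperature only through the
instantaneous response — mirroring the decadal-acclimation assumption.

Temperature enters GPP only through (D, K, Γ*, η*, capacity), so the
five chain-rule pathways close on the total ∂GPP/∂T_a to machine
precision by construction; the closure is still asserted at 1e-6 as an
integration check. `ta_pathways` accepts an override for ∂D/∂T_a so
constructions that co-vary humidity to hold D fixed yield a D pathway of
exactly zero.

Attribution follows the univariate factorial recipe (one driver
time-varying, the others at calendar-month climatology; the Sen trend of
the resulting annual GPP is that driver's contribution; "aggregated" is
the exact sum), with the partial-derivative CO2 estimate
(β_CO2 × Sen trend of annual CO2) as a cross-check. Network series are
cross-site means of per-site annual anomalies. β^ln endpoints default to
the Sen-fit values at the first and last study year (noise-robust); raw
endpoint years are selectable. Per-factor IAV is |annual partial| × 1 SD
of the Sen-detrended annual driver.

## Preprocessing and trend statistics

The flux pipeline implements: QC flags {0,1} required on TA/SW_IN/VPD
(masking drivers and GPP alike; SWC carries no QC, and the exclusion log
notes this); two-stage monthly daytime means (slot across days, then
across daytime slots; daytime = nighttime flag 0 and SW_IN > 0, with
cadence auto-detected); reference GPP as the mean of the four
NT/DT × VUT/CUT variants; exclusion of months with good-quality fraction
< 50% (exactly 50% retained — literal reading) or negative GPP; annual
aggregation allowing at most one missing growing-season month
(climatological reference GPP > 30 gC m⁻² mo⁻¹), backfilled from the
unfiltered series, missing non-growing months filled with their monthly
climatology; anomalies as deviations from the site's study-period mean;
and a site screen of more than 5 qualified years (≥ 6, strict reading).
Every exclusion carries a reason code; a no-filter pathway retains a
strict superset of months for comparison.

Trend testing is Mann–Kendall with tie-corrected variance and continuity
correction, the Sen (median-of-pairwise-slopes) estimator, and optional
trend-free prewhitening (off by default for synthetic data whose AR
structure is known). Resampling keeps ⌈n/2⌉ years per site without
replacement, never mixing years across sites; site anomalies are taken
against the full-record site mean so a noiseless common trend yields
identical draws; 2,000 draws by default (the published-scale 200,000 is a
parameter). IAV is 1 SD of Sen-detrended residuals.

## Synthetic data

The generator emulates: a shared deterministic CO2 ramp (370 ppm + 2 ppm
yr⁻¹ by default, with a seasonal cycle whose annual mean cancels exactly),
site climatologies over a 35–55° latitude band, seasonal cycles in all
drivers, stationary monthly AR(1) anomalies (defaults: T_a 0.4 K (ρ 0.4),
SW_in 3% (ρ 0.2), q_a 3% (ρ 0.3), SWC 0.02 m³ m⁻³ (ρ 0.5), LAI 2%),
optional secular trends per driver, and truth GPP produced by the model
itself from known site constants (extinction base 0.55 ± jitter and a mild
seasonal cycle; ζ₀ 146 ± 20%). Half-hourly fixtures add sinusoidal diurnal
shortwave and GPP shapes whose discrete daytime-slot means reproduce the
monthly values exactly, nighttime flags, four lognormal GPP variants
(shared month noise 5%, variant spread 3%) and configurable QC corruption;
the grid mode spans an equator-to-60° × humid-to-dry gradient with an
exact-count C4 mask. Every stochastic operation is a pure function of
(config, seed).

What passing these tests shows — and does not. The synthetic network
matches the *assumed* statistical structure of the analysis
(well-mixed CO2, stationary climate anomalies, multiplicative partitioning
noise, model-generated GPP). It does not contain disturbance or management
history, trends in cloudiness, instrument drift, partitioning bias
correlated with climate, or model-structure error; recovery results
therefore validate the machinery (estimators, derivatives, bookkeeping),
not the realism of the model for any particular site. The CO2-only
attribution experiment uses deterministic seasonal climatologies for the
non-CO2 drivers — the construction that guarantees a clean decomposition;
with realistic stationary variability the CO2 share of a 14-year
aggregated trend scatters around ~85–100% because finite-sample Sen
slopes of stationary drivers are not exactly zero (the acceptance script
reports both numbers).

## Numerical details and edge cases

* Domain checks name the offending field (T_a outside [−40, 60] °C,
  non-positive pressure, SWC outside [0, 1], β ≤ 0, degenerate Fick
  gradient c_a ≤ c_i); missing drivers flag the month rather than raise.
* c_i < Γ* yields A ≤ 0 and is flagged, not raised; GPP is clipped at 0
  with the clip pinned during differentiation.
* Ties A_c = A_j are labelled Rubisco-limited (light-saturated).
* Coordination brackets V_cmax25 in [1e-3, 2000] µmol m⁻² s⁻¹ and fails
  loudly (with the site/month) when no colimitation root exists, e.g.
  zero reference light.
* The calibration inner 1-D fits use bounded Brent to xatol 1e-12; the
  outer ζ₀ search refines a 25-point log grid to xatol 1e-11.
* Problem sizes in the default test run and acceptance script (1000-point
  oracle sweeps, 20 × 14 site-years, one 30-year calibration record, 2000
  resampling draws) keep the whole suite under a minute while leaving
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

Big-leaf, single-layer radiative transfer (no sunlit/shaded split, no
clumping); no mesophyll or boundary-layer resistance; nutrient effects
only implicitly through LAI and coordination; the C4 scheme is a
placeholder shape, flagged experimental; the mWUE–SWC logistic shape is a
design choice whose site constant is weakly identified from monthly data
(see above); alternative coordination timescales (annual/monthly CO2 or
full-environment acclimation) are expressible by recoordinating with
different reference environments but only the decadal peak-LAI default is
hardened by tests.
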
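"""Model constants and tunable parameters.

All kinetic constants, light-response parameters and numerical knobs live in a
single :class:`PhotoParams` table so they can be inspected, serialized to YAML
and swapped without touching the model code.  Defaults follow widely used
conventions in the optimality-photosynthesis literature: Bernacchi-type
Arrhenius responses for the Rubisco kinetics, a peaked Arrhenius for the
capacities with entropy terms from growth-temperature acclimation studies, and
a non-rectangular hyperbola for the light response of electron transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Universal gas constant, J mol-1 K-1
R_GAS = 8.31446
#: Reference temperature for 25 degC kinetics, K
T_REF = 298.15
#: Molar mass of carbon, g mol-1
M_CARBON = 12.011


@dataclass
class PhotoParams:
    """Kinetic constants and numerical settings of the photosynthesis model.

    Units: energies J mol-1, pressures Pa, temperatures degC unless noted.
    """

    # --- Rubisco kinetics (Bernacchi-type, values at 25 degC in Pa) ---
    kc25: float = 39.97           # Michaelis constant for CO2
    ha_kc: float = 79430.0
    ko25: float = 27480.0         # Michaelis constant for O2
    ha_ko: float = 36380.0
    gammastar25: float = 4.332    # CO2 compensation point
    ha_gammastar: float = 37830.0
    o2_mole_frac: float = 0.2095  # atmospheric O2 mole fraction

    # --- Capacity temperature response (peaked Arrhenius) ---
    ha_vcmax: float = 71513.0
    hd_vcmax: float = 200000.0
    ds_vcmax: float = 641.64      # entropy term, J mol-1 K-1
    ha_jmax: float = 49884.0
    hd_jmax: float = 200000.0
    ds_jmax: float = 640.95

    # Reference Jmax/Vcmax ratio as a linear function of the growth
    # (reference-month) temperature: rjv25 = rjv_intercept - rjv_slope * Tg
    rjv_intercept: float = 2.59
    rjv_slope: float = 0.035

    # --- Light response ---
    phi_j: float = 0.30           # quantum yield of electron transport, mol e- / mol photon
    theta_j: float = 0.85         # curvature of the non-rectangular hyperbola
    par_frac: float = 0.45        # PAR fraction of shortwave
    umol_per_j: float = 4.57      # photon content of PAR, umol J-1

    # --- Stomatal optimization ---
    d_floor: float = 10.0         # Pa; floor on vapour pressure deficit
    transp_factor: float = 1.6    # water/CO2 diffusivity ratio in the unit cost

    # --- mWUE soil-moisture logistic ---
    swc_half: float = 0.15        # SWC at half of the asymptotic cost ratio
    swc_steep: float = 20.0       # logistic steepness, per unit SWC
    zeta0_default: float = 146.0  # default site cost-ratio constant

    # --- C4 approximation (experimental) ---
    c4_ksat: float = 2.0          # Pa; ci half-saturation of the CO2 pump

    # --- Input domain ---
    ta_min: float = -40.0
    ta_max: float = 60.0

    # --- Finite-difference oracle steps, per driver ---
    # Sized so central-difference truncation stays well below 1e-5 relative
    # even in low-VPD months (where the chain's curvature in D is sharpest)
    # while round-off in the difference remains orders of magnitude smaller.
    fd_steps: dict = field(default_factory=lambda: {
        "ca": 0.1,      # ppm
        "ta": 1e-4,     # K
        "swc": 1e-4,    # m3 m-3
        "qa": 1e-7,     # kg kg-1
        "swin": 0.05,   # W m-2
        "pa": 2.0,      # Pa
        "lai": 1e-3,    # m2 m-2
    })

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhotoParams":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


DEFAULT_PARAMS = PhotoParams()
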
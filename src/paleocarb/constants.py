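"""Fixed constants, modern anchors, and declared closure constants.

Everything here is immutable per run and recorded in output metadata.  Two
groups live in this module:

* **Fixed constants** of the model: the 28 permil carbonate--organic burial
  offset, the modern mantle delta13C, the redox-budget anchor fluxes, and the
  eon-wise prescription of atmospheric O2.
* **Closure constants** of the plumbing (silicate weathering, seafloor
  dissolution, carbonate precipitation kinetics, heatflow, metamorphic and
  subduction rate anchors, carbonate chemistry).  These are the package's own
  declared closures; they are exposed through the scenario configuration so a
  user can swap them without touching code.
"""

from __future__ import annotations

import math

# --- isotope bookkeeping -------------------------------------------------
DELTA_ORG_OFFSET = 28.0          # permil, buried carbonate minus buried organic
DELTA_MANTLE_MOD = -5.5          # permil vs VPDB, modern mantle carbon

# --- redox-budget anchors (mol O2-equivalents / yr) ----------------------
F_BURIAL_OTHER_MOD = 5.2e12      # O2 from sulfide + Fe(II) burial, modern
F_REDUCED_MOD = 2.4e12           # O2 consumed by reduced volcanic gases, modern
NPP_MOD = 4.0e15                 # mol C/yr, modern net primary productivity

# --- prescribed atmospheric O2 (PAL = present atmospheric level) ---------
PO2_ARCHEAN = 1e-9
PO2_PHANEROZOIC = 1.0
OXW_EXPONENT_DEFAULT = 0.3       # O2 power-law exponent of oxidative weathering
PO2_RAMP_HALFWIDTH = 0.025       # Ga; 50 Myr smooth step at 2.5 and 0.5 Ga
GOE_AGE = 2.5                    # Ga, Archean -> Proterozoic pO2 step
NOE_AGE = 0.5                    # Ga, Proterozoic -> Phanerozoic pO2 step

# --- time conventions ----------------------------------------------------
T_START = 4.1                    # Ga, model initialization
AGE_EARTH = 4.5                  # Ga, used in the heatflow closure
ARCHEAN_WINDOW = (3.8, 2.5)      # Ga, averaging window for "Archean" K_oxy
FORG_RAMP_HALFWIDTH = 0.025      # Ga, smoothing of the f_org epoch boundaries

# --- modern reference reservoirs (Table of shipped constraints) ----------
R_ORG_MOD = 1.66e21              # mol C, crustal organic carbon
R_CARB_MOD = 9.4e21              # mol C, crustal carbonate carbon
R_MANTLE_MOD = 2.0e22            # mol C, mantle carbon
R_ORG_INIT = 1.0e18              # mol C, negligible-but-positive seed at 4.1 Ga

# --- modern climate anchors ----------------------------------------------
PCO2_MOD_PPM = 280.0
PCO2_MOD_BAR = 280.0e-6
T_SURF_MOD = 285.0               # K at 280 ppm and modern luminosity
PH_MOD = 8.2
CLIMATE_SENSITIVITY = 5.6        # K per ln(pCO2) unit; doubling ~ 3.9 K
LUMINOSITY_SENSITIVITY = 70.0    # K per unit relative solar luminosity
SUN_AGE = 4.57                   # Ga, for the standard main-sequence brightening

# --- ocean / carbonate chemistry (apparent seawater constants) -----------
K1_CARB = 10.0 ** -6.0           # first apparent dissociation constant
K2_CARB = 10.0 ** -9.1           # second apparent dissociation constant
KH_CO2 = 0.033                   # mol kg^-1 bar^-1, CO2 solubility
M_OCEAN = 1.4e21                 # kg, ocean mass
N_ATM_PER_BAR = 1.8e20           # mol of gas per bar of CO2 partial pressure
CA_CONC = 0.0103                 # mol/kg, calcium (held fixed)
OMEGA_MOD = 3.0                  # modern carbonate saturation state (anchor)
PRECIP_EXPONENT = 1.7            # P = k (Omega - 1)^1.7
CARB_CHEM_RTOL = 1e-4            # fixed-point relative tolerance
CARB_CHEM_MAXITER = 100

# --- declared modern flux anchors (mol C / yr) ---------------------------
F_SIL_MOD = 10.0e12              # continental silicate weathering
F_DIS_MOD = 0.45e12              # seafloor basalt dissolution
F_OUT_MANTLE_MOD = 2.5e12        # mantle (ridge + plume) outgassing
F_META_CARB_MOD = 2.0e12         # metamorphic decarbonation of crustal carbonate
F_META_ORG_MOD = 0.5e12          # metamorphic devolatilization of crustal organics
F_SUB_CARB_MOD = 2.5e12          # subducted carbonate flux
F_SUB_ORG_MOD = 1.0e12           # subducted organic flux

# xi_carb(t) = xi_carb_mod * exp(-LAMBDA_XI * (Q - 1)); LAMBDA_XI fixed so
# that at n_out = 1 the 4 Ga carbonate subduction efficiency is 20% of modern
# (hot mantle devolatilizes nearly all downgoing carbonate).
LAMBDA_XI = math.log(5.0) / 8.0

T_PORE_OFFSET = -13.0            # K, pore-space minus surface temperature
R_GAS = 8.314                    # J mol^-1 K^-1
LAND_RAMP_HALFWIDTH = 0.5        # Ga, half-width of the continental growth ramp

# --- integration ----------------------------------------------------------
ODE_RTOL = 1e-6
ODE_ATOL = 1e3                   # mol (or mol*permil for the isotope lines)

# --- derived modern ocean state (from the 280 ppm / pH 8.2 anchor) --------
_H_MOD = 10.0 ** -PH_MOD
_S_MOD = KH_CO2 * PCO2_MOD_BAR                   # dissolved CO2, mol/kg
_HCO3_MOD = K1_CARB * _S_MOD / _H_MOD
_CO3_MOD = K2_CARB * _HCO3_MOD / _H_MOD
DIC_MOD = _S_MOD + _HCO3_MOD + _CO3_MOD
ALK_MOD = _HCO3_MOD + 2.0 * _CO3_MOD
CO3_MOD = _CO3_MOD
R_AO_MOD = PCO2_MOD_BAR * N_ATM_PER_BAR + DIC_MOD * M_OCEAN
A_AO_MOD = ALK_MOD * M_OCEAN
KSP_CALCITE = CA_CONC * CO3_MOD / OMEGA_MOD      # anchors modern Omega


def solar_luminosity(t_ga: float) -> float:
    """Relative solar luminosity at age ``t_ga`` (Gough main-sequence law)."""
    return 1.0 / (1.0 + 0.4 * t_ga / SUN_AGE)


def fixed_constants_dict() -> dict:
    """All fixed constants as a plain dict, for run metadata sidecars."""
    out = {}
    for name, value in globals().items():
        if name.isupper() and isinstance(value, (int, float)):
            out[name] = value
    return out
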
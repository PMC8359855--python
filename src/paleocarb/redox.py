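"""Redox bookkeeping: K_oxy, surface redox imbalance, burial efficiency.

The model does not solve for atmospheric O2.  Instead, the diagnostic ratio
K_oxy compares the oxygen source flux (organic burial plus a sulfide/Fe(II)
burial term scaled with fractional organic burial) to the fast oxygen sinks
(reduced volcanic/metamorphic gases, scaled with total outgassing).
K_oxy < 1 diagnoses an anoxic atmosphere: reduced gases overwhelm the O2
source and photochemistry keeps O2 negligible.
"""

from __future__ import annotations

import numpy as np

from . import constants as C


def reduced_gas_flux(t_ga, scenario_on: bool = False):
    """Reduced-gas O2 sink (mol O2/yr) at age ``t_ga``.

    With the reduced-Archean-mantle scenario on, the flux grows linearly
    back in time, reaching 3.5x modern at 4.1 Ga (a 1.2 log-unit secular
    mantle oxidation mapped onto the outgassed reductant flux).
    """
    t_ga = np.asarray(t_ga, dtype=float)
    if np.any(t_ga < 0.0) or np.any(t_ga > C.T_START):
        raise ValueError("age outside the 0-4.1 Ga model span")
    if scenario_on:
        out = C.F_REDUCED_MOD * (1.0 + 2.5 * t_ga / C.T_START)
    else:
        out = C.F_REDUCED_MOD * np.ones_like(t_ga)
    return out if out.ndim else float(out)


def koxy(F_burial_org, f_org, f_org_mod, F_outg, F_outg_mod,
         reduced_scenario: bool = False, t_ga=0.0):
    """Atmospheric oxygenation parameter (dimensionless)."""
    F_outg = np.asarray(F_outg, dtype=float)
    if np.any(F_outg <= 0.0) or F_outg_mod <= 0.0:
        raise ValueError("K_oxy requires positive outgassing fluxes")
    if f_org_mod <= 0.0:
        raise ValueError("K_oxy requires positive modern f_org")
    source = (np.asarray(F_burial_org, dtype=float)
              + C.F_BURIAL_OTHER_MOD * np.asarray(f_org, dtype=float)
              / f_org_mod)
    sink = reduced_gas_flux(t_ga, reduced_scenario) * F_outg / F_outg_mod
    out = source / sink
    return out if out.ndim else float(out)


def redox_imbalance(F_burial_org, f_org, f_org_mod, F_outg, F_outg_mod,
                    F_weath_org, reduced_scenario: bool = False, t_ga=0.0):
    """Net O2 source minus sink flux (mol O2-equivalents/yr).

    The model carries no full redox accounting (no H escape, no explicit S
    or Fe cycling), so this quantity need not vanish; in fitted histories it
    flips from negative to positive around the Great Oxidation Event.
    """
    source = (np.asarray(F_burial_org, dtype=float)
              + C.F_BURIAL_OTHER_MOD * np.asarray(f_org, dtype=float)
              / f_org_mod)
    sink = reduced_gas_flux(t_ga, reduced_scenario) * np.asarray(
        F_outg, dtype=float) / F_outg_mod
    out = source - sink - np.asarray(F_weath_org, dtype=float)
    return out if out.ndim else float(out)


def burial_efficiency(F_burial_org, npp):
    """Organic burial flux over net primary productivity (fraction)."""
    npp = np.asarray(npp, dtype=float)
    if np.any(npp <= 0.0):
        raise ValueError("NPP must be positive")
    out = np.asarray(F_burial_org, dtype=float) / npp
    return out if out.ndim else float(out)
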
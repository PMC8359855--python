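"""Carbon-isotope mass balance: input delta, true and apparent f_org.

The organic burial fraction follows from the lever rule between the buried
carbonate and buried organic end members::

    f_org = (d13C_carb_buried - d13C_inputs) / (d13C_carb_buried - d13C_org_buried)

The "apparent" f_org replaces the flux-weighted input value with the modern
mantle value (-5.5 permil), which is the conventional reading of the isotope
record; true and apparent f_org coincide exactly when the inputs are
mantle-like, and decouple when O2-dependent organic weathering or
preferential subduction of organics shifts the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .forward import FluxSet


@dataclass
class IsotopeSnapshot:
    """Per-time isotope diagnostics of a trajectory."""

    delta_inputs: float
    delta_carb_buried: float
    delta_org_buried: float
    f_org_true: float
    f_org_apparent: float

    def __post_init__(self):
        gap = self.delta_carb_buried - self.delta_org_buried
        if abs(gap - C.DELTA_ORG_OFFSET) > 1e-9:
            raise ValueError("buried carbonate-organic offset must be 28 permil")


def delta_inputs(fluxes: FluxSet, delta_carb: float, delta_org: float,
                 delta_mantle: float) -> float:
    """Flux-weighted mean delta13C of all inputs to the atmosphere-ocean.

    Weathering fluxes carry the delta of their crustal source reservoir,
    mantle outgassing carries the mantle delta, and the metamorphic/arc
    components of outgassing carry the delta of the crustal reservoir they
    devolatilize (instantaneous recycling; no slab residence time).
    """
    w_carb = (fluxes.F_weath_carb + fluxes.F_meta_carb
              + (1.0 - fluxes.xi_carb_t) * fluxes.F_sub_carb)
    w_org = (fluxes.F_weath_org + fluxes.F_meta_org
             + (1.0 - fluxes.xi_org_t) * fluxes.F_sub_org)
    total = w_carb + w_org + fluxes.F_out_mantle
    if total <= 0.0:
        raise ValueError("total carbon input flux must be positive")
    return (w_carb * delta_carb + w_org * delta_org
            + fluxes.F_out_mantle * delta_mantle) / total


def forg_massbalance(delta_carb_b, delta_org_b, delta_in):
    """True fractional organic burial from the isotope lever rule."""
    denom = np.asarray(delta_carb_b, dtype=float) - np.asarray(
        delta_org_b, dtype=float)
    if np.any(denom == 0.0):
        raise ZeroDivisionError("buried carbonate and organic deltas coincide")
    out = (np.asarray(delta_carb_b, dtype=float) - delta_in) / denom
    return out if out.ndim else float(out)


def apparent_forg(delta_carb_b, delta_org_b):
    """f_org under the conventional mantle-input (-5.5 permil) assumption."""
    return forg_massbalance(delta_carb_b, delta_org_b, C.DELTA_MANTLE_MOD)


def snapshot(fluxes: FluxSet, delta_AO: float, delta_carb: float,
             delta_org: float, delta_mantle: float,
             carb_burial_offset: float = 0.0) -> IsotopeSnapshot:
    """Assemble the isotope diagnostics at one instant of a trajectory."""
    d_carb_b = delta_AO + carb_burial_offset
    d_org_b = d_carb_b - C.DELTA_ORG_OFFSET
    d_in = delta_inputs(fluxes, delta_carb, delta_org, delta_mantle)
    return IsotopeSnapshot(
        delta_inputs=d_in,
        delta_carb_buried=d_carb_b,
        delta_org_buried=d_org_b,
        f_org_true=forg_massbalance(d_carb_b, d_org_b, d_in),
        f_org_apparent=apparent_forg(d_carb_b, d_org_b))
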
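"""Forward model of mantle--crust--ocean carbon cycling over 4.1 Ga.

Five reservoirs are integrated: atmosphere--ocean carbon ``R_AO``, crustal
organic carbon ``R_org``, crustal carbonate carbon ``R_carb``, mantle carbon
``R_mantle``, and atmosphere--ocean carbonate alkalinity ``A_AO``, together
with the 13C content of each carbon reservoir.  Fractional organic burial
``f_org`` is a free history (epoch-wise or linear); absolute organic burial
follows from steady-state partitioning of total carbon inputs.  All flux
closures are documented on the individual operations below.

Public operations validate their inputs and delegate to the jitted kernel in
:mod:`paleocarb._kernel`, so the formulas checked by unit tests are exactly
the formulas the ODE integrator evaluates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint, ODEintWarning

from . import constants as C
from . import _kernel as K
from . import redox
from .params import ModelParams
from .scenario import Scenario, pack_theta


class IntegrationError(RuntimeError):
    """Raised when a forward integration fails (consumed as -inf likelihood)."""


class ConvergenceError(RuntimeError):
    """Carbonate-chemistry/climate fixed point failed; carries last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReservoirState:
    """Instantaneous reservoir masses (mol) and per-reservoir delta13C (permil)."""

    R_AO: float
    R_org: float
    R_carb: float
    R_mantle: float
    A_AO: float
    delta_AO: float = C.DELTA_MANTLE_MOD
    delta_org: float = C.DELTA_MANTLE_MOD - C.DELTA_ORG_OFFSET
    delta_carb: float = C.DELTA_MANTLE_MOD
    delta_mantle: float = C.DELTA_MANTLE_MOD

    def __post_init__(self):
        for name in ("R_AO", "R_org", "R_carb", "R_mantle", "A_AO"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("delta_AO", "delta_org", "delta_carb", "delta_mantle"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (-60.0 <= v <= 20.0):
                raise ValueError(f"{name}={v} outside [-60, 20] permil")

    def to_y(self) -> np.ndarray:
        return np.array([
            self.R_AO, self.R_org, self.R_carb, self.R_mantle, self.A_AO,
            self.R_AO * self.delta_AO, self.R_org * self.delta_org,
            self.R_carb * self.delta_carb, self.R_mantle * self.delta_mantle])

    @classmethod
    def from_y(cls, y) -> "ReservoirState":
        y = np.asarray(y, dtype=float)
        r = np.maximum(y[:4], 1e8)
        return cls(R_AO=y[0], R_org=y[1], R_carb=y[2], R_mantle=y[3],
                   A_AO=y[4], delta_AO=y[5] / r[0], delta_org=y[6] / r[1],
                   delta_carb=y[7] / r[2], delta_mantle=y[8] / r[3])

    @property
    def total_carbon(self) -> float:
        return self.R_AO + self.R_org + self.R_carb + self.R_mantle


@dataclass
class FluxSet:
    """Instantaneous carbon and alkalinity fluxes (mol C/yr) with tags."""

    F_weath_carb: float
    F_weath_org: float
    F_burial_org: float
    P_ocean: float
    P_pore: float
    F_sil: float
    F_dis: float
    F_sub_org: float
    F_sub_carb: float
    F_meta_org: float
    F_meta_carb: float
    F_out_mantle: float
    F_outg: float
    xi_org_t: float
    xi_carb_t: float
    delta_inputs: float = np.nan

    @classmethod
    def from_kernel(cls, f: np.ndarray) -> "FluxSet":
        return cls(
            F_weath_carb=f[K.FWC], F_weath_org=f[K.FWO],
            F_burial_org=f[K.FBORG], P_ocean=f[K.FPOC], P_pore=f[K.FPPORE],
            F_sil=f[K.FFSIL], F_dis=f[K.FFDIS], F_sub_org=f[K.FSUBO],
            F_sub_carb=f[K.FSUBC], F_meta_org=f[K.FMETAO],
            F_meta_carb=f[K.FMETAC], F_out_mantle=f[K.FOUTM],
            F_outg=f[K.FOUTG], xi_org_t=f[K.FXIORG], xi_carb_t=f[K.FXICARB],
            delta_inputs=f[K.FDINP])


#: Trajectory column order (one row per grid time).
TRAJECTORY_COLUMNS = (
    "t_ga", "R_AO", "R_org", "R_carb", "R_mantle", "A_AO",
    "delta_AO", "delta_org", "delta_carb", "delta_mantle",
    "F_weath_carb", "F_weath_org", "F_burial_org", "P_ocean", "P_pore",
    "F_sil", "F_dis", "F_sub_org", "F_sub_carb", "F_meta_org", "F_meta_carb",
    "F_out_mantle", "F_outg", "xi_org_t", "xi_carb_t",
    "pCO2_ppm", "T_s", "pH", "Omega", "pO2_rel", "f_land", "Q", "S",
    "f_org", "f_org_apparent", "delta_inputs", "delta_carb_buried",
    "delta_org_buried", "K_oxy", "redox_imbalance", "F_reduced",
    "total_carbon", "total_c13",
)


@dataclass
class Trajectory:
    """Time-gridded forward-model output (grid in Ga, descending age).

    Stored as plain arrays keyed by column name; the pandas view is built
    lazily (the likelihood path touches only arrays).
    """

    data: dict
    params: ModelParams
    scenario: Scenario
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.data["t_ga"])
        if len(t) < 2 or not np.all(np.diff(t) < 0):
            raise ValueError("trajectory grid must be strictly descending age")
        self._modern = None

    def __len__(self):
        return len(self.data["t_ga"])

    @property
    def frame(self) -> pd.DataFrame:
        cols = [c for c in TRAJECTORY_COLUMNS if c in self.data]
        return pd.DataFrame({c: self.data[c] for c in cols}, columns=cols)

    @property
    def t_ga(self) -> np.ndarray:
        return self.data["t_ga"]

    def series(self, name: str) -> np.ndarray:
        return self.data[name]

    def at_age(self, t_ga: float, column: str) -> float:
        """Linear interpolation of a column at age ``t_ga``."""
        t = self.t_ga
        return float(np.interp(t_ga, t[::-1], self.data[column][::-1]))

    @property
    def modern(self) -> dict:
        """The youngest grid row (age 0) as a column -> value mapping."""
        if self._modern is None:
            self._modern = {k: v[-1] for k, v in self.data.items()}
        return self._modern

    def archean_koxy(self) -> float:
        """Likelihood-facing 'Archean K_oxy' (window mean or single epoch)."""
        mode = self.scenario.koxy_eval
        if mode == "archean_mean":
            hi, lo = C.ARCHEAN_WINDOW
            m = (self.t_ga <= hi) & (self.t_ga >= lo)
            return float(np.mean(self.series("K_oxy")[m]))
        return self.at_age(float(mode), "K_oxy")

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            meta = {
                "params": self.params.to_dict(),
                "scenario": self.scenario.to_dict(),
                "constants": C.fixed_constants_dict(),
                **self.metadata,
            }
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(meta, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# elementary operations (validated wrappers over the kernel closures)
# ---------------------------------------------------------------------------

def _check_age(t_ga: float) -> None:
    if not (0.0 <= t_ga <= C.T_START):
        raise ValueError(f"age {t_ga} Ga outside the 0-{C.T_START} Ga model span")


def heatflow_and_spreading(t_ga: float, n_out: float, beta: float):
    """Relative internal heatflow Q(t) and spreading rate S = Q**beta.

    The declared closure Q = (4.5 / (4.5 - t))**n_out equals 1 today and
    grows monotonically with age; n_out = 0 freezes all heatflow scaling.
    """
    _check_age(t_ga)
    return K.heatflow(t_ga, n_out, beta)


def land_fraction(t_ga: float, f_land_archean: float, t_grow: float) -> float:
    """Subaerial land area relative to modern.

    A cubic smoothstep ramp of half-width 0.5 Ga, centered on ``t_grow``,
    connects the Archean fraction to exactly 1 at present.
    """
    _check_age(t_ga)
    if not (0.0 <= f_land_archean <= 1.0):
        raise ValueError("f_land_archean must lie in [0, 1]")
    return K.land_fraction(t_ga, f_land_archean, t_grow)


def epoch_forg(t_ga: float, params: ModelParams,
               variant: str = "piecewise") -> float:
    """Fractional organic burial at age ``t_ga``.

    Piecewise: 0 before 4.0 Ga, j1 in the Archean, j1*j2 in the Proterozoic,
    j1*j2*j3 after 0.5 Ga (boundaries crossed with +-25 Myr smoothsteps).
    Linear: a_grad*(4.0 - t) + b_int, floored at 0.  Values >= 1 at any epoch
    flag the parameter vector invalid (rejected by the prior, not clipped).
    """
    _check_age(t_ga)
    scen = Scenario(name="_op", forg_variant=variant)
    theta = pack_theta(params, scen)
    f = K.epoch_forg(t_ga, theta)
    if params.max_forg(variant) >= 1.0:
        raise ValueError("f_org >= 1 at some epoch: invalid parameter vector")
    return f


def organic_weathering(R_org: float, f_land: float, pO2_rel: float,
                       F_oxid_mod: float, F_thermo_mod: float,
                       oxw_exponent: float = C.OXW_EXPONENT_DEFAULT) -> float:
    """Organic carbon weathering flux (mol C/yr).

    Oxidative weathering scales with the crustal organic reservoir, land
    fraction, and pO2**exponent; the thermogenic-methane photochemical
    oxidation term scales with the reservoir only (O2- and land-independent).
    """
    if R_org < 0:
        raise ValueError("R_org must be non-negative")
    if pO2_rel <= 0:
        raise ValueError("pO2_rel must be positive")
    ratio = R_org / C.R_ORG_MOD
    return (F_oxid_mod * ratio * f_land * pO2_rel ** oxw_exponent
            + F_thermo_mod * ratio)


def carbonate_weathering(R_carb: float, f_land: float, pCO2_rel: float,
                         dT: float, F_weathcarb_mod: float, alpha: float,
                         T_e: float, variant: str = "powerlaw") -> float:
    """Carbonate weathering flux (mol C/yr), power-law or Michaelis-Menten CO2."""
    if pCO2_rel <= 0:
        raise ValueError("pCO2_rel must be positive")
    if R_carb < 0:
        raise ValueError("R_carb must be non-negative")
    if variant == "michaelis_menten":
        co2_fac = (2.0 * pCO2_rel / (1.0 + pCO2_rel)) ** alpha
    elif variant == "powerlaw":
        co2_fac = pCO2_rel ** alpha
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return (F_weathcarb_mod * (R_carb / C.R_CARB_MOD) * f_land * co2_fac
            * np.exp(dT / T_e))


def climate_and_ocean(R_AO: float, A_AO: float, t_ga: float):
    """Self-consistent (pCO2 ppm, T_s K, pH, Omega) of the atmosphere-ocean.

    Partitions R_AO between the atmosphere and ocean carbonate speciation at
    fixed alkalinity, then evaluates the logarithmic CO2 climate function
    under time-dependent solar luminosity.  Anchored to 280 ppm / 285 K /
    pH 8.2 at the modern reference state.
    """
    if R_AO <= 0 or A_AO <= 0:
        raise ValueError("R_AO and A_AO must be positive")
    _check_age(t_ga)
    pco2, ts, ph, omega = K.climate_ocean_state(R_AO, A_AO, t_ga)
    if not np.isfinite(pco2):
        raise ConvergenceError(
            "carbonate-system solve failed (degenerate alkalinity/carbon)",
            last_iterate={"R_AO": R_AO, "A_AO": A_AO})
    return pco2 * 1e6, ts, ph, omega


def carbonate_burial(Omega: float, S: float, k_ocean: float | None = None,
                     k_pore: float | None = None):
    """Ocean and pore-space carbonate precipitation (mol C/yr).

    Both vanish at or below saturation (Omega <= 1) and grow as
    (Omega - 1)**1.7; the pore-space term additionally scales with the
    spreading rate.  Default rate constants close the modern alkalinity
    budget at the default closure fluxes.
    """
    if Omega < 0:
        raise ValueError("Omega must be non-negative")
    ex_mod = (C.OMEGA_MOD - 1.0) ** C.PRECIP_EXPONENT
    if k_ocean is None:
        k_ocean = (C.F_SIL_MOD + 16e12) / ex_mod
    if k_pore is None:
        k_pore = C.F_DIS_MOD / ex_mod
    ex = max(Omega - 1.0, 0.0) ** C.PRECIP_EXPONENT
    return k_ocean * ex, k_pore * S * ex


def organic_burial(f_org: float, F_weath_carb: float, F_weath_org: float,
                   F_outg: float) -> float:
    """Absolute organic burial: f_org times total carbon inputs (mol C/yr)."""
    if not (0.0 <= f_org < 1.0):
        raise ValueError("f_org must lie in [0, 1)")
    return f_org * (F_weath_carb + F_weath_org + F_outg)


def subduction_and_outgassing(state: ReservoirState, Q: float, S: float,
                              params: ModelParams, t_ga: float,
                              scenario: Scenario | None = None) -> FluxSet:
    """Subduction, metamorphic and outgassing fluxes at one state/time.

    Mantle outgassing and metamorphic fluxes scale with their source
    reservoirs and Q**mu; subduction fluxes scale with reservoirs and S.
    The carbonate subduction efficiency decays with heatflow (hot mantle
    devolatilizes downgoing carbonate) unless frozen by the scenario.
    """
    if scenario is None:
        scenario = Scenario(name="_op")
    if not (0.0 <= params.xi_org <= 1.0 and 0.0 <= params.xi_carb_mod <= 1.0):
        raise ValueError("subduction efficiencies must lie in [0, 1]")
    if Q < 1.0 or S < 1.0:
        raise ValueError("Q and S must be >= 1")
    theta = pack_theta(params, scenario)
    f = K.compute_fluxes(t_ga, state.to_y(), theta)
    return FluxSet.from_kernel(f)


def derivatives(state: ReservoirState, t_ga: float, params: ModelParams,
                scenario: Scenario | None = None) -> np.ndarray:
    """d/dt of [R_AO, R_org, R_carb, R_mantle, A_AO, D_AO, D_org, D_carb,
    D_mantle] in mol/yr, where D_i = R_i * delta_i.

    Carbon and 13C are conserved identically: the four carbon lines and the
    four D lines each sum to zero for any valid state.
    """
    if scenario is None:
        scenario = Scenario(name="_op")
    _check_age(t_ga)
    y = state.to_y()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    theta = pack_theta(params, scenario)
    tau = (C.T_START - t_ga) * 1e9
    dy = K.rhs(tau, y, theta)
    if not np.all(np.isfinite(dy)):
        raise ConvergenceError("flux evaluation failed at this state",
                               last_iterate=y)
    return dy


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def default_grid(n: int = 411) -> np.ndarray:
    """Uniform output grid from 4.1 Ga to present (descending age)."""
    return np.linspace(C.T_START, 0.0, n)


def integrate(params: ModelParams, scenario: Scenario | None = None,
              grid: np.ndarray | None = None) -> Trajectory:
    """Integrate the coupled reservoir/isotope system from 4.1 Ga to 0 Ga.

    Uses an adaptive stiff-capable solver (LSODA, rtol 1e-6, atol 1e3 mol);
    any failure raises :class:`IntegrationError`, which the likelihood maps
    to -inf.
    """
    if scenario is None:
        scenario = Scenario(name="nominal")
    if grid is None:
        grid = default_grid(scenario.grid_n)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0.0 or grid.max() > C.T_START:
        raise ValueError("grid must lie within [0, 4.1] Ga")
    theta = pack_theta(params, scenario)
    y0 = K.initial_state(theta)
    tau_eval = (C.T_START - grid) * 1e9

    # LSODA via odeint: the stepping loop runs in compiled code, which
    # matters at inverse-analysis call volumes
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        # mxstep is a per-output-interval cap; set it explicitly so that
        # success does not depend on how coarse the output grid is
        Y, info = odeint(
            K.rhs, y0, tau_eval, args=(theta,), tfirst=True,
            rtol=C.ODE_RTOL, atol=C.ODE_ATOL, mxstep=5000,
            full_output=True, printmessg=False)
    Y = Y.T
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE solver failed: {info['message']}")
    if not np.all(np.isfinite(Y)):
        raise IntegrationError("non-finite state along trajectory")
    if Y[:5].min() < -1.0:
        raise IntegrationError("negative reservoir along trajectory")

    return _postprocess(grid, Y, theta, params, scenario)


def _postprocess(grid, Y, theta, params, scenario) -> Trajectory:
    n = len(grid)
    F = K.compute_fluxes_batch(grid, np.ascontiguousarray(Y), theta)
    if not np.all(np.isfinite(F[K.FPCO2])):
        raise IntegrationError("ocean chemistry failed along trajectory")

    R = np.maximum(Y[:4], 1e8)
    deltas = Y[5:9] / R
    eps = scenario.carb_burial_offset
    d_carb_b = deltas[0] + eps
    d_org_b = d_carb_b - C.DELTA_ORG_OFFSET

    forg = F[K.FFORG]
    forg_mod = forg[-1]
    foutg_mod = F[K.FOUTG, -1]
    fred = redox.reduced_gas_flux(grid, scenario.reduced_mantle)
    with np.errstate(all="ignore"):
        if forg_mod > 0.0 and foutg_mod > 0.0:
            source = F[K.FBORG] + C.F_BURIAL_OTHER_MOD * forg / forg_mod
            sink = fred * F[K.FOUTG] / foutg_mod
            koxy_series = source / sink
            imbalance = source - sink - F[K.FWO]
        else:
            koxy_series = np.full(n, np.nan)
            imbalance = np.full(n, np.nan)

    data = {
        "t_ga": grid,
        "R_AO": Y[0], "R_org": Y[1], "R_carb": Y[2], "R_mantle": Y[3],
        "A_AO": Y[4],
        "delta_AO": deltas[0], "delta_org": deltas[1],
        "delta_carb": deltas[2], "delta_mantle": deltas[3],
        "F_weath_carb": F[K.FWC], "F_weath_org": F[K.FWO],
        "F_burial_org": F[K.FBORG], "P_ocean": F[K.FPOC],
        "P_pore": F[K.FPPORE], "F_sil": F[K.FFSIL], "F_dis": F[K.FFDIS],
        "F_sub_org": F[K.FSUBO], "F_sub_carb": F[K.FSUBC],
        "F_meta_org": F[K.FMETAO], "F_meta_carb": F[K.FMETAC],
        "F_out_mantle": F[K.FOUTM], "F_outg": F[K.FOUTG],
        "xi_org_t": F[K.FXIORG], "xi_carb_t": F[K.FXICARB],
        "pCO2_ppm": F[K.FPCO2] * 1e6, "T_s": F[K.FTS], "pH": F[K.FPH],
        "Omega": F[K.FOMEGA], "pO2_rel": F[K.FPO2], "f_land": F[K.FLAND],
        "Q": F[K.FQ], "S": F[K.FS],
        "f_org": forg,
        "f_org_apparent": (d_carb_b - C.DELTA_MANTLE_MOD) / C.DELTA_ORG_OFFSET,
        "delta_inputs": F[K.FDINP],
        "delta_carb_buried": d_carb_b, "delta_org_buried": d_org_b,
        "K_oxy": koxy_series, "redox_imbalance": imbalance,
        "F_reduced": np.broadcast_to(fred, (n,)).copy(),
        "total_carbon": Y[:4].sum(axis=0),
        "total_c13": Y[5:9].sum(axis=0),
    }
    return Trajectory(data=data, params=params, scenario=scenario)
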
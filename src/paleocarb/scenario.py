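"""Scenario configurations: parameterization variants and sensitivity cases.

A :class:`Scenario` bundles every switchable piece of the forward model --
the f_org functional form, the O2 dependence of organic weathering, the
carbonate-weathering CO2 law, the continental growth case, the evolving
(or frozen) carbonate subduction efficiency, the reduced-Archean-mantle
redox case -- together with the declared closure constants and any prior
overrides.  The module also hosts the sensitivity-suite registry mirroring
the standard endmember experiments, and the packing of a parameter draw
plus a scenario into the flat ``theta`` vector the jitted kernel consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import constants as C
from . import _kernel as K
from .params import ModelParams, PRIOR_BOUNDS, param_names

#: closure constants a scenario may override, with their defaults
DEFAULT_CLOSURES: dict[str, float] = {
    "F_sil_mod": C.F_SIL_MOD,
    "F_dis_mod": C.F_DIS_MOD,
    "F_out_mantle_mod": C.F_OUT_MANTLE_MOD,
    "F_meta_carb_mod": C.F_META_CARB_MOD,
    "F_meta_org_mod": C.F_META_ORG_MOD,
    "F_sub_carb_mod": C.F_SUB_CARB_MOD,
    "F_sub_org_mod": C.F_SUB_ORG_MOD,
    "lambda_xi": C.LAMBDA_XI,
    "T_pore_offset": C.T_PORE_OFFSET,
    "R_org_init": C.R_ORG_INIT,
}


@dataclass
class Scenario:
    """One forward-model / inversion configuration."""

    name: str = "nominal"
    forg_variant: str = "piecewise"          # "piecewise" | "linear"
    oxw_exponent: float = C.OXW_EXPONENT_DEFAULT
    oxidative_weathering: bool = True        # O2-dependent term included
    thermogenic: bool = True                 # O2-independent term included
    carbonate_weathering_variant: str = "powerlaw"   # | "michaelis_menten"
    land_case: str = "nominal"               # nominal|zero|mid|constant
    reduced_mantle: bool = False
    subduction_evolution: bool = True
    carb_burial_offset: float = 0.0          # permil, delta_carb_buried - delta_AO
    koxy_eval: str | float = "archean_mean"  # window mean, or a single epoch (Ga)
    closures: dict = field(default_factory=dict)
    prior_overrides: dict = field(default_factory=dict)
    grid_n: int = 411

    def __post_init__(self):
        if self.forg_variant not in ("piecewise", "linear"):
            raise ValueError(f"unknown forg_variant {self.forg_variant!r}")
        if self.carbonate_weathering_variant not in (
                "powerlaw", "michaelis_menten"):
            raise ValueError("unknown carbonate weathering variant")
        if self.land_case not in ("nominal", "zero", "mid", "constant"):
            raise ValueError(f"unknown land_case {self.land_case!r}")
        unknown = set(self.closures) - set(DEFAULT_CLOSURES)
        if unknown:
            raise ValueError(f"unknown closure constants: {sorted(unknown)}")

    # -- priors ------------------------------------------------------------
    def param_names(self) -> tuple[str, ...]:
        return param_names(self.forg_variant)

    @property
    def ndim(self) -> int:
        return len(self.param_names())

    def prior_bounds(self) -> dict[str, tuple[float, float]]:
        """Per-parameter uniform bounds after scenario adjustments."""
        bounds = {n: PRIOR_BOUNDS[n] for n in self.param_names()}
        if self.carbonate_weathering_variant == "michaelis_menten":
            bounds["alpha"] = (0.0, 1.0)
        if self.land_case == "zero":
            bounds["f_land_archean"] = (0.0, 0.01)
        elif self.land_case == "mid":
            bounds["f_land_archean"] = (0.1, 0.5)
        for name, rng in self.prior_overrides.items():
            if name not in bounds:
                raise ValueError(f"prior override for unknown parameter {name}")
            bounds[name] = (float(rng[0]), float(rng[1]))
        return bounds

    def closure(self, name: str) -> float:
        return float(self.closures.get(name, DEFAULT_CLOSURES[name]))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        for key in ("closures", "prior_overrides"):
            if d.get(key) is None:
                d[key] = {}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def pack_theta(params: ModelParams, scenario: Scenario) -> np.ndarray:
    """Flatten a parameter draw + scenario into the kernel theta vector."""
    th = np.zeros(K.N_THETA)
    if scenario.forg_variant == "linear":
        th[K.IJ1] = params.a_grad
        th[K.IJ2] = params.b_int
        th[K.IJ3] = 0.0
        th[K.IVARIANT] = 1.0
    else:
        th[K.IJ1] = params.j1
        th[K.IJ2] = params.j2
        th[K.IJ3] = params.j3
        th[K.IVARIANT] = 0.0
    th[K.IFOXID] = params.F_oxid_mod
    th[K.IFTHERMO] = params.F_thermo_mod
    th[K.ILOGPO2] = params.log10_pO2_proterozoic
    th[K.ILOGPCO2] = params.log10_pCO2_init
    th[K.IALPHA] = params.alpha
    th[K.ITE] = params.T_e
    th[K.IMU] = params.mu
    th[K.IBETA] = params.beta
    th[K.INOUT] = params.n_out
    th[K.IEBAS] = params.E_bas
    th[K.IFWC] = params.F_weathcarb_mod
    th[K.IFLAND] = params.f_land_archean
    th[K.ITGROW] = params.t_grow
    th[K.IPHINIT] = params.pH_init
    th[K.ILOGRCARB] = params.log10_Rcarb_init
    th[K.IRMANTLE] = params.Rmantle_init
    th[K.IXIORG] = params.xi_org
    th[K.IXICARB] = params.xi_carb_mod

    th[K.IOXWEXP] = scenario.oxw_exponent
    th[K.IOXID_ON] = 1.0 if scenario.oxidative_weathering else 0.0
    th[K.ITHERMO_ON] = 1.0 if scenario.thermogenic else 0.0
    th[K.ICARBW] = (1.0 if scenario.carbonate_weathering_variant
                    == "michaelis_menten" else 0.0)
    th[K.ILANDCONST] = 1.0 if scenario.land_case == "constant" else 0.0
    th[K.IREDUCED] = 1.0 if scenario.reduced_mantle else 0.0
    th[K.ISUBEVO] = 1.0 if scenario.subduction_evolution else 0.0
    th[K.IEPSCARB] = scenario.carb_burial_offset

    th[K.IFSIL] = scenario.closure("F_sil_mod")
    th[K.IFDIS] = scenario.closure("F_dis_mod")
    th[K.IFOUTM] = scenario.closure("F_out_mantle_mod")
    th[K.IFMETAC] = scenario.closure("F_meta_carb_mod")
    th[K.IFMETAO] = scenario.closure("F_meta_org_mod")
    th[K.IFSUBC] = scenario.closure("F_sub_carb_mod")
    th[K.IFSUBO] = scenario.closure("F_sub_org_mod")
    th[K.ILAMXI] = scenario.closure("lambda_xi")
    th[K.ITPOFF] = scenario.closure("T_pore_offset")
    th[K.IRORG0] = scenario.closure("R_org_init")

    # precipitation rate constants calibrated so the modern alkalinity budget
    # closes at the modern anchor state: P_ocean + P_pore = F_sil + F_wc +
    # F_dis with P_pore(modern) = F_dis(modern)
    ex_mod = (C.OMEGA_MOD - 1.0) ** C.PRECIP_EXPONENT
    th[K.IKOC] = (th[K.IFSIL] + params.F_weathcarb_mod) / ex_mod
    th[K.IKPORE] = th[K.IFDIS] / ex_mod
    return th


def scenario_registry() -> dict[str, Scenario]:
    """The sensitivity-suite registry (endmember inversion configurations)."""
    reg = {
        "nominal": Scenario(name="nominal"),
        "linear_forg": Scenario(name="linear_forg", forg_variant="linear"),
        "o2_independent": Scenario(
            # organic weathering limited to the thermogenic pathway
            name="o2_independent", oxidative_weathering=False),
        "constant_subduction": Scenario(
            name="constant_subduction", subduction_evolution=False),
        "both_off": Scenario(
            name="both_off", oxidative_weathering=False,
            subduction_evolution=False),
        "strong_o2": Scenario(
            # all organic weathering O2-dependent: no thermogenic term
            name="strong_o2", thermogenic=False),
        "oxw_exponent_05": Scenario(name="oxw_exponent_05", oxw_exponent=0.5),
        "reduced_mantle": Scenario(name="reduced_mantle", reduced_mantle=True),
        "land_zero": Scenario(name="land_zero", land_case="zero"),
        "land_mid": Scenario(name="land_mid", land_case="mid"),
        "land_constant": Scenario(name="land_constant", land_case="constant"),
        "michaelis_menten": Scenario(
            name="michaelis_menten",
            carbonate_weathering_variant="michaelis_menten"),
        "high_org_low_carb": Scenario(
            name="high_org_low_carb",
            prior_overrides={"F_oxid_mod": (4e12, 8e12),
                             "F_thermo_mod": (2e12, 4e12),
                             "F_weathcarb_mod": (7e12, 15e12)}),
        "low_org_high_carb": Scenario(
            name="low_org_high_carb",
            prior_overrides={"F_weathcarb_mod": (15e12, 25e12)}),
    }
    return reg
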
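"""Observational constraints: the binned isotope record and the likelihood.

The inverse analysis fits thirteen constrained variables: the 200-Myr-binned
carbonate and organic delta13C time series, ten scalar proxy/modern
constraints, and a hard organic-burial-exceeds-weathering condition.  The
log-likelihood is a diagonal Gaussian over all of them, with two special
rows: modern pCO2 is compared in log10 space (its stated uncertainty is
0.2 log10 units), and the Archean K_oxy anoxia constraint is one-sided --
it penalizes only K_oxy > 1, with sigma 0.20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .forward import Trajectory

#: half-open [0, 3.8) Ga binning of the record, 200 Myr wide
BIN_WIDTH = 0.2
RECORD_SPAN = (0.0, 3.8)
SD_FLOOR = 0.5          # permil; smallest plausible analytical+population scatter
#: burial-exceeds-weathering checked where f_org has fully switched on
BURIAL_CHECK_MAX_AGE = 3.95

RECORD_COLUMNS = ("age_Ga", "d13c_carb_mean", "d13c_carb_sd",
                  "d13c_org_mean", "d13c_org_sd", "n")


@dataclass
class IsotopeRecord:
    """Binned carbonate/organic delta13C record (200 Myr bins, per-bin sd)."""

    age_ga: np.ndarray
    carb_mean: np.ndarray
    carb_sd: np.ndarray
    org_mean: np.ndarray
    org_sd: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.age_ga = np.asarray(self.age_ga, dtype=float)
        for name in ("carb_mean", "carb_sd", "org_mean", "org_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n = np.asarray(self.n, dtype=int)
        keep = self.n > 0
        for name in ("age_ga", "carb_mean", "carb_sd", "org_mean",
                     "org_sd", "n"):
            setattr(self, name, getattr(self, name)[keep])
        if len(self.age_ga) == 0:
            raise ValueError("empty isotope record")
        if np.any(self.carb_sd <= 0) or np.any(self.org_sd <= 0):
            raise ValueError("per-bin standard deviations must be positive")

    def __len__(self):
        return len(self.age_ga)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_Ga": self.age_ga,
            "d13c_carb_mean": self.carb_mean, "d13c_carb_sd": self.carb_sd,
            "d13c_org_mean": self.org_mean, "d13c_org_sd": self.org_sd,
            "n": self.n})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "IsotopeRecord":
        df = pd.read_csv(path)
        missing = set(RECORD_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"record CSV missing columns: {sorted(missing)}")
        return cls(age_ga=df["age_Ga"], carb_mean=df["d13c_carb_mean"],
                   carb_sd=df["d13c_carb_sd"], org_mean=df["d13c_org_mean"],
                   org_sd=df["d13c_org_sd"], n=df["n"])


def bin_centers() -> np.ndarray:
    """Centers of the 19 record bins, 3.7 ... 0.1 Ga (descending age)."""
    lo, hi = RECORD_SPAN
    edges = np.arange(lo, hi + 0.5 * BIN_WIDTH, BIN_WIDTH)
    return (edges[:-1] + 0.5 * BIN_WIDTH)[::-1]


def bin_isotope_record(ages, deltas, phases) -> IsotopeRecord:
    """Bin raw (age, delta13C, phase) samples into the 200 Myr record.

    ``phases`` entries are "carb" or "org".  Per-bin mean and sample
    standard deviation; bins with fewer than two samples, or with no
    scatter, take the declared 0.5 permil floor.  Bins missing either phase
    are dropped.  Deterministic for a fixed input order.
    """
    ages = np.asarray(ages, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    phases = np.asarray(phases)
    if len(ages) == 0:
        raise ValueError("no samples to bin")
    if ages.min() < RECORD_SPAN[0] or ages.max() > RECORD_SPAN[1]:
        raise ValueError("sample ages must lie within [0, 3.8] Ga")

    centers = bin_centers()
    out = {k: [] for k in ("age", "cm", "cs", "om", "os", "n")}
    for c in centers:
        in_bin = (ages >= c - 0.5 * BIN_WIDTH) & (ages < c + 0.5 * BIN_WIDTH)
        stats = {}
        for phase in ("carb", "org"):
            vals = deltas[in_bin & (phases == phase)]
            if len(vals) == 0:
                stats = None
                break
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            stats[phase] = (mean, max(sd, SD_FLOOR), len(vals))
        if stats is None:
            continue
        out["age"].append(c)
        out["cm"].append(stats["carb"][0])
        out["cs"].append(stats["carb"][1])
        out["om"].append(stats["org"][0])
        out["os"].append(stats["org"][1])
        out["n"].append(min(stats["carb"][2], stats["org"][2]))
    if not out["age"]:
        raise ValueError("no bin contains both phases")
    return IsotopeRecord(age_ga=out["age"], carb_mean=out["cm"],
                         carb_sd=out["cs"], org_mean=out["om"],
                         org_sd=out["os"], n=out["n"])


@dataclass
class ScalarConstraint:
    """One scalar row: observed value, 1-sigma, and evaluation age."""

    name: str
    value: float
    sigma: float
    age_ga: float = 0.0
    kind: str = "normal"        # normal | log10 | upper

    def __post_init__(self):
        if self.kind != "upper" and self.sigma <= 0:
            raise ValueError(f"{self.name}: sigma must be positive")


def default_scalar_constraints() -> list[ScalarConstraint]:
    """The shipped scalar constraint rows (proxy and modern observations)."""
    return [
        ScalarConstraint("xe_outgassing_ratio", 8.1, 3.9, age_ga=3.3),
        ScalarConstraint("modern_pco2_ppm", 280.0, 0.2, kind="log10"),
        ScalarConstraint("modern_surface_temp_K", 285.0, 5.0),
        ScalarConstraint("modern_ocean_ph", 8.2, 0.5),
        ScalarConstraint("modern_R_mantle", 2.0e22, 1.0e22),
        ScalarConstraint("modern_R_carb", 9.4e21, 5.5e21),
        ScalarConstraint("modern_R_org", 1.66e21, 0.55e21),
        ScalarConstraint("archean_koxy", 1.0, 0.20, kind="upper"),
        ScalarConstraint("archean_mantle_d13c", -5.5, 3.0, age_ga=3.5),
        ScalarConstraint("modern_mantle_d13c", -5.5, 0.5),
    ]


@dataclass
class ConstraintSet:
    """Everything the likelihood sees: record bins + scalar rows + hard rule."""

    record: IsotopeRecord
    scalars: list[ScalarConstraint] = field(
        default_factory=default_scalar_constraints)
    burial_exceeds_weathering: bool = True

    def __post_init__(self):
        for s in self.scalars:
            if s.kind not in ("normal", "log10", "upper"):
                raise ValueError(f"unknown constraint kind {s.kind!r}")

    def to_yaml(self, path) -> None:
        doc = {"scalars": [asdict(s) for s in self.scalars],
               "burial_exceeds_weathering": self.burial_exceeds_weathering,
               "record": self.record.to_frame().to_dict(orient="list")}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConstraintSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rec = doc["record"]
        record = IsotopeRecord(
            age_ga=rec["age_Ga"], carb_mean=rec["d13c_carb_mean"],
            carb_sd=rec["d13c_carb_sd"], org_mean=rec["d13c_org_mean"],
            org_sd=rec["d13c_org_sd"], n=rec["n"])
        scalars = [ScalarConstraint(**s) for s in doc["scalars"]]
        return cls(record=record, scalars=scalars,
                   burial_exceeds_weathering=doc["burial_exceeds_weathering"])


_LOG2PI = math.log(2.0 * math.pi)


def _gauss(obs, mod, sigma):
    return -0.5 * ((obs - mod) / sigma) ** 2 - 0.5 * _LOG2PI - math.log(sigma)


def _model_value(traj: Trajectory, c: ScalarConstraint) -> float:
    m = traj.modern
    if c.name == "xe_outgassing_ratio":
        return traj.at_age(c.age_ga, "F_out_mantle") / m["F_out_mantle"]
    if c.name == "modern_pco2_ppm":
        return m["pCO2_ppm"]
    if c.name == "modern_surface_temp_K":
        return m["T_s"]
    if c.name == "modern_ocean_ph":
        return m["pH"]
    if c.name == "modern_R_mantle":
        return m["R_mantle"]
    if c.name == "modern_R_carb":
        return m["R_carb"]
    if c.name == "modern_R_org":
        return m["R_org"]
    if c.name == "archean_koxy":
        return traj.archean_koxy()
    if c.name == "archean_mantle_d13c":
        return traj.at_age(c.age_ga, "delta_mantle")
    if c.name == "modern_mantle_d13c":
        return m["delta_mantle"]
    raise KeyError(f"no model extraction rule for constraint {c.name!r}")


def log_likelihood(traj: Trajectory, constraints: ConstraintSet) -> float:
    """Diagonal Gaussian log-likelihood of a trajectory.

    Returns -inf on a burial-exceeds-weathering violation (integration
    failures never reach this point: they raise upstream and are mapped to
    -inf by the posterior).
    """
    ll = 0.0
    rec = constraints.record
    t = traj.t_ga[::-1]
    mod_carb = np.interp(rec.age_ga, t, traj.series("delta_carb_buried")[::-1])
    mod_org = np.interp(rec.age_ga, t, traj.series("delta_org_buried")[::-1])
    ll += float(np.sum(
        -0.5 * ((rec.carb_mean - mod_carb) / rec.carb_sd) ** 2
        - 0.5 * _LOG2PI - np.log(rec.carb_sd)))
    ll += float(np.sum(
        -0.5 * ((rec.org_mean - mod_org) / rec.org_sd) ** 2
        - 0.5 * _LOG2PI - np.log(rec.org_sd)))

    for c in constraints.scalars:
        mod = _model_value(traj, c)
        if not np.isfinite(mod):
            return -np.inf
        if c.kind == "upper":
            if mod > c.value:
                ll += -0.5 * ((mod - c.value) / c.sigma) ** 2
        elif c.kind == "log10":
            if mod <= 0:
                return -np.inf
            ll += _gauss(math.log10(c.value), math.log10(mod), c.sigma)
        else:
            ll += _gauss(c.value, mod, c.sigma)

    if constraints.burial_exceeds_weathering:
        mask = traj.t_ga < BURIAL_CHECK_MAX_AGE
        if np.any(traj.series("F_burial_org")[mask]
                  < traj.series("F_weath_org")[mask]):
            return -np.inf
    return ll
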
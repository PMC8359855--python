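"""Bayesian inverse analysis: priors, posterior, ensemble MCMC, summaries.

The posterior over the sampled unknowns is explored with an
affine-invariant ensemble sampler (emcee's stretch move): each proposal
moves a walker along the line toward a randomly chosen companion with a
scale drawn from the standard stretch distribution, accepted by a
Metropolis rule.  Priors are uniform boxes (log-uniform for the log10-
specified parameters, which are sampled on the log scale), with three
structural constraints folded into the prior: xi_org > xi_carb(modern),
f_org < 1 at every epoch, and modern f_org bounded away from zero (the
redox bookkeeping divides by it).

The headline derived quantity is the fold change in fractional organic
burial over Earth history: j2*j3 under the piecewise parameterization, or
f_org(0 Ga)/f_org(3.5 Ga) under the linear one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .forward import IntegrationError, Trajectory, integrate, default_grid
from .params import ModelParams
from .record import ConstraintSet, IsotopeRecord, log_likelihood
from .scenario import Scenario

logger = logging.getLogger(__name__)

#: minimum modern f_org admitted by the prior (K_oxy scales by 1/f_org_mod)
MIN_MODERN_FORG = 0.01

BLOB_DTYPE = [("modern_forg", float), ("modern_burial", float),
              ("archean_koxy", float), ("fold_change", float),
              ("modern_delta_inputs", float)]

_NAN_BLOBS = (np.nan,) * len(BLOB_DTYPE)


def fold_change(params: ModelParams, variant: str = "piecewise") -> float:
    """Relative increase in f_org over Earth history for one draw."""
    if variant == "linear":
        f_old = 0.5 * params.a_grad + params.b_int   # f_org at 3.5 Ga
        f_now = 4.0 * params.a_grad + params.b_int
        if f_old <= 0.0:
            return np.inf if f_now > 0 else np.nan
        return f_now / f_old
    return params.j2 * params.j3


def log_prior(x, scenario: Scenario) -> float:
    """Uniform box prior with the structural constraints; 0 inside, -inf out."""
    x = np.asarray(x, dtype=float)
    bounds = scenario.prior_bounds()
    names = scenario.param_names()
    for v, n in zip(x, names):
        lo, hi = bounds[n]
        if not (lo <= v <= hi):
            return -np.inf
    p = ModelParams.from_vector(x, scenario.forg_variant)
    if not p.xi_org > p.xi_carb_mod:
        return -np.inf
    if p.max_forg(scenario.forg_variant) >= 1.0:
        return -np.inf
    if p.modern_forg(scenario.forg_variant) < MIN_MODERN_FORG:
        return -np.inf
    return 0.0


def log_posterior(x, constraints: ConstraintSet, scenario: Scenario,
                  grid=None):
    """Log posterior plus per-call diagnostics (emcee blobs).

    Integration failures and constraint violations map to -inf; the blobs
    carry modern f_org, modern organic burial, Archean K_oxy, the f_org
    fold change, and modern delta13C of inputs.
    """
    lp = log_prior(x, scenario)
    if not np.isfinite(lp):
        return (-np.inf,) + _NAN_BLOBS
    params = ModelParams.from_vector(x, scenario.forg_variant)
    try:
        traj = integrate(params, scenario, grid=grid)
    except IntegrationError:
        return (-np.inf,) + _NAN_BLOBS
    ll = log_likelihood(traj, constraints)
    if not np.isfinite(ll):
        return (-np.inf,) + _NAN_BLOBS
    m = traj.modern
    return (lp + ll,
            params.modern_forg(scenario.forg_variant),
            float(m["F_burial_org"]),
            traj.archean_koxy(),
            fold_change(params, scenario.forg_variant),
            float(m["delta_inputs"]))


@dataclass
class PosteriorChain:
    """Raw ensemble output plus run provenance."""

    samples: np.ndarray            # (n_steps, n_walkers, ndim)
    log_prob: np.ndarray           # (n_steps, n_walkers)
    blobs: np.ndarray              # structured, (n_steps, n_walkers)
    param_names: tuple
    scenario: Scenario
    seed: int
    burn_in: int
    acceptance_fraction: np.ndarray
    autocorr_time: np.ndarray | None = None
    prior_predictive_success: float | None = None

    def __post_init__(self):
        ns, nw, nd = self.samples.shape
        if self.log_prob.shape != (ns, nw) or nd != len(self.param_names):
            raise ValueError("inconsistent chain dimensions")

    @property
    def n_steps(self):
        return self.samples.shape[0]

    @property
    def n_walkers(self):
        return self.samples.shape[1]

    def flat(self, discard: int | None = None) -> np.ndarray:
        """Post-burn-in samples flattened to (n_draws, ndim)."""
        d = self.burn_in if discard is None else discard
        return self.samples[d:].reshape(-1, len(self.param_names))

    def flat_blobs(self, discard: int | None = None) -> np.ndarray:
        d = self.burn_in if discard is None else discard
        return self.blobs[d:].reshape(-1)

    def flat_log_prob(self, discard: int | None = None) -> np.ndarray:
        d = self.burn_in if discard is None else discard
        return self.log_prob[d:].reshape(-1)

    def to_frame(self, discard: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.flat(discard), columns=list(self.param_names))
        df["log_prob"] = self.flat_log_prob(discard)
        fb = self.flat_blobs(discard)
        for name, _ in BLOB_DTYPE:
            df[name] = fb[name]
        return df


def sample_prior(scenario: Scenario, n: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """Draw one batch of points uniform over the prior box (no constraints)."""
    bounds = scenario.prior_bounds()
    names = scenario.param_names()
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    return rng.uniform(lo, hi, size=(n, len(names)))


def _ball_center(scenario: Scenario) -> np.ndarray:
    """Feasible reference point for tight-ball initialization."""
    return ModelParams().to_vector(scenario.forg_variant)


def run_inference(record: IsotopeRecord, scenario: Scenario | None = None,
                  constraints: ConstraintSet | None = None,
                  n_walkers: int = 100, n_steps: int = 400,
                  burn_in: int = 100, seed: int = 0,
                  grid_n: int = 206, init: str = "prior",
                  progress: bool = False) -> PosteriorChain:
    """Affine-invariant ensemble inversion of an isotope record.

    Walkers are initialized by rejection sampling until every walker has a
    finite posterior, drawing either uniformly over the prior box
    (``init="prior"``, the default) or from a tight Gaussian ball around a
    feasible interior point (``init="ball"``, 2% of the prior width per
    dimension) -- the latter trades full prior dispersion for a much
    shorter burn-in at scaled-down chain lengths.  Deterministic for a
    fixed seed.
    """
    if scenario is None:
        scenario = Scenario(name="nominal")
    if constraints is None:
        constraints = ConstraintSet(record=record)
    ndim = scenario.ndim
    if n_walkers <= 2 * ndim:
        raise ValueError(f"need n_walkers > {2 * ndim} for dimension {ndim}")
    if init not in ("prior", "ball"):
        raise ValueError(f"unknown init mode {init!r}")

    grid = default_grid(grid_n)
    rng = np.random.default_rng(seed)
    args = (constraints, scenario, grid)

    if init == "ball":
        bounds = scenario.prior_bounds()
        names = scenario.param_names()
        lo = np.array([bounds[k][0] for k in names])
        hi = np.array([bounds[k][1] for k in names])
        center = np.clip(_ball_center(scenario), lo, hi)
        width = 0.02 * (hi - lo)

    def _draw_batch(n):
        if init == "prior":
            return sample_prior(scenario, n, rng)
        x = rng.normal(center, width, size=(n, ndim))
        return np.clip(x, lo, hi)

    # rejection-initialize walkers at finite posterior
    p0 = np.empty((n_walkers, ndim))
    found = 0
    tried = 0
    ok = 0
    max_tries = 400 * n_walkers
    while found < n_walkers and tried < max_tries:
        batch = _draw_batch(64)
        for x in batch:
            tried += 1
            if not np.isfinite(log_prior(x, scenario)):
                continue
            out = log_posterior(x, *args)
            if np.isfinite(out[0]):
                ok += 1
                if found < n_walkers:
                    p0[found] = x
                    found += 1
            if found >= n_walkers:
                break
    if found < n_walkers:
        raise RuntimeError(
            f"could not initialize {n_walkers} walkers in {max_tries} tries")
    prior_success = ok / max(tried, 1)
    logger.info("initialized %d walkers (%.1f%% of prior-box tries usable)",
                n_walkers, 100 * prior_success)

    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_posterior, args=args, blobs_dtype=BLOB_DTYPE)
    # emcee draws from a module-held RandomState; pin it for determinism
    sampler._random = np.random.RandomState(int((seed + 1) % 2**31))
    sampler.run_mcmc(p0, n_steps, progress=progress,
                     skip_initial_state_check=True)

    acc = sampler.acceptance_fraction
    if float(np.max(acc)) == 0.0:
        raise RuntimeError("all walkers stuck: zero acceptance over the run")
    try:
        tau = sampler.get_autocorr_time(quiet=True)
    except Exception:     # pragma: no cover - emcee raises on short chains
        tau = None
    logger.info("mean acceptance fraction %.3f", float(np.mean(acc)))

    return PosteriorChain(
        samples=sampler.get_chain(), log_prob=sampler.get_log_prob(),
        blobs=sampler.get_blobs(), param_names=scenario.param_names(),
        scenario=scenario, seed=seed, burn_in=burn_in,
        acceptance_fraction=acc, autocorr_time=tau,
        prior_predictive_success=prior_success)


#: trajectory series summarized into posterior time envelopes
ENVELOPE_COLUMNS = (
    "delta_carb_buried", "delta_org_buried", "f_org", "f_org_apparent",
    "K_oxy", "F_burial_org", "F_weath_org", "F_weath_carb", "F_outg",
    "delta_inputs", "delta_mantle", "delta_carb", "R_org", "R_carb",
    "R_mantle", "pCO2_ppm", "T_s", "pH", "redox_imbalance",
)

_QUANTS = (0.025, 0.16, 0.5, 0.84, 0.975)
_QLABELS = ("q025", "q16", "q50", "q84", "q975")


@dataclass
class PosteriorSummary:
    """Posterior medians, credible intervals, and derived distributions."""

    scenario_name: str
    n_draws: int
    params: dict                    # name -> {q025, q16, q50, q84, q975}
    derived: dict                   # fold change, modern f_org, ...
    frac_archean_koxy_lt1: float
    envelopes: dict = field(default_factory=dict)  # column -> DataFrame

    def fold_change_summary(self) -> dict:
        return self.derived["fold_change"]

    def to_json(self, path) -> None:
        doc = {"scenario": self.scenario_name, "n_draws": self.n_draws,
               "params": self.params, "derived": self.derived,
               "frac_archean_koxy_lt1": self.frac_archean_koxy_lt1}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)

    def envelopes_to_csv(self, directory) -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.envelopes.items():
            df.to_csv(directory / f"envelope_{name}.csv", index=False,
                      float_format="%.8g")


def _qdict(values) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return {k: float("nan") for k in _QLABELS}
    qs = np.quantile(values, _QUANTS)
    return dict(zip(_QLABELS, (float(v) for v in qs)))


def summarize(chain: PosteriorChain, n_envelope: int = 100,
              envelope_grid_n: int = 206, seed: int = 0) -> PosteriorSummary:
    """Posterior summary of a chain (requires >= 1000 retained draws).

    Time envelopes are built by re-running the forward model on a random
    posterior subsample and taking pointwise quantiles.
    """
    flat = chain.flat()
    if flat.shape[0] < 1000:
        raise ValueError(
            f"only {flat.shape[0]} retained samples; need >= 1000")
    blobs = chain.flat_blobs()
    scen = chain.scenario

    params = {n: _qdict(flat[:, i])
              for i, n in enumerate(chain.param_names)}
    derived = {
        "fold_change": _qdict(blobs["fold_change"]),
        "modern_forg": _qdict(blobs["modern_forg"]),
        "modern_burial": _qdict(blobs["modern_burial"]),
        "archean_koxy": _qdict(blobs["archean_koxy"]),
        "modern_delta_inputs": _qdict(blobs["modern_delta_inputs"]),
    }
    if scen.forg_variant == "piecewise":
        names = list(chain.param_names)
        derived["archean_to_proterozoic"] = _qdict(flat[:, names.index("j2")])
        derived["proterozoic_to_phanerozoic"] = _qdict(
            flat[:, names.index("j3")])
    koxy = blobs["archean_koxy"]
    koxy = koxy[np.isfinite(koxy)]
    frac = float(np.mean(koxy < 1.0)) if len(koxy) else float("nan")

    envelopes: dict[str, pd.DataFrame] = {}
    if n_envelope > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(flat.shape[0], size=min(n_envelope, flat.shape[0]),
                         replace=False)
        grid = default_grid(envelope_grid_n)
        rows = []
        for i in idx:
            p = ModelParams.from_vector(flat[i], scen.forg_variant)
            try:
                traj = integrate(p, scen, grid=grid)
            except IntegrationError:
                continue
            rows.append([traj.series(c) for c in ENVELOPE_COLUMNS])
        if rows:
            cube = np.array(rows)     # (ndraw, ncol, ntime)
            for j, col in enumerate(ENVELOPE_COLUMNS):
                qs = np.nanquantile(cube[:, j, :], _QUANTS, axis=0)
                df = pd.DataFrame({"t_ga": grid})
                for lbl, q in zip(_QLABELS, qs):
                    df[lbl] = q
                envelopes[col] = df

    return PosteriorSummary(
        scenario_name=scen.name, n_draws=int(flat.shape[0]),
        params=params, derived=derived, frac_archean_koxy_lt1=frac,
        envelopes=envelopes)
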
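"""Shared fixtures: default parameter points, scenarios, cached trajectories."""

from __future__ import annotations

import numba
import numpy as np
import pytest

import paleocarb as pc
from paleocarb import constants as C
from paleocarb import _kernel as K
from paleocarb.scenario import pack_theta


@pytest.fixture(scope="session")
def nominal_scenario():
    return pc.Scenario(name="nominal")


@pytest.fixture(scope="session")
def default_params():
    return pc.ModelParams()


@pytest.fixture(scope="session")
def nominal_trajectory(default_params, nominal_scenario):
    """One forward integration at the shipped synthetic-truth point."""
    return pc.integrate(default_params, nominal_scenario)


def draw_valid_params(rng: np.random.Generator, scenario: pc.Scenario,
                      n: int) -> list[pc.ModelParams]:
    """Rejection-sample n parameter vectors with finite prior probability."""
    out = []
    while len(out) < n:
        x = pc.inversion.sample_prior(scenario, 64, rng)
        for xi in x:
            if np.isfinite(pc.log_prior(xi, scenario)):
                out.append(pc.ModelParams.from_vector(
                    xi, scenario.forg_variant))
                if len(out) >= n:
                    break
    return out


@pytest.fixture(scope="session")
def valid_param_draws(nominal_scenario):
    """Reproducible draws from the nominal prior support."""
    rng = np.random.default_rng(20260923)
    return draw_valid_params(rng, nominal_scenario, 20)


@numba.njit(cache=True)
def _rk4_loop(y, t, tau_target, theta, dt_max):
    # predeclared step schedule: geometric ramp (dt = t/4000, floored at
    # 10 yr) through the stiff initial ocean-equilibration transient, then
    # a fixed step small enough for the measured stiffest mode
    # (|lambda| ~ 2e-4 / yr -> dt_max 4 kyr keeps RK4 stable and accurate)
    while t < tau_target - 1e-6:
        h = min(max(10.0, 2.5e-4 * t), dt_max, tau_target - t)
        k1 = K.rhs(t, y, theta)
        k2 = K.rhs(t + 0.5 * h, y + 0.5 * h * k1, theta)
        k3 = K.rhs(t + 0.5 * h, y + 0.5 * h * k2, theta)
        k4 = K.rhs(t + h, y + h * k3, theta)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
        if np.isnan(y[0]) or np.isnan(y[4]):
            break       # schedule unstable for this draw; caller skips it
    return y, t


def rk4_integrate(params: pc.ModelParams, scenario: pc.Scenario,
                  grid_ga: np.ndarray, dt_yr: float = 4e3) -> np.ndarray:
    """Independent fixed-schedule RK4 integration of the kernel RHS.

    The oracle for the adaptive integrator.  Returns the state at the
    requested grid ages, shape (len(grid_ga), 9).  Draws whose stiffness
    exceeds the explicit schedule return NaNs (detected immediately) and
    are skipped by the caller; the comparison set is drawn until enough
    oracle-stable draws are certified.
    """
    theta = pack_theta(params, scenario)
    taus = (C.T_START - np.asarray(grid_ga)) * 1e9
    order = np.argsort(taus)
    y = K.initial_state(theta)
    out = np.full((len(taus), K.NY), np.nan)
    t = 0.0
    for k, tau_target in enumerate(taus[order]):
        y, t = _rk4_loop(y, t, tau_target, theta, dt_yr)
        if np.isnan(y[0]) or np.isnan(y[4]):
            return out
        out[order[k]] = y
    return out


def make_flat_trajectory(**overrides) -> pc.Trajectory:
    """A hand-built constant trajectory for likelihood unit tests.

    All columns default to benign constants; keyword overrides replace
    individual columns (scalars are broadcast).
    """
    n = 42
    t_ga = np.linspace(C.T_START, 0.0, n)
    defaults = {c: np.zeros(n) for c in pc.forward.TRAJECTORY_COLUMNS}
    defaults.update(
        t_ga=t_ga,
        R_AO=np.full(n, C.R_AO_MOD), A_AO=np.full(n, C.A_AO_MOD),
        R_org=np.full(n, C.R_ORG_MOD), R_carb=np.full(n, C.R_CARB_MOD),
        R_mantle=np.full(n, C.R_MANTLE_MOD),
        delta_mantle=np.full(n, C.DELTA_MANTLE_MOD),
        delta_carb_buried=np.zeros(n),
        delta_org_buried=np.full(n, -C.DELTA_ORG_OFFSET),
        pCO2_ppm=np.full(n, C.PCO2_MOD_PPM), T_s=np.full(n, C.T_SURF_MOD),
        pH=np.full(n, C.PH_MOD),
        F_out_mantle=np.full(n, C.F_OUT_MANTLE_MOD),
        F_outg=np.full(n, 6e12),
        F_burial_org=np.full(n, 1e13), F_weath_org=np.full(n, 5e12),
        K_oxy=np.full(n, 0.8),
        f_org=np.full(n, 0.3),
    )
    for key, val in overrides.items():
        if key not in defaults:
            raise KeyError(key)
        defaults[key] = np.broadcast_to(np.asarray(val, dtype=float),
                                        (n,)).copy()
    return pc.Trajectory(data=defaults, params=pc.ModelParams(),
                         scenario=pc.Scenario(name="_test"))
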
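"""Jitted numerical core of the forward model.

The inverse analysis evaluates the forward model O(10^4)-O(10^6) times per
run, so the ODE right-hand side, the flux closures and the ocean carbonate
system solver are compiled with numba.  The public operations in
:mod:`paleocarb.forward` are thin validated wrappers over the same jitted
functions, which guarantees that the formulas exercised by the unit tests are
bit-for-bit the formulas integrated inside the ODE.

State vector layout (all extensive quantities)::

    y = [R_AO, R_org, R_carb, R_mantle, A_AO, D_AO, D_org, D_carb, D_mantle]

where ``D_i = R_i * delta_i`` (mol * permil) carries the 13C bookkeeping in
the standard linearized form; conservation of total carbon and of total 13C
is then the statement that the sums of the R-derivatives and of the
D-derivatives both vanish identically.

Parameters, scenario switches and closure constants are packed into a single
float64 ``theta`` vector (see the ``I*`` index constants) so the kernel has a
single, flat calling convention.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import constants as C

# --- theta layout: sampled parameters (Table-2 unknowns) ------------------
IJ1, IJ2, IJ3 = 0, 1, 2          # piecewise f_org; linear variant reuses
#                                  slot 0 for a_grad and slot 1 for b_int
IFOXID = 3                       # modern oxidative weathering flux (mol C/yr)
IFTHERMO = 4                     # modern thermogenic CH4 oxidation (mol C/yr)
ILOGPO2 = 5                      # log10 Proterozoic pO2 (PAL)
ILOGPCO2 = 6                     # log10 initial pCO2 (bar)
IALPHA = 7                       # CO2 exponent of continental weathering
ITE = 8                          # e-folding temperature (K)
IMU = 9                          # outgassing-heatflow exponent
IBETA = 10                       # spreading-heatflow exponent
INOUT = 11                       # heatflow-evolution exponent
IEBAS = 12                       # seafloor weathering activation energy (J/mol)
IFWC = 13                        # modern carbonate weathering flux (mol C/yr)
IFLAND = 14                      # Archean land fraction (of modern)
ITGROW = 15                      # continental growth midpoint (Ga)
IPHINIT = 16                     # initial ocean pH
ILOGRCARB = 17                   # log10 initial crustal carbonate (mol C)
IRMANTLE = 18                    # initial mantle carbon (mol C)
IXIORG = 19                      # organic subduction efficiency
IXICARB = 20                     # modern carbonate subduction efficiency
N_SAMPLED = 21

# --- theta layout: scenario switches --------------------------------------
IVARIANT = 21                    # 0 piecewise f_org, 1 linear
IOXWEXP = 22                     # O2 exponent of oxidative weathering
ITHERMO_ON = 23                  # 1: include thermogenic term
ICARBW = 24                      # 0 power law, 1 Michaelis-Menten CO2 factor
ILANDCONST = 25                  # 1: land fraction pinned at modern
IREDUCED = 26                    # 1: reduced Archean mantle (redox module)
ISUBEVO = 27                     # 1: xi_carb evolves with heatflow
IEPSCARB = 28                    # permil, buried-carbonate minus delta_AO

# --- theta layout: closure constants --------------------------------------
IFSIL = 29
IFDIS = 30
IFOUTM = 31
IFMETAC = 32
IFMETAO = 33
IFSUBC = 34
IFSUBO = 35
ILAMXI = 36
ITPOFF = 37
IKOC = 38                        # ocean carbonate precipitation rate constant
IKPORE = 39                      # pore-space precipitation rate constant
IRORG0 = 40
IOXID_ON = 41                    # 1: include the O2-dependent oxidative term
N_THETA = 42

# --- flux/diagnostic vector layout ----------------------------------------
FWC, FWO, FBORG, FPOC, FPPORE, FFSIL, FFDIS = 0, 1, 2, 3, 4, 5, 6
FSUBO, FSUBC, FMETAO, FMETAC, FOUTM, FOUTG = 7, 8, 9, 10, 11, 12
FXIORG, FXICARB, FPCO2, FTS, FPH, FOMEGA, FFORG = 13, 14, 15, 16, 17, 18, 19
FDINP, FPO2, FLAND, FQ, FS = 20, 21, 22, 23, 24
N_FLUX = 25

NY = 9


@njit(cache=True)
def smoothstep(x):
    """Cubic smoothstep clamped to [0, 1]."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x * x * (3.0 - 2.0 * x)


@njit(cache=True)
def heatflow(t_ga, n_out, beta):
    """Relative heatflow Q and spreading rate S = Q**beta at age t_ga."""
    q = (C.AGE_EARTH / (C.AGE_EARTH - t_ga)) ** n_out
    return q, q ** beta


@njit(cache=True)
def land_fraction(t_ga, f_arch, t_grow):
    """Subaerial land relative to modern; smooth ramp centered on t_grow."""
    w = C.LAND_RAMP_HALFWIDTH
    u = smoothstep((t_grow + w - t_ga) / (2.0 * w))
    return f_arch + (1.0 - f_arch) * u


@njit(cache=True)
def po2_relative(t_ga, log10_po2_prot):
    """Prescribed pO2 (PAL): eon steps with 50 Myr smooth ramps."""
    w = C.PO2_RAMP_HALFWIDTH
    lo_arch = math.log10(C.PO2_ARCHEAN)
    lo_phan = math.log10(C.PO2_PHANEROZOIC)
    # Archean -> Proterozoic at 2.5 Ga
    u1 = smoothstep((C.GOE_AGE + w - t_ga) / (2.0 * w))
    # Proterozoic -> Phanerozoic at 0.5 Ga
    u2 = smoothstep((C.NOE_AGE + w - t_ga) / (2.0 * w))
    lo = lo_arch + u1 * (log10_po2_prot - lo_arch) + u2 * (lo_phan - log10_po2_prot)
    return 10.0 ** lo


@njit(cache=True)
def epoch_forg(t_ga, theta):
    """Fractional organic burial at age t_ga for the configured variant.

    Epoch boundaries (4.0, 2.5, 0.5 Ga) are crossed with a +-25 Myr
    smoothstep so the ODE right-hand side stays continuous.
    """
    w = C.FORG_RAMP_HALFWIDTH
    u0 = smoothstep((4.0 + w - t_ga) / (2.0 * w))
    if theta[IVARIANT] == 1.0:
        f = theta[IJ1] * (4.0 - t_ga) + theta[IJ2]
        if f < 0.0:
            f = 0.0
        return u0 * f
    v1 = theta[IJ1]
    v2 = v1 * theta[IJ2]
    v3 = v2 * theta[IJ3]
    u1 = smoothstep((C.GOE_AGE + w - t_ga) / (2.0 * w))
    u2 = smoothstep((C.NOE_AGE + w - t_ga) / (2.0 * w))
    return u0 * v1 + u1 * (v2 - v1) + u2 * (v3 - v2)


@njit(cache=True)
def max_epoch_forg(theta):
    """Largest f_org over the run; >= 1 flags the draw invalid in the prior."""
    if theta[IVARIANT] == 1.0:
        f0 = theta[IJ1] * 4.0 + theta[IJ2]
        f4 = theta[IJ2]
        return max(f0, f4)
    v1 = theta[IJ1]
    v2 = v1 * theta[IJ2]
    v3 = v2 * theta[IJ3]
    return max(v1, max(v2, v3))


@njit(cache=True)
def solve_carbonate_system(r_ao, a_ao):
    """Partition R_AO between atmosphere and ocean speciation.

    Solves total-carbon = R_AO at fixed carbonate alkalinity by bisection on
    ln[H+].  Returns (pco2_bar, h, co3, dic, ok); ok=False when no root
    exists in the pH 1..13 bracket (degenerate alkalinity/carbon ratio).
    """
    a = a_ao / C.M_OCEAN
    if a <= 0.0 or r_ao <= 0.0:
        return 0.0, 0.0, 0.0, 0.0, False
    atm_per_conc = C.N_ATM_PER_BAR / (C.KH_CO2 * C.M_OCEAN)

    ln_lo = math.log(1e-13)
    ln_hi = math.log(1e-1)
    # total carbon is monotonically increasing in h at fixed alkalinity
    f_lo = -1.0
    f_hi = 1.0
    for it in range(2):
        h = math.exp(ln_lo if it == 0 else ln_hi)
        denom = C.K1_CARB / h + 2.0 * C.K1_CARB * C.K2_CARB / (h * h)
        s = a / denom
        tot = s * (atm_per_conc + 1.0 + C.K1_CARB / h
                   + C.K1_CARB * C.K2_CARB / (h * h)) * C.M_OCEAN
        if it == 0:
            f_lo = tot - r_ao
        else:
            f_hi = tot - r_ao
    if f_lo > 0.0 or f_hi < 0.0:
        return 0.0, 0.0, 0.0, 0.0, False

    for _ in range(60):
        ln_mid = 0.5 * (ln_lo + ln_hi)
        h = math.exp(ln_mid)
        denom = C.K1_CARB / h + 2.0 * C.K1_CARB * C.K2_CARB / (h * h)
        s = a / denom
        tot = s * (atm_per_conc + 1.0 + C.K1_CARB / h
                   + C.K1_CARB * C.K2_CARB / (h * h)) * C.M_OCEAN
        if tot > r_ao:
            ln_hi = ln_mid
        else:
            ln_lo = ln_mid
    h = math.exp(0.5 * (ln_lo + ln_hi))
    denom = C.K1_CARB / h + 2.0 * C.K1_CARB * C.K2_CARB / (h * h)
    s = a / denom
    hco3 = C.K1_CARB * s / h
    co3 = C.K2_CARB * hco3 / h
    dic = s + hco3 + co3
    pco2 = s / C.KH_CO2
    return pco2, h, co3, dic, True


@njit(cache=True)
def surface_temperature(pco2_bar, t_ga):
    """Log-CO2 climate function with main-sequence solar brightening."""
    lum = 1.0 / (1.0 + 0.4 * t_ga / C.SUN_AGE)
    return (C.T_SURF_MOD
            + C.CLIMATE_SENSITIVITY * math.log(pco2_bar / C.PCO2_MOD_BAR)
            + C.LUMINOSITY_SENSITIVITY * (lum - 1.0))


@njit(cache=True)
def climate_ocean_state(r_ao, a_ao, t_ga):
    """Self-consistent (pCO2 bar, T_s, pH, Omega); NaNs when degenerate.

    The carbonate speciation and the climate function are iterated to the
    declared fixed point (the apparent equilibrium constants carry no
    explicit temperature dependence, so the loop converges immediately; the
    cap guards swapped-in temperature-dependent closures).
    """
    pco2_prev = -1.0
    pco2 = 0.0
    h = 0.0
    co3 = 0.0
    for _ in range(C.CARB_CHEM_MAXITER):
        pco2, h, co3, _dic, ok = solve_carbonate_system(r_ao, a_ao)
        if not ok:
            return np.nan, np.nan, np.nan, np.nan
        if pco2_prev > 0.0 and abs(pco2 - pco2_prev) <= C.CARB_CHEM_RTOL * pco2:
            break
        pco2_prev = pco2
    ts = surface_temperature(pco2, t_ga)
    ph = -math.log10(h)
    omega = C.CA_CONC * co3 / C.KSP_CALCITE
    return pco2, ts, ph, omega


@njit(cache=True)
def compute_fluxes(t_ga, y, theta):
    """All instantaneous fluxes and diagnostics at one state/time.

    Returns a length-N_FLUX vector (see F* index constants).  NaN pCO2
    signals a failed ocean-chemistry solve; the integrator will reject the
    step and, if persistent, the run is flagged as an integration failure.
    """
    out = np.empty(N_FLUX)
    r_ao, r_org, r_carb, r_mantle, a_ao = y[0], y[1], y[2], y[3], y[4]
    # reservoir deltas (guarded against tiny reservoirs)
    d_org = y[6] / max(r_org, 1e8)
    d_carb = y[7] / max(r_carb, 1e8)
    d_mantle = y[8] / max(r_mantle, 1e8)

    q, s_rate = heatflow(t_ga, theta[INOUT], theta[IBETA])
    if theta[ILANDCONST] == 1.0:
        fland = 1.0
    else:
        fland = land_fraction(t_ga, theta[IFLAND], theta[ITGROW])
    po2 = po2_relative(t_ga, theta[ILOGPO2])

    pco2, ts, ph, omega = climate_ocean_state(r_ao, a_ao, t_ga)
    pco2_rel = pco2 / C.PCO2_MOD_BAR
    dts = ts - C.T_SURF_MOD

    # --- weathering ---
    if theta[ICARBW] == 1.0:
        co2_fac = (2.0 * pco2_rel / (1.0 + pco2_rel)) ** theta[IALPHA]
    else:
        co2_fac = pco2_rel ** theta[IALPHA]
    f_wc = (theta[IFWC] * (r_carb / C.R_CARB_MOD) * fland * co2_fac
            * math.exp(dts / theta[ITE]))
    f_wo = 0.0
    if theta[IOXID_ON] == 1.0:
        f_wo = theta[IFOXID] * (r_org / C.R_ORG_MOD) * fland \
            * po2 ** theta[IOXWEXP]
    if theta[ITHERMO_ON] == 1.0:
        f_wo += theta[IFTHERMO] * (r_org / C.R_ORG_MOD)
    f_sil = theta[IFSIL] * fland * pco2_rel ** theta[IALPHA] \
        * math.exp(dts / theta[ITE])
    t_pore = ts + theta[ITPOFF]
    t_pore_mod = C.T_SURF_MOD + theta[ITPOFF]
    f_dis = theta[IFDIS] * s_rate ** theta[IBETA] * math.exp(
        -theta[IEBAS] / C.R_GAS * (1.0 / t_pore - 1.0 / t_pore_mod))

    # --- subduction, metamorphism, outgassing ---
    xi_org = theta[IXIORG]
    if theta[ISUBEVO] == 1.0:
        xi_carb = theta[IXICARB] * math.exp(-theta[ILAMXI] * (q - 1.0))
    else:
        xi_carb = theta[IXICARB]
    qmu = q ** theta[IMU]
    f_outm = theta[IFOUTM] * (r_mantle / C.R_MANTLE_MOD) * qmu
    f_metac = theta[IFMETAC] * (r_carb / C.R_CARB_MOD) * qmu
    f_metao = theta[IFMETAO] * (r_org / C.R_ORG_MOD) * qmu
    f_subc = theta[IFSUBC] * (r_carb / C.R_CARB_MOD) * s_rate
    f_subo = theta[IFSUBO] * (r_org / C.R_ORG_MOD) * s_rate
    f_outg = (f_outm + f_metao + f_metac
              + f_subo * (1.0 - xi_org) + f_subc * (1.0 - xi_carb))

    # --- carbonate burial ---
    ex = max(omega - 1.0, 0.0) ** C.PRECIP_EXPONENT
    p_ocean = theta[IKOC] * ex
    p_pore = theta[IKPORE] * s_rate * ex

    # --- organic burial (steady-state atmosphere-ocean partitioning) ---
    forg = epoch_forg(t_ga, theta)
    total_in = f_wc + f_wo + f_outg
    f_borg = forg * total_in

    # --- flux-weighted delta of inputs to the atmosphere-ocean system ---
    if total_in > 0.0:
        d_in = (d_carb * (f_wc + f_metac + (1.0 - xi_carb) * f_subc)
                + d_org * (f_wo + f_metao + (1.0 - xi_org) * f_subo)
                + d_mantle * f_outm) / total_in
    else:
        d_in = np.nan

    out[FWC] = f_wc
    out[FWO] = f_wo
    out[FBORG] = f_borg
    out[FPOC] = p_ocean
    out[FPPORE] = p_pore
    out[FFSIL] = f_sil
    out[FFDIS] = f_dis
    out[FSUBO] = f_subo
    out[FSUBC] = f_subc
    out[FMETAO] = f_metao
    out[FMETAC] = f_metac
    out[FOUTM] = f_outm
    out[FOUTG] = f_outg
    out[FXIORG] = xi_org
    out[FXICARB] = xi_carb
    out[FPCO2] = pco2
    out[FTS] = ts
    out[FPH] = ph
    out[FOMEGA] = omega
    out[FFORG] = forg
    out[FDINP] = d_in
    out[FPO2] = po2
    out[FLAND] = fland
    out[FQ] = q
    out[FS] = s_rate
    return out


@njit(cache=True)
def rhs(tau_yr, y, theta):
    """Time derivative of the 9-component state; tau is years since 4.1 Ga."""
    t_ga = C.T_START - tau_yr * 1e-9
    f = compute_fluxes(t_ga, y, theta)
    dy = np.empty(NY)
    if not np.isfinite(f[FPCO2]):
        for i in range(NY):
            dy[i] = np.nan
        return dy

    d_ao = y[5] / max(y[0], 1e8)
    d_org = y[6] / max(y[1], 1e8)
    d_carb = y[7] / max(y[2], 1e8)
    d_mantle = y[8] / max(y[3], 1e8)
    eps = theta[IEPSCARB]
    d_carb_b = d_ao + eps
    d_org_b = d_carb_b - C.DELTA_ORG_OFFSET

    p_tot = f[FPOC] + f[FPPORE]
    arc_c = (1.0 - f[FXICARB]) * f[FSUBC]
    arc_o = (1.0 - f[FXIORG]) * f[FSUBO]

    dy[0] = f[FOUTG] + f[FWC] + f[FWO] - p_tot - f[FBORG]
    dy[1] = f[FBORG] - f[FSUBO] - f[FMETAO] - f[FWO]
    dy[2] = p_tot - f[FWC] - f[FSUBC] - f[FMETAC]
    dy[3] = f[FXICARB] * f[FSUBC] + f[FXIORG] * f[FSUBO] - f[FOUTM]
    dy[4] = 2.0 * (f[FFSIL] + f[FWC] + f[FFDIS] - f[FPOC] - f[FPPORE])
    # 13C bookkeeping: every flux carries the delta of its source reservoir;
    # burial carries delta_AO + eps (carbonate) and that minus 28 (organic).
    dy[5] = (d_carb * (f[FWC] + f[FMETAC] + arc_c)
             + d_org * (f[FWO] + f[FMETAO] + arc_o)
             + d_mantle * f[FOUTM]
             - d_carb_b * p_tot - d_org_b * f[FBORG])
    dy[6] = d_org_b * f[FBORG] - d_org * (f[FSUBO] + f[FMETAO] + f[FWO])
    dy[7] = d_carb_b * p_tot - d_carb * (f[FWC] + f[FSUBC] + f[FMETAC])
    dy[8] = (d_carb * f[FXICARB] * f[FSUBC] + d_org * f[FXIORG] * f[FSUBO]
             - d_mantle * f[FOUTM])
    return dy


@njit(cache=True)
def initial_state(theta):
    """State vector at 4.1 Ga from the sampled initial conditions."""
    pco2 = 10.0 ** theta[ILOGPCO2]
    h = 10.0 ** (-theta[IPHINIT])
    s = C.KH_CO2 * pco2
    hco3 = C.K1_CARB * s / h
    co3 = C.K2_CARB * hco3 / h
    dic = s + hco3 + co3
    alk = hco3 + 2.0 * co3
    r_ao = pco2 * C.N_ATM_PER_BAR + dic * C.M_OCEAN
    a_ao = alk * C.M_OCEAN
    r_org = theta[IRORG0]
    r_carb = 10.0 ** theta[ILOGRCARB]
    r_mantle = theta[IRMANTLE]
    y0 = np.empty(NY)
    y0[0] = r_ao
    y0[1] = r_org
    y0[2] = r_carb
    y0[3] = r_mantle
    y0[4] = a_ao
    # all initial carbon carries mantle delta13C except the (negligible)
    # organic seed, offset by the photosynthetic fractionation
    y0[5] = r_ao * C.DELTA_MANTLE_MOD
    y0[6] = r_org * (C.DELTA_MANTLE_MOD - C.DELTA_ORG_OFFSET)
    y0[7] = r_carb * C.DELTA_MANTLE_MOD
    y0[8] = r_mantle * C.DELTA_MANTLE_MOD
    return y0


@njit(cache=True)
def compute_fluxes_batch(grid_ga, Y, theta):
    """compute_fluxes over a whole trajectory; Y has shape (NY, n)."""
    n = grid_ga.shape[0]
    out = np.empty((N_FLUX, n))
    for i in range(n):
        out[:, i] = compute_fluxes(grid_ga[i], Y[:, i], theta)
    return out
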
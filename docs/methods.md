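# Methods

## The model

`paleocarb` integrates a five-reservoir model of the long-term carbon cycle
from 4.1 Ga to the present: carbon in the atmosphere–ocean system (R_AO),
crustal organic carbon (R_org), crustal carbonate carbon (R_carb), mantle
carbon (R_mantle), and atmosphere–ocean carbonate alkalinity (A_AO).  The
solid Earth is treated as an infinite alkalinity reservoir.  Carbon moves
between reservoirs by carbonate and organic weathering, organic burial,
ocean and pore-space carbonate precipitation, subduction, metamorphic
devolatilization, and mantle outgassing; total outgassing is the sum of the
mantle flux, the two metamorphic fluxes, and the arc-returned complements
(1−ξ) of the two subduction fluxes, where ξ_org and ξ_carb are subduction
efficiencies (the fractions delivered to the mantle).

Fractional organic burial f_org is *not* predicted from productivity or
nutrient cycling; it is a free history fitted to data.  Two functional
forms are supported: an epoch-wise form (zero before 4.0 Ga, j1 in the
Archean, j1·j2 in the Proterozoic, j1·j2·j3 after 0.5 Ga) and a linear form
a_grad·(4.0 − t) + b_int floored at zero.  The absolute burial flux follows
from steady-state partitioning of the total carbon input to the
atmosphere–ocean system:

    F_burial_org = f_org · (F_weath_carb + F_weath_org + F_outg)

Organic weathering is the sum of an oxidative term, scaling with the
crustal organic reservoir, land fraction and pO2^0.3 (exponent switchable
to 0.5 or 0), and an O2-independent thermogenic-methane photo-oxidation
term scaling with the reservoir only.  Atmospheric O2 is prescribed per
eon — 10⁻⁹ PAL in the Archean, a sampled value in 10⁻³–10⁻¹ PAL in the
Proterozoic, 1 PAL after 0.5 Ga — with 50-Myr smoothstep ramps at 2.5 and
0.5 Ga so the ODE right-hand side stays continuous.  The same ±25 Myr
smoothing is applied to the f_org epoch boundaries; all stated epoch
values hold exactly away from the ramps.

### Isotope bookkeeping

Each reservoir carries a δ¹³C; the integrated state uses the linearized
masses D_i = R_i·δ_i.  Every flux carries the δ of its source reservoir
(arc volcanism returns subducted material at the δ of the crustal
reservoir it came from — instantaneous recycling, no slab residence
time).  Burial fractionation is imposed as a fixed 28‰ separation:
carbonates are buried at δ_AO (zero carbonate–DIC offset; a symmetric
split is available as the `carb_burial_offset` scenario switch) and
organics at δ_AO − 28‰.  With this construction the sums of the four
carbon derivatives and of the four D derivatives vanish identically, so
total carbon and total ¹³C are conserved to integrator precision (the
test suite checks 10⁻⁶ relative; observed drift is ~10⁻¹⁵).  The mantle
δ evolves by exact bookkeeping of subducted inputs versus outgassed
outputs, with no parameterized relaxation.

### Declared closures

Closures not pinned by the reservoir equations are declared explicitly and
exposed through the scenario configuration (all fluxes mol C/yr):

| closure | form | default |
|---|---|---|
| heatflow | Q(t) = (4.5/(4.5−t))^n_out, S = Q^β | — |
| land fraction | smoothstep ramp, half-width 0.5 Ga, centered on t_grow | — |
| silicate weathering | F_sil_mod·f_land·(pCO2/pCO2_mod)^α·e^(ΔT/T_e) | F_sil_mod = 10×10¹² |
| seafloor dissolution | F_dis_mod·S^β·exp(−E_bas/R·(1/T_pore−1/T_pore_mod)), T_pore = T_s − 13 K | F_dis_mod = 0.45×10¹² |
| carbonate precipitation | P = k·(Ω−1)^1.7 (ocean); ×S (pore) | k calibrated (below) |
| mantle outgassing | F_out_mantle_mod·(R_mantle/R_mantle_mod)·Q^μ | 2.5×10¹² |
| metamorphism | F_meta_x_mod·(R_x/R_x_mod)·Q^μ | 2.0 / 0.5×10¹² (carb/org) |
| subduction | F_sub_x_mod·(R_x/R_x_mod)·S | 2.5 / 1.0×10¹² (carb/org) |
| ξ_carb evolution | ξ_carb_mod·exp(−λ(Q−1)), λ = ln5/8 | ξ_carb(4 Ga) ≈ 0.2·ξ_carb_mod at n_out = 1 |

The precipitation rate constants are calibrated per parameter draw so the
modern alkalinity budget closes at the modern anchor state:
P_ocean + P_pore = F_sil_mod + F_weath_carb_mod + F_dis_mod with
P_pore(modern) = F_dis(modern).  Modern reference values used in all
"relative to modern" ratio terms are fixed constants (R_org 1.66×10²¹,
R_carb 9.4×10²¹, R_mantle 2×10²² mol C, 280 ppm CO2, 1 PAL O2), not the
run's own endpoint.

### Ocean chemistry and climate

The atmosphere–ocean carbon pool is partitioned self-consistently between
atmospheric CO2 and ocean speciation at fixed carbonate alkalinity, using
apparent seawater equilibrium constants (pK1 = 6.0, pK2 = 9.1,
K_H = 0.033 mol kg⁻¹ bar⁻¹, ocean mass 1.4×10²¹ kg, 1.8×10²⁰ mol of
atmosphere per bar).  The total-carbon residual is monotone in [H⁺], so
the solve is a bracketed bisection on ln[H⁺] over pH 1–13, embedded in the
declared fixed-point loop (cap 100 iterations, relative tolerance 10⁻⁴;
with temperature-independent constants the loop converges immediately).
Surface temperature is a logarithmic CO2 climate function anchored at
285 K for 280 ppm under modern luminosity, with sensitivity 5.6 K per ln
unit (≈3.9 K per doubling) and a main-sequence solar brightening term
(70 K per unit relative luminosity, L(t) = 1/(1 + 0.4·t/4.57)).  The
modern anchor state reproduces 280 ppm, 285 K, pH 8.2 and Ω = 3 by
construction; carbonate saturation uses fixed [Ca²⁺] = 10.3 mmol/kg.

The initial state at 4.1 Ga is built from the sampled initial pCO2 and pH
(which fix R_AO and A_AO), the sampled initial crustal carbonate and
mantle reservoirs, and a negligible-but-positive organic seed
(10¹⁸ mol, avoiding zero-reservoir singularities in ratio terms).  All
initial carbon carries the mantle δ¹³C of −5.5‰ (the organic seed is
offset by −28‰).

### Integration

LSODA (via `scipy.integrate.odeint`, whose stepping loop is compiled)
with rtol 10⁻⁶ and atol 10³ mol, over an output grid of 411 points
(4.1 Ga → 0; inversions use 206 points — the likelihood needs only the
19 bin centers plus a handful of epochs, and 20-Myr output resolution is
far finer than any constraint).  Any solver failure, non-finite state or
negative reservoir raises an integration-failure signal that the
posterior maps to −∞.  The adaptive integrator is cross-checked in the
test suite against an independent fixed-step RK4 oracle; the oracle step
is 25 kyr because the atmosphere–ocean residence time is O(10⁵) yr and an
explicit method must resolve it.

## Redox bookkeeping

K_oxy compares O2 sources (organic burial plus a sulfide/Fe(II) burial
term 5.2×10¹² mol/yr scaled by f_org/f_org_modern) to fast sinks (reduced
gases, 2.4×10¹² mol/yr scaled by F_outg/F_outg_modern); K_oxy < 1
diagnoses an anoxic atmosphere.  "Archean K_oxy" for the likelihood is the
time-average over 3.8–2.5 Ga (switchable to a single epoch): the anoxia
constraint speaks about the eon, not an instant.  The
reduced-Archean-mantle scenario multiplies the reduced-gas flux by
(1 + 2.5·t/4.1), i.e. 3.5× modern at 4.1 Ga.  The surface redox imbalance
subtracts organic weathering as well; it need not vanish because the model
carries no H-escape or explicit S/Fe cycling.  The F_burial_other scaling
uses the instantaneous f_org ratio.  Burial efficiency is
F_burial_org/NPP with modern NPP 4×10¹⁵ mol C/yr; NPP histories are
supplied as piecewise-constant scenario curves and are reported, not
fitted.

## Constraints and likelihood

Thirteen constrained variables: the 200-Myr-binned carbonate and organic
δ¹³C series (compared against the model's buried-phase values δ_AO and
δ_AO − 28‰ at bin centers), eight Gaussian scalar rows (3.3 Ga mantle
outgassing ratio 8.1 ± 3.9 from Xe isotopes; modern pCO2 280 ppm ± 0.2
log₁₀ units, applied in log space; T_s 285 ± 5 K; pH 8.2 ± 0.5; the three
modern reservoirs; mantle δ¹³C at 3.5 Ga −5.5 ± 3‰ and today
−5.5 ± 0.5‰), a one-sided Archean K_oxy ≤ 1 term (quadratic penalty with
σ = 0.2 only when the window mean exceeds 1, no normalizer), and a hard
organic-burial-exceeds-weathering condition mapped to −∞.  The hard
condition is evaluated for ages < 3.95 Ga: within the 4.0 Ga switch-on
ramp f_org passes through zero by construction while weathering of the
seed reservoir is positive, so the instantaneous comparison is meaningful
only once burial has switched on.  Bins require both phases and at least
one sample; degenerate per-bin scatter takes a 0.5‰ floor (smallest
plausible analytical plus population scatter).

## Inverse analysis

emcee's affine-invariant stretch move, seeded for exact reproducibility.
Dimension 21 (epoch-wise f_org) or 20 (linear; the gradient/intercept
bounds, which the prior table of the epoch-wise variant does not fix, are declared as
b_int ∈ [0, 0.5] and a_grad ∈ [−0.1, 0.25] Gyr⁻¹, spanning the same
decline-to-large-increase range as the epoch parameters).  The prior is a
uniform box with log-uniform handling of the three log₁₀-specified
parameters, plus ξ_org > ξ_carb(modern), f_org < 1 at every epoch
(violating draws get −∞ rather than being clipped, which would distort
the posterior), and modern f_org ≥ 0.01 (the redox scalings divide by
it).  Note the prior-box *midpoint* is itself invalid (j2 = j3 = 2.75
gives max f_org ≈ 1.9): the constraints carve a non-trivial support out
of the box, and roughly 20% of box draws survive them.

Walker initialization is rejection sampling to a finite posterior, either
uniform over the prior box (default) or from a tight Gaussian ball (2% of
the prior width) around a feasible interior point.  Full-scale runs use
prior-box initialization; the scaled-down scenario suite uses ball
initialization, because at a few hundred steps a 21-dimensional ensemble
started from the prior is still dominated by it (integrated
autocorrelation times are ~25 steps), whereas the ball-initialized
ensemble reaches likelihood-shaped marginals within the first hundred
steps.  Acceptance fractions and autocorrelation estimates are logged;
there is no hard convergence gate.

Reference problem sizes: a full analysis uses 500 walkers × 10,000 steps
(5×10⁶ forward calls) with a 2,000-step burn-in; the desk-scale default
is 100 walkers × 400 steps with a 100-step burn-in, and the
scenario-suite runs use 48 walkers × 250 steps (burn 100).  The package's
forward call costs ~20 ms, so these desk configurations run in minutes.

The headline derived quantity is the fold change in f_org over Earth
history: j2·j3, or f_org(0)/f_org(3.5 Ga) for the linear variant.
Posterior summaries report per-parameter quantiles, the fold-change and
modern-f_org distributions, the fraction of draws with Archean K_oxy < 1,
and pointwise time envelopes from re-running the forward model on a
posterior subsample.

## Synthetic data

`generate_record` draws Gaussian noise around the model's buried-phase
curves at the 19 bin centers under a known truth (default: j1 = 0.1,
j2 = j3 = 1.8 — an interior test point with fold change 3.24, not a claim
about Earth) and re-bins the samples.  `stylized_record` emulates the
gross structure of the observed archive — carbonates scattered about 0‰
(sd 2‰), organics about −28‰ (sd 3‰), 20 samples per 200-Myr bin over
3.8–0 Ga — and serves as the stand-in archive for scaled-down headline
runs.  Neither generator reproduces the real archive's uneven sampling
density, diagenetic filtering, or sub-bin excursions; passing the
round-trip and surrogate tests therefore demonstrates that the inverse
machinery is unbiased and that the model's mechanisms behave as designed
under record-like data, not that the shipped numbers are Earth's.

## Numerical choices and edge cases

- Reservoir δ values are computed as D/max(R, 10⁸ mol) to avoid 0/0 at
  negligible reservoirs; the organic seed makes this path cold in
  practice.
- The carbonate solve fails (and the draw is rejected) when no root
  exists in the pH 1–13 bracket, which happens for degenerate
  alkalinity/carbon ratios (R_AO ≤ A_AO/2 in the carbonate-ion limit).
- The alkalinity equation's precipitation sink is identified with
  P_ocean + P_pore — the only precipitation terms in the model; a
  distinct shelf-precipitation term would enter the same way.
- Ties and boundaries: prior bounds are closed intervals; the smoothstep
  ramps make every prescribed step (pO2, f_org epochs, land growth) C¹.

## Limitations

- No explicit O2 ODE: pO2 is prescribed per eon, so the model can
  diagnose redox consistency (K_oxy, imbalance) but not predict oxygen.
- No authigenic or seafloor-carbonate missing sinks; no O2 dependence of
  photosynthetic fractionation (fixed 28‰); crust and mantle are
  well-mixed and isotopically homogeneous.
- The climate and ocean-chemistry closures are deliberately minimal
  (logarithmic CO2 forcing, temperature-independent apparent constants);
  they anchor the modern state exactly but are not a paleoclimate model.
- Scaled-down inversions trade posterior tail accuracy for runtime; the
  shipped configurations are sized for qualitative orderings and
  parameter recovery, with quantile uncertainty of order ±0.5 on the
  fold change.
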
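# Methods

`c4dyn` simulates the dynamics of NADP-ME-type C4 photosynthesis — the
pathway of maize, sorghum and sugarcane — during transitions between
light environments, and implements the gas-exchange analysis workflow
that parameterises the model for a species. This note documents the
model structure, the choices made where the design was genuinely open,
the parameterisation, and the limits of what the tests demonstrate.

## Model structure

The model couples four subsystems, all integrated together as one stiff
ODE system (SciPy LSODA, rtol 1e-6, atol 1e-9, with the time grid
segmented at every forcing breakpoint):

1. **Metabolic core** (`c4dyn.network`). A reduced-order two-cell
   reaction network spanning mesophyll cytosol/chloroplast and
   bundle-sheath cytosol/chloroplast plus the intercellular airspace.
   It contains the enzymes that carry flux control in this pathway —
   PEPC, PPDK, NADP-MDH, NADP-ME, a lumped mutase+enolase step, Rubisco
   (carboxylation plus a lumped oxygenation term), GAPDH in both cell
   types, FBPase, a lumped SBPase/transketolase regeneration step, PRK
   and carbonic anhydrase — along with malate/pyruvate and PGA/triose-P
   shuttles, plasmodesmatal CO2 leakage, light-driven ATP/NADPH supply,
   a carbohydrate export sink and mitochondrial respiration. Rate laws
   are irreversible Michaelis–Menten forms linear in a transient Vmax,
   with two reversible mass-action steps (CA, mutase+enolase) and
   linear-gradient transports. Net CO2 uptake A is the velocity of CO2
   flowing through the stomata into the airspace; leakiness is
   φ = v_leak / v_PEPC with v_leak = P_CO2,pd ([CO2]_BS − [CO2]_MC).

2. **Post-translational regulation** (`c4dyn.regulation`). PPDK is
   switched between active and phospho-inactive forms by the
   bifunctional regulatory protein PDRP (ADP-fuelled inactivation with
   competitive pyruvate inhibition; Pi-dependent activation inhibited by
   ADP), reading ADP, pyruvate and Pi live from the mesophyll
   chloroplast pools. Rubisco's transient maximal activity relaxes
   first-order with time constant τ_Rubisco toward a target set by the
   active Rubisco-activase pool, [Rca] = 216.9/τ_Rubisco mg m⁻²,
   half-saturating at 12.3 mg m⁻². The remaining light-modulated enzymes
   (ATPase, FBPase, GAPDH, PRK, Rca, SBPase, PEPC) follow a
   clamped-linear steady-state activation fraction
   a_s = min(k_A·I + c_A, 1) approached first-order with a per-enzyme
   time constant. Temperature responses are peaked Arrhenius (PEPC, CA),
   Arrhenius (PPDK, Rubisco, Jmax, Kc) or Q10 = 2 (all others), all
   normalised to 1 at 25 °C.

3. **Stomata** (`c4dyn.stomata`). Steady-state conductance follows
   Ball–Berry, gs* = slope·A·RH/Ca + intercept (floored at the intercept
   when A ≤ 0), and gs relaxes first-order toward it with distinct
   opening (k_i) and closing (k_d) rate constants, switching at target
   crossings with no hysteresis. gs is a water-vapour conductance; the
   CO2 path divides by 1.6 and composes in series with the boundary
   layer (÷1.37).

4. **Leaf energy balance** (`c4dyn.energy_balance`). Leaf temperature is
   a state: absorbed short-wave (85 % of PAR, 0.2175 J µmol⁻¹) and
   long-wave input balance sensible heat (both faces, g_bh = 0.924 g_b),
   latent heat (internal airspace vapour-saturated at leaf temperature),
   emitted long-wave (2εσT⁴) and the energy consumed by photosynthesis
   (0.506·A W m⁻² per µmol m⁻² s⁻¹). Boundary-layer conductance is the
   maximum of forced (∝√u) and free (∝|ΔT|^0.25) convection in the
   Nikolov formulation, floored at 1e-4 mol m⁻² s⁻¹ in still air.

### Design choices in the open

* **Long-wave input.** With emitted long-wave 2εσT⁴ and zero absorbed
  long-wave, a leaf would settle ~10 °C below air temperature, and an
  isothermal leaf in dark saturated air would not be a fixed point. The
  default absorbed long-wave is therefore the black-enclosure value at
  air temperature, 2εσT_air⁴ (ε = 0.97); an explicit value (including 0)
  overrides it.

* **Stomatal demand signal.** The Ball–Berry index is driven by
  max(A, A_demand), where A_demand is the light-gated transient Rubisco
  capacity at a reference CO2 saturation (factor 0.4) minus respiration.
  At steady state A ≥ A_demand, so the steady conductance satisfies the
  plain Ball–Berry relation in realised A (light-response regressions
  recover slope and intercept), while during induction the demand term
  anticipates the supply-limited A. This reproduces the observed
  sigmoidal opening — a lag while the enzymes activate, then rapid
  opening — which a target driven by instantaneous A alone cannot (the
  gs–A loop then relaxes several-fold slower than 1/k_i), and which a
  constant final-value target overshoots (stomata would open before the
  intercellular CO2 drawdown seen in measurements).

* **Stabilising feedbacks in the reduced core.** Three regulatory terms
  replace pathway detail that the full network resolves explicitly:
  sucrose/starch export engages sigmoidally above a hexose-phosphate
  setpoint (protecting the autocatalytic Calvin cycle during induction),
  a starch-remobilisation term buffers the hexose-phosphate pool in
  darkness (so the cycle can bootstrap at light-on), and PRK/the lumped
  regeneration step carry product feedback (RuBP, pentose-P) that caps
  those pools. PEPC carries malate+OAA feedback inhibition
  (K_i = 17 mM), which also bounds the dark C4 pools.

* **Bundle-sheath CO2 capacitance.** The BS CO2 pool is given a large
  effective capacitance (multiplier on the compartment volume)
  representing its CO2/HCO3⁻ buffering and the CO2-exchanging metabolite
  pools that the reduced network lumps away. It sets the timescale of
  the leakiness transient (the φ minimum roughly 30 s after light-on)
  and is a calibration constant; leaf-scale carbon accounting includes
  it consistently.

* **Scenario semantics.** A disabled regulatory mechanism is steered to
  its fully-light-activated value with a ~2 s time constant, i.e. held
  at its steady light-on value from t = 0; enabled mechanisms start from
  the dark-adapted state. Scenario 1 therefore fires a brief (seconds)
  transient as the dark metabolite pools re-equilibrate — comparisons
  between scenarios 4 and 5 are made after the first minute for this
  reason.

* **Dark adaptation.** Every induction starts from a 30-min dark
  pre-simulation (full dynamics) from a stored reference state shipped
  in the parameter file. The dark equilibrium of PPDK activation is
  independent of [PDRP] (both PDRP rates scale linearly with it), which
  the PDRP estimator exploits by reusing one dark state across
  candidate values.

## Parameterisation

Species-level inputs (Ball–Berry slope/intercept, k_i, k_d, Vpmax,
Vcmax, τ_Rubisco, f_VmPEPC, f_VmRubisco, [PDRP], Rd) live in
`src/c4dyn/data/species.yml` for the reference ("original") set and the
three crops. The model-level capacities are Vmax_PEPC = Vpmax/f_VmPEPC
and Vmax_Rubisco = Vcmax/f_VmRubisco; all other C4-cycle capacities
scale with the former, all Calvin-cycle capacities (plus ATP/NADPH
supply and the export sink) with the latter.

All remaining kinetic constants are in one versioned file,
`src/c4dyn/data/network.yml`. Michaelis constants take literature-range
values for the respective enzymes; compartment volumes, transport
constants, the plasmodesmatal permeability, the BS CO2 capacitance, the
PDRP turnover numbers and the light-activation coefficients are free
constants of the reduced reconstruction. They were calibrated once, as
a set, so that the reference parameter set reproduces the documented
behaviour of this system: rapid (<2 min) induction with instant
activation, a leakiness minimum ~30 s after light-on climbing to ~0.22
by 600 s, a higher (~0.27) steady leakiness when only PPDK and Rubisco
activation are dynamic, and maize induction kinetics (IT50 ≈ 190 s,
~18 % induction loss, minimum Ci in the 50–70 µmol mol⁻¹ range).
Substituting other constants is a data change, not a code change.

## Estimation workflow

* **A–Ci**: Vpmax and Vcmax by nonlinear least squares of the
  enzyme-limited von Caemmerer C4 model (Kc 650 µbar, Ko 450 mbar, Kp
  80 µbar, g_bs 3·10⁻³ mol m⁻² s⁻¹ bar⁻¹, γ* 1.93·10⁻⁴, V_pr 80); the
  light-limited branch is not used because measurements are at
  saturating light.
* **f scalars**: 1-D bounded least squares of the dynamic model's
  clamped-Ci steady-state A against the measured curve — f_VmRubisco on
  the CO2-saturated points (Ca 800–1500), then f_VmPEPC on the
  initial-slope points (Ca 120–10).
* **Ball–Berry**: plain OLS of gs on A·RH/Ca with standard errors.
* **τ_Rubisco**: regression of ln(A_f − A) on t over the 3–7 min window;
  τ = −1/slope; A_f is the mean over the final 5 min (the operational
  steady state used throughout).
* **[PDRP]**: 1-D least squares of simulated against measured A over
  the 1–3 min window; a coarse log-grid scan brackets the global basin
  before bounded refinement, because the objective develops a shallow
  secondary basin at high [PDRP] where activation no longer limits.
* **Rd**: −mean(A) over the dark tail, flagged if non-respiring.
* **Stomatal kinetics**: nonlinear fit of
  gs = (g_max − g_0)e^(−kt) + g_0; opening transients fit the mirrored
  (rising) form of the same family.

## Analyses

Scenario runner (the six regulation settings), leakiness time courses
(φ reported 0 where v_PEPC < 0.1 µmol m⁻² s⁻¹), induction metrics (IT50
by linear interpolation of the first half-crossing; induction loss
100·(1 − mean A / steady A); minimum Ci after light-on; iWUE = A/gs),
and central-difference ±1 % sensitivity coefficients
SC = (A⁺ − A⁻)/(0.02·A) for species parameters and, applied to an
enzyme's Vmax, flux control coefficients.

## Synthetic data

The generator forward-simulates the full dynamic model under the
standard measurement designs (A–Ci sequence 400→10→400→1500 µmol mol⁻¹;
A–Q sequence 2000→50 µmol m⁻² s⁻¹; 30-min dark then 30-min 1800
µmol m⁻² s⁻¹ induction; 1800/200/1800 fluctuating steps; 10-s logging;
28 °C, VPD 1.32 kPa) and applies multiplicative Gaussian noise (2 % on
A, 5 % on gs, truncated to keep gs positive, seeded). Ground truth is
carried in the file metadata. It emulates chamber gas exchange without
instrument drift, leak artefacts or matching-valve transients; passing
recovery tests therefore demonstrate estimator correctness under the
stated noise model, not robustness to instrument systematics.

## Numerical choices and problem sizes

Default runs are 30-min inductions at 2-s output resolution (~0.5 s wall
time each); steady-state leakiness uses a 60-min run. The conservation
check integrates a closed configuration (no gas exchange, export,
remobilisation or respiration) for one simulated hour at rtol 1e-10 and
verifies total carbon — including the airspace and the BS capacitance —
to 1e-8 relative. Estimator Monte-Carlo checks use 50 replicates with
fixed seeds. Concentrations are kept non-negative by the guarded rate
laws plus solver tolerances; integration aborts if any pool undershoots
beyond −1e-6 mM rather than clipping.

## Known limitations

* The metabolic core is a reduced reconstruction: quantitative pool
  sizes (e.g. the very high bundle-sheath malate accumulations) are not
  individually validated, and the lumped regeneration stoichiometry
  (5 TP → 3 Ru5P via two steps) hides the individual sugar-phosphate
  intermediates.
* In the reduced model the 3–7 min window of a maize induction remains
  stomatally co-limited, so applying the semilog τ_Rubisco estimator to
  the model's own full-dynamics output reads a mixture of the stomatal
  and Rubisco timescales (~6.8 min) rather than the τ that generated it.
  The estimator is validated against its defining exponential model.
* Chlorophyll-fluorescence quantities (NPQ) are not modelled; the
  energy balance uses a single big-leaf formulation with no canopy
  radiative transfer.
* The Ball–Berry demand signal is a phenomenological reconstruction of
  anticipatory stomatal opening; mechanistic guard-cell models are out
  of scope.
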
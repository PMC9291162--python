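# c4dyn — dynamic simulation of NADP-ME C4 photosynthesis

The most productive C4 crops — maize, sorghum, sugarcane — use the
NADP-malic-enzyme pathway, concentrating CO2 into bundle-sheath cells
via a PEP-carboxylase/malate shuttle. In the field their leaves almost
never sit at steady state: light fluctuates on second timescales while
enzyme activation, stomatal opening and metabolite pools adjust over
minutes, costing a substantial fraction of potential carbon gain.
`c4dyn` is a dynamic model of this system for plant physiologists and
crop modellers who want to ask *what limits photosynthesis during
light transitions, and by how much*.

The package couples, as one stiff ODE system:

* a reduced-order two-cell metabolic network (PEPC, PPDK, NADP-MDH,
  NADP-ME, mutase+enolase, Rubisco, GAPDH, FBPase, SBPase, PRK, carbonic
  anhydrase, metabolite shuttles, plasmodesmatal CO2 leakage and
  light-driven ATP/NADPH supply),
* post-translational regulation — PPDK switching by its regulatory
  protein PDRP, Rubisco activation by Rubisco activase
  (d**V**max/dt = (V_s − V_i)/τ, with [Rca] = 216.9/τ_Rubisco), and
  clamped-linear light activation a_s = min(k_A·I + c_A, 1) for the
  remaining enzymes, with Arrhenius/Q10 temperature responses,
* Ball–Berry stomata, gs* = m·A·RH/Ca + b, approached first-order with
  separate opening/closing rate constants, and
* a leaf energy-balance ODE with forced/free-convection boundary layer.

Two headline diagnostics fall out of the flux solution: net CO2 uptake
A (the stomatal influx) and bundle-sheath leakiness
φ = P_CO2,pd([CO2]_BS − [CO2]_MC)/v_PEPC, the fraction of C4-cycle
carbon that diffuses back out of the bundle sheath.

The estimation module implements the gas-exchange workflow that
parameterises the model per species: von Caemmerer A–Ci fitting (Vpmax,
Vcmax), Ball–Berry regression from light-response curves, the semilog
induction plot for τ_Rubisco (τ = −1/slope over the 3–7 min window),
least-squares [PDRP] from early induction, and dark-efflux Rd. A
synthetic-data generator produces LI-6800-style tables from known
ground truth for end-to-end recovery tests.

## Worked example

Induction metrics for the maize and sorghum parameter sets — a 30-min
dark adaptation followed by a step to 1800 µmol m⁻² s⁻¹, full dynamic
model:

```console
$ c4dyn metrics --species maize
species,IT50_s,mean_A_reduction_pct,min_Ci,steady_A
maize,186.4,17.92,62.9,37.17

$ c4dyn metrics --species sorghum
species,IT50_s,mean_A_reduction_pct,min_Ci,steady_A
sorghum,246.4,20.82,51.8,36.38
```

Reading the maize row: the leaf needs 186 s to reach half of its steady
uptake (IT50); averaged over the 30-min induction it loses 17.9 % of
the carbon it would fix at steady state; intercellular CO2 dips to
63 µmol mol⁻¹ while assimilation outruns stomatal opening; the steady
rate is 37.2 µmol m⁻² s⁻¹. Sorghum inducts more slowly (its Rubisco
activation time constant is 2.5× longer), losing 20.8 %.

The same machinery is available as a library:

```python
import c4dyn
from c4dyn.analysis import run_scenario, induction_metrics, leakiness

res = run_scenario(6, c4dyn.get_species("maize"))   # full dynamics
print(induction_metrics(res).it50_s)                # 186.4
phi = leakiness(res)                                # phi(t) series
```

`run_scenario(1, ...)` reproduces the instant-activation limit (all
enzymes at their light-on activities, stomata open), scenarios 2–5 add
PPDK, Rubisco and generic enzyme activation dynamics incrementally, and
scenario 6 adds stomatal dynamics. `c4dyn.analysis` also provides ±1 %
central-difference sensitivity coefficients and per-enzyme flux control
coefficients through induction; `c4dyn generate` / `c4dyn fit` round-trip
synthetic gas-exchange tables through the estimators.

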
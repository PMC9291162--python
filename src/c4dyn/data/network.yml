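# Reduced-order NADP-ME C4 network: kinetic defaults, version 1.
#
# All Vmax / capacities are umol m-2 s-1 at 25 C for the reference
# parameter set (Vpmax 120, Vcmax 60, f_vmpepc 1, f_vmrubisco 0.85);
# C4-cycle capacities scale with Vmax_PEPC and C3-cycle capacities with
# Vmax_Rubisco when a species parameter set is applied.  Michaelis and
# inhibition constants are mM.  Transport and mass-action constants are
# umol m-2 s-1 per mM of concentration difference.

version: 1

compartments:
  # liquid volumes, L per m2 leaf
  mesophyll_cytosol: 0.050
  mesophyll_chloroplast: 0.020
  bundlesheath_cytosol: 0.020
  bundlesheath_chloroplast: 0.015
  # intercellular airspace, mol air per m2 leaf
  airspace_mol: 0.008

gas_exchange:
  co2_dissolution: 30000.0      # airspace <-> mesophyll liquid, umol m-2 s-1 mM-1
  p_co2_pd: 410.0               # plasmodesmatal CO2 permeability, umol m-2 s-1 mM-1
  bs_co2_buffer: 2500.0         # effective BS CO2 capacitance multiplier on the
                                # BS cytosol volume: lumped CO2/HCO3-/metabolite
                                # CO2-exchange pools; sets the leakiness
                                # transient timescale (calibration constant)
  o2_kc_multiplier: 1.4667      # (1 + O/Ko) at 21% O2 applied to Kc
  gamma_star_mm: 0.00135        # CO2 compensation-scale constant, mM

carbonic_anhydrase:
  rate_constant: 20000.0        # umol m-2 s-1 mM-1
  keq_hco3_co2: 5.0             # [HCO3-]/[CO2] at equilibrium (stromal pH)

enzymes:
  PEPC:
    vmax: 120.0                 # set directly from Vpmax / f_vmpepc
    km_hco3: 0.012
    km_pep: 0.08
    ki_feedback: 17.0           # malate+OAA feedback inhibition, mM
  MDH:
    vmax: 220.0
    km_oaa: 0.056
    km_nadph: 0.05
  ME:
    vmax: 150.0
    km_mal: 0.23
    km_nadp: 0.024
  PPDK:
    vmax: 50.0
    km_pyr: 0.25
    km_atp: 0.15
  mutase_enolase:
    rate_constant: 12.0         # reversible PGA <-> PEP, umol m-2 s-1 mM-1
    keq_pep_per_pga: 0.5
  Rubisco:
    vmax: 70.588                # Vcmax / f_vmrubisco for the reference set
    kc: 0.0217                  # mM CO2
    km_rubp: 0.02
  GAPDH_bs:
    vmax: 130.0
    km_pga: 0.6
    km_atp: 0.3
    km_nadph: 0.1
  GAPDH_mc:
    vmax: 90.0
    km_pga: 0.6
    km_atp: 0.3
    km_nadph: 0.1
  FBPase:
    vmax: 70.0
    km_tp: 0.6
  SBPase:
    vmax: 60.0                  # lumped SBPase/transketolase/aldolase step
    km_hp: 0.5
    km_tp: 0.3
    ki_ru5p: 2.0                # product feedback, caps the pentose-P pool
  PRK:
    vmax: 130.0
    km_ru5p: 0.05
    km_atp: 0.1
    ki_rubp: 2.0                # RuBP product inhibition

transports:
  malate: 12.0                  # MC cytosol -> BS cytosol
  pyruvate: 12.0                # BS cytosol -> M chloroplast
  pga: 20.0                     # BS chloroplast -> MC
  triose_p: 20.0                # MC -> BS chloroplast

light_reactions:
  # saturating light response s(I) = I / (I + k_sat); capacities are the
  # electron-transport-limited supply rates at s = 1 and 25 C
  k_sat: 280.0
  atp_capacity_mc: 260.0
  atp_capacity_bs: 160.0
  nadph_capacity_mc: 150.0
  km_adp: 0.15
  km_pi: 1.0
  km_nadp: 0.05

stomata:
  # CO2-saturation factor converting the transient Rubisco capacity into
  # the demand signal feeding the Ball-Berry index
  demand_saturation: 0.4

sinks:
  export_vmax: 9.0              # hexose-P -> carbohydrate sink, HP units
  export_km: 2.5               # sigmoidal half-point, mM
  remobilization_vmax: 3.0      # starch buffer feeding HP in darkness
  remobilization_km: 0.2
  atp_maintenance: 2.0          # umol m-2 s-1 per mM ATP
  rd_q10: 2.0

pools:
  ppdk_total: 0.3               # mM, mesophyll chloroplast
  adenylate_mc: 1.5             # ATP + ADP, mM
  adenylate_bs: 1.5
  nadp_total_mc: 0.5            # NADPH + NADP+
  nadp_total_bs: 0.5
  phosphate_mc: 12.0            # Pi + ATP (conserved pair)
  phosphate_bs: 12.0

pdrp:
  kcat_inact: 9.0
  kcat_act: 25.0
  km_ppdk_inact: 0.08
  km_adp_inact: 0.06
  ki_pyr_inact: 2.2
  km_ppdk_act: 0.08
  km_pi_act: 2.0
  ki_adp_act: 0.03

light_activation:
  # a_s = min(k_a * I + c_a, 1); tau in minutes
  PEPC:   {tau: 0.7, k_a: 2.0e-3, c_a: 0.0}
  ATPase: {tau: 1.0, k_a: 2.0e-3, c_a: 0.15}
  FBPase: {tau: 1.5, k_a: 2.0e-3, c_a: 0.15}
  GAPDH:  {tau: 1.5, k_a: 2.0e-3, c_a: 0.15}
  PRK:    {tau: 1.5, k_a: 2.0e-3, c_a: 0.15}
  SBPase: {tau: 1.5, k_a: 2.0e-3, c_a: 0.15}
  Rca:    {tau: 1.0, k_a: 5.5e-4, c_a: 0.25}

temperature:
  # peaked Arrhenius (Ea, Hd, deltaS in J mol-1, J mol-1, J mol-1 K-1)
  PEPC:    {form: peaked_arrhenius, ea: 64800.0, hd: 149250.0, delta_s: 486.0}
  CA:      {form: peaked_arrhenius, ea: 40000.0, hd: 149250.0, delta_s: 486.0}
  # Arrhenius
  PPDK:    {form: arrhenius, ea: 58000.0}
  Rubisco: {form: arrhenius, ea: 67000.0}
  Jmax:    {form: arrhenius, ea: 43000.0}
  Kc:      {form: arrhenius, ea: 80990.0}
  # everything else: Q10 = 2
  default: {form: q10, q10: 2.0}

initial_state:
  # dark-adaptation reference state, mM (Ci in umol mol-1)
  CO2_mc: 0.016
  HCO3_mc: 0.08
  PEP_mc: 0.1
  OAA_mc: 0.02
  MAL_mc: 0.5
  PYR_mchl: 0.3
  PGA_mc: 2.0
  TP_mc: 0.5
  ATP_mc: 0.3
  NADPH_mc: 0.15
  Pi_mc: 11.7
  CO2_bs: 0.016
  MAL_bs: 0.5
  PYR_bs: 0.3
  PGA_bs: 2.0
  TP_bs: 0.5
  HP_bs: 0.3
  RU5P_bs: 0.05
  RUBP_bs: 0.5
  ATP_bs: 0.3
  NADPH_bs: 0.25
  Pi_bs: 11.7
  Ci: 400.0
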
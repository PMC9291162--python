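# Species parameter sets: the 11 gas-exchange-derived inputs of the
# dynamic model.  'original' is the literature-parameterised reference set;
# the three crop sets were estimated from LI-6800 measurements.
#
# slope_bb / intercept_bb  Ball-Berry slope (-) and intercept (mol m-2 s-1)
# gs_ki / gs_kd            stomatal opening/closing rate constants (min-1)
# vpmax / vcmax            maximal PEPC / Rubisco activity (umol m-2 s-1)
# tau_rubisco              Rubisco activation time constant (min)
# f_vmpepc / f_vmrubisco   measured-to-model Vmax ratios (-)
# pdrp                     PPDK regulatory protein concentration (umol)
# rd                       mitochondrial respiration (umol m-2 s-1)

original:
  slope_bb: 4.53
  intercept_bb: 0.020
  gs_ki: 0.227
  gs_kd: 0.071
  vpmax: 120.0
  vcmax: 60.0
  tau_rubisco: 5.0
  f_vmpepc: 1.0
  f_vmrubisco: 0.85
  pdrp: 0.04
  rd: 1.0

maize:
  slope_bb: 5.183
  intercept_bb: 0.036
  gs_ki: 0.127
  gs_kd: 0.123
  vpmax: 124.128
  vcmax: 49.919
  tau_rubisco: 3.881
  f_vmpepc: 0.72
  f_vmrubisco: 0.67
  pdrp: 0.058
  rd: 2.282

sorghum:
  slope_bb: 4.843
  intercept_bb: 0.019
  gs_ki: 0.257
  gs_kd: 0.377
  vpmax: 133.626
  vcmax: 51.082
  tau_rubisco: 9.714
  f_vmpepc: 0.68
  f_vmrubisco: 0.56
  pdrp: 0.038
  rd: 0.979

sugarcane:
  slope_bb: 4.941
  intercept_bb: 0.027
  gs_ki: 0.204
  gs_kd: 0.221
  vpmax: 83.840
  vcmax: 52.783
  tau_rubisco: 4.776
  f_vmpepc: 0.92
  f_vmrubisco: 0.67
  pdrp: 0.037
  rd: 1.446
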
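"""Physical constants and unit conversions used throughout the model.

Conventions
-----------
* concentrations        mM (mmol L-1), per compartment
* area-based fluxes     umol m-2 s-1
* conductances          mol m-2 s-1 (gas phase, per leaf area)
* temperatures          degrees C externally, Kelvin internally
* light                 umol photons m-2 s-1 (PAR)

A compartment with liquid volume ``V`` (L m-2) converts an area flux ``v``
(umol m-2 s-1) to a concentration derivative ``v / (1000 * V)`` (mM s-1).
"""

#: Universal gas constant, J mol-1 K-1
R_GAS = 8.314

#: Reference temperature for all kinetic constants, degrees C / K
T_REF_C = 25.0
T_REF_K = 298.15

#: Stefan-Boltzmann constant, W m-2 K-4
SIGMA_SB = 5.670374419e-8

#: Mean energy of a PAR photon (~550 nm), J umol-1; converts quantum flux
#: to an energy flux before leaf absorptance is applied.
PAR_J_PER_UMOL = 0.2175

#: Henry-law solubility of CO2 in water at 25 C expressed as
#: mM of dissolved CO2 per (umol mol-1) of gas mole fraction at 1 atm.
#: 0.0334 mol L-1 atm-1 * 1e-6 atm/(umol mol-1) * 1e3 mM/M
CO2_SOLUBILITY_MM_PER_PPM = 3.34e-5

#: Ratio of diffusivities: stomatal conductance to water vs CO2
GS_H2O_PER_CO2 = 1.6
#: Boundary-layer conductance to water vs CO2
GB_H2O_PER_CO2 = 1.37

#: Zero Celsius in Kelvin
KELVIN = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN
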
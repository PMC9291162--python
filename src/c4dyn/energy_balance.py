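"""Leaf energy balance and boundary-layer conductance.

Leaf temperature is a dynamic state:

    dT_leaf/dt = (PAR_abs + NIR + LR - (H + LE + E_emit + M_e)) / (Cp * m_leaf)

with sensible heat H = 2 Cp_air g_bh (T_leaf - T_air) (both leaf faces,
g_bh = 0.924 g_b), latent heat LE = C_lv g_l (E_sat(T_leaf) - E_air)/Pa
(internal airspace assumed vapour-saturated at leaf temperature), emitted
long-wave E_emit = 2 eps sigma T_K^4, and the energy consumed by net
photosynthesis M_e = 0.506 A.  PAR is converted from quantum flux to W m-2
(0.2175 J per umol photons, ~550 nm mean) before the 0.85 absorptance.

Boundary-layer conductance takes the larger of the forced- and
free-convection estimates (Nikolov et al. 1995 forms): the forced term
grows with sqrt(wind speed), the free term with |T_leaf - T_air|^0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import PAR_J_PER_UMOL, SIGMA_SB, celsius_to_kelvin


@dataclass(frozen=True)
class EnergyBalanceParams:
    absorptance_par: float = 0.85
    nir: float = 0.0                 # absorbed near-infrared, W m-2
    #: Absorbed long-wave, W m-2.  None means "black enclosure at air
    #: temperature", i.e. 2 eps sigma T_air^4, so that with no short-wave
    #: input an isothermal leaf in saturated air is a fixed point; an
    #: explicit number (e.g. 0) overrides this.
    lr: float | None = None
    cp_leaf: float = 4.184           # J g-1 C-1 (water)
    m_leaf: float = 198.0            # specific leaf fresh weight, g m-2
    cp_air: float = 29.3             # J mol-1 C-1
    c_lv: float = 44000.0            # latent heat of vaporisation, J mol-1
    emissivity: float = 0.97
    me_per_a: float = 0.506          # W m-2 per umol CO2 m-2 s-1
    d_leaf: float = 0.08             # characteristic leaf dimension, m
    c_forced: float = 4.322e-3       # forced-convection constant
    c_free: float = 1.6361e-3        # free-convection constant
    gb_floor: float = 1e-4           # mol m-2 s-1, still-air guard


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapour pressure over water (Tetens form), kPa."""
    if not (-20.0 < t_c < 60.0):
        raise ValueError(f"temperature out of range for Tetens formula: {t_c}")
    return 0.61078 * math.exp(17.27 * t_c / (t_c + 237.3))


def boundary_layer_conductance(
    t_air_c: float,
    t_leaf_c: float,
    wind: float,
    d_leaf: float,
    pa_kpa: float,
    p: EnergyBalanceParams | None = None,
) -> float:
    """Leaf boundary-layer conductance to water vapour, mol m-2 s-1.

    Maximum of forced convection (wind-driven, ~u^0.5) and free convection
    (buoyancy-driven, ~|dT|^0.25), with a small floor guarding the
    still-air isothermal degenerate case.
    """
    if wind < 0:
        raise ValueError("wind speed must be >= 0")
    if d_leaf <= 0:
        raise ValueError("leaf dimension must be positive")
    p = p or EnergyBalanceParams()
    t_air_k = celsius_to_kelvin(t_air_c)
    t_leaf_k = celsius_to_kelvin(t_leaf_c)
    g_forced = p.c_forced * t_air_k**0.56 * math.sqrt(
        (t_air_k + 120.0) * wind / (d_leaf * pa_kpa)
    )
    g_free = (
        p.c_free
        * t_leaf_k**0.56
        * math.sqrt((t_leaf_k + 120.0) / pa_kpa)
        * abs(t_leaf_k - t_air_k) ** 0.25
    )
    return max(g_forced, g_free, p.gb_floor)


def leaf_temperature_rate(
    t_leaf_c: float,
    t_air_c: float,
    par: float,
    rh: float,
    wind: float,
    pa_kpa: float,
    gs: float,
    a_net: float,
    p: EnergyBalanceParams | None = None,
) -> float:
    """Rate of leaf temperature change, C s-1.

    Parameters are the current leaf/air temperatures (C), incident PAR
    (umol m-2 s-1), air relative humidity (fraction), wind speed (m s-1),
    atmospheric pressure (kPa), stomatal conductance to water
    (mol m-2 s-1) and net CO2 uptake (umol m-2 s-1).
    """
    if gs < 0:
        raise ValueError("gs must be >= 0")
    p = p or EnergyBalanceParams()
    g_b = boundary_layer_conductance(t_air_c, t_leaf_c, wind, p.d_leaf, pa_kpa, p)
    g_bh = 0.924 * g_b
    # series total conductance to water (stomata + boundary layer)
    g_l = 0.0 if gs == 0 else 1.0 / (1.0 / gs + 1.0 / g_b)

    par_abs = p.absorptance_par * par * PAR_J_PER_UMOL
    h = 2.0 * p.cp_air * g_bh * (t_leaf_c - t_air_c)
    e_air = rh * saturation_vapor_pressure(t_air_c)
    le = p.c_lv * g_l * (saturation_vapor_pressure(t_leaf_c) - e_air) / pa_kpa
    e_emit = 2.0 * p.emissivity * SIGMA_SB * celsius_to_kelvin(t_leaf_c) ** 4
    m_e = p.me_per_a * a_net
    lr = p.lr
    if lr is None:
        lr = 2.0 * p.emissivity * SIGMA_SB * celsius_to_kelvin(t_air_c) ** 4
    net = par_abs + p.nir + lr - (h + le + e_emit + m_e)
    return net / (p.cp_leaf * p.m_leaf)


def transpiration_rate(
    t_leaf_c: float, t_air_c: float, rh: float, pa_kpa: float, gs: float, g_b: float
) -> float:
    """Transpiration, mol H2O m-2 s-1, from the leaf-air vapour gradient."""
    if gs <= 0 or g_b <= 0:
        return 0.0
    g_l = 1.0 / (1.0 / gs + 1.0 / g_b)
    e_air = rh * saturation_vapor_pressure(t_air_c)
    return g_l * (saturation_vapor_pressure(t_leaf_c) - e_air) / pa_kpa
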
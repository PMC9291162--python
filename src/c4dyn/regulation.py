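"""Post-translational regulation of photosynthetic enzymes.

Three regulatory mechanisms set the transient maximal activity of each
light-modulated enzyme:

1. PPDK is switched between an active (E) and a phospho-inactive (EP) form
   by the bifunctional PPDK regulatory protein (PDRP).  The inactivation
   (kinase) rate uses ADP as phosphoryl donor and is competitively inhibited
   by pyruvate; the activation (phosphatase) rate uses Pi and is inhibited
   by ADP.  Darkness raises stromal ADP, which both fuels inactivation and
   suppresses re-activation, so PPDK deactivates in the dark and activates
   in the light on a minutes timescale set by [PDRP].

2. Rubisco activation is catalysed by Rubisco activase (Rca).  The total
   Rca pool is inferred from the measured Rubisco activation time constant
   (tau_Rubisco) via [Rca] = k / tau_Rubisco with k = 216.9 min mg m-2; the
   light-dependent active fraction then sets the steady-state target of the
   transient maximal Rubisco activity, which relaxes first-order with
   tau_Rubisco.

3. The remaining light-activated enzymes (ATPase, FBPase, GAPDH, PRK, Rca
   itself, SBPase and PEPC) follow a clamped-linear steady-state activation
   fraction a_s = min(k_A * I + c_A, 1) approached first-order with a
   per-enzyme time constant.

Temperature responses of enzyme capacities use one of three forms (peaked
Arrhenius, Arrhenius, Q10), all normalised to 1 at 25 C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R_GAS, T_REF_C, T_REF_K, celsius_to_kelvin

#: [Rca] = RCA_TAU_CONSTANT / tau_Rubisco, min mg m-2
RCA_TAU_CONSTANT = 216.9
#: Half-saturation of Rubisco activation on active Rca, mg m-2
K_ACTIVASE = 12.3


@dataclass(frozen=True)
class PDRPParams:
    """Kinetic constants of the PPDK regulatory protein.

    Concentrations in mM ([PDRP] in the mesophyll chloroplast stroma),
    kcat in s-1, Michaelis/inhibition constants in mM.
    """

    pdrp_mchl: float = 4.0e-5          # 0.04 uM expressed in mM
    kcat_inact: float = 9.0
    kcat_act: float = 25.0
    km_ppdk_inact: float = 0.08
    km_adp_inact: float = 0.06
    ki_pyr_inact: float = 2.2
    km_ppdk_act: float = 0.08
    km_pi_act: float = 2.0
    ki_adp_act: float = 0.03

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"PDRPParams.{name} must be positive, got {value}")


@dataclass
class PPDKState:
    """Active (e) and phospho-inactive (ep) PPDK, mM. e + ep is conserved."""

    e_mchl: float
    ep_mchl: float

    @property
    def total(self) -> float:
        return self.e_mchl + self.ep_mchl


def pdrp_rates(
    pdrp: PDRPParams,
    ppdk: PPDKState,
    adp_mchl: float,
    pyr_mchl: float,
    pi_mchl: float,
) -> tuple[float, float]:
    """Inactivation and activation rates of PPDK by PDRP, mM s-1.

    Returns ``(v_inact, v_act)``; the active-PPDK balance is
    ``dE/dt = v_act - v_inact``, which conserves total PPDK exactly.

    Raises
    ------
    ValueError
        If any substrate concentration is negative.
    """
    for name, c in (("ADP", adp_mchl), ("pyruvate", pyr_mchl), ("Pi", pi_mchl)):
        if c < 0:
            raise ValueError(f"negative {name} concentration: {c}")
    if ppdk.e_mchl < 0 or ppdk.ep_mchl < 0:
        raise ValueError("negative PPDK pool")

    v_inact = (
        pdrp.pdrp_mchl
        * pdrp.kcat_inact
        * ppdk.e_mchl
        / (ppdk.e_mchl + pdrp.km_ppdk_inact)
        * adp_mchl
        / (adp_mchl + pdrp.km_adp_inact * (1.0 + pyr_mchl / pdrp.ki_pyr_inact))
    )
    v_act = (
        pdrp.pdrp_mchl
        * pdrp.kcat_act
        * ppdk.ep_mchl
        / (ppdk.ep_mchl + pdrp.km_ppdk_act * (1.0 + adp_mchl / pdrp.ki_adp_act))
        * pi_mchl
        / (pi_mchl + pdrp.km_pi_act)
    )
    return v_inact, v_act


def rca_total_from_tau(tau_rubisco_min: float) -> float:
    """Total Rubisco-activase pool (mg m-2) from the activation time constant.

    [Rca] = 216.9 / tau_Rubisco, with tau in minutes.
    """
    if tau_rubisco_min <= 0:
        raise ValueError(f"tau_Rubisco must be positive, got {tau_rubisco_min}")
    return RCA_TAU_CONSTANT / tau_rubisco_min


@dataclass(frozen=True)
class RubiscoActivationParams:
    """Parameters of Rca-mediated Rubisco activation."""

    tau_rubisco_min: float
    vmax_rubisco_full: float           # umol m-2 s-1, fully activated capacity
    k_activase: float = K_ACTIVASE     # mg m-2
    rca_total: float | None = None     # mg m-2; derived from tau if omitted

    def __post_init__(self) -> None:
        if self.tau_rubisco_min <= 0:
            raise ValueError("tau_Rubisco must be positive")
        if self.rca_total is None:
            object.__setattr__(self, "rca_total", rca_total_from_tau(self.tau_rubisco_min))


def rubisco_target_vmax(p: RubiscoActivationParams, a_rca: float) -> float:
    """Steady-state target of transient Rubisco Vmax, umol m-2 s-1.

    ``a_rca`` is the light-dependent active fraction of the Rca pool;
    the target saturates hyperbolically on active Rca with K_activase.
    Monotone nondecreasing in both a_rca and the Rca pool.
    """
    if a_rca < 0:
        raise ValueError("a_rca must be >= 0")
    rca_active = p.rca_total * a_rca
    return p.vmax_rubisco_full * rca_active / (p.k_activase + rca_active)


def first_order_activation(current: float, target: float, tau_min: float) -> float:
    """First-order relaxation rate d(current)/dt toward target, per minute.

    Units of the returned rate are (units of current) min-1; under a
    constant target the solution is exponential with time constant tau.
    """
    if tau_min <= 0:
        raise ValueError(f"tau must be positive, got {tau_min}")
    return (target - current) / tau_min


def steady_activation_fraction(irradiance: float, k_a: float, c_a: float) -> float:
    """Clamped-linear steady-state activation fraction min(k_A*I + c_A, 1)."""
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    return min(k_a * irradiance + c_a, 1.0)


@dataclass(frozen=True)
class TempResponse:
    """Temperature scaling of a kinetic constant, normalised to 1 at 25 C.

    form='arrhenius'        exp(Ea (T-25) / (298.15 R T_K))
    form='peaked_arrhenius' Arrhenius rise multiplied by the Hd/deltaS
                            high-temperature inactivation ratio, normalised
                            so the factor is exactly 1 at 25 C
    form='q10'              Q10 ** ((T - 25)/10)
    """

    form: str = "q10"
    ea: float = 0.0          # J mol-1
    hd: float = 0.0          # J mol-1
    delta_s: float = 0.0     # J mol-1 K-1
    q10: float = 2.0

    def __post_init__(self) -> None:
        if self.form not in ("arrhenius", "peaked_arrhenius", "q10"):
            raise ValueError(f"unsupported temperature-response form: {self.form!r}")


def temperature_scale(tr: TempResponse, t_leaf_c: float) -> float:
    """Dimensionless multiplier on a 25 C kinetic constant at t_leaf_c."""
    if not (-10.0 <= t_leaf_c <= 60.0):
        raise ValueError(f"leaf temperature out of physical range: {t_leaf_c}")
    t_k = celsius_to_kelvin(t_leaf_c)
    if tr.form == "q10":
        return tr.q10 ** ((t_leaf_c - T_REF_C) / 10.0)
    arrh = math.exp(tr.ea * (t_leaf_c - T_REF_C) / (T_REF_K * R_GAS * t_k))
    if tr.form == "arrhenius":
        return arrh
    # peaked: high-temperature decline from the entropy/enthalpy ratio,
    # normalised to unity at the 25 C reference
    num = 1.0 + math.exp((T_REF_K * tr.delta_s - tr.hd) / (T_REF_K * R_GAS))
    den = 1.0 + math.exp((t_k * tr.delta_s - tr.hd) / (t_k * R_GAS))
    return arrh * num / den
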
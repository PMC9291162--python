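"""Dynamic simulation: couples the metabolic network to enzyme-activation
dynamics, Ball-Berry stomata and the leaf energy balance, and integrates
the full system with a stiff ODE solver.

The full state vector is the 23 metabolite concentrations followed by the
regulatory and physical states: active PPDK, transient Rubisco Vmax, the
activation fractions of the generically light-activated enzymes (PEPC,
ATPase, FBPase, GAPDH, PRK, SBPase, Rca), stomatal conductance and leaf
temperature.

Scenario flags reproduce the six regulation settings of the induction
analysis: a disabled mechanism is steered to its fully-light-activated
value with a very short time constant (seconds), i.e. it is effectively
held at its steady-state light-on value from t = 0, while enabled
mechanisms follow their own ODEs from dark-adapted initial values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .energy_balance import EnergyBalanceParams, leaf_temperature_rate
from .forcing import EnvConditions, EnvForcing, chamber
from .network import (
    ACTIVITY_ORDER,
    METABOLITE_NAMES,
    N_MET,
    N_RXN,
    REACTION_NAMES,
    C4Network,
    IntegrationError,
    _AI,
    _RI,
)
from .regulation import steady_activation_fraction
from .stomata import BallBerryParams, ball_berry_steady

# --- full state layout ------------------------------------------------------
REG_NAMES = (
    "E_PPDK", "VMAX_RUB", "a_PEPC", "a_ATPase", "a_FBPase", "a_GAPDH",
    "a_PRK", "a_SBPase", "a_Rca", "GS", "TLEAF",
)
STATE_NAMES = METABOLITE_NAMES + REG_NAMES
N_STATE = len(STATE_NAMES)
_SI = {n: i for i, n in enumerate(STATE_NAMES)}
_LIGHT_ENZYMES = ("PEPC", "ATPase", "FBPase", "GAPDH", "PRK", "SBPase", "Rca")

#: time constant (s) used to hold a disabled mechanism at its target
TAU_FAST_S = 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Which regulatory mechanisms run dynamically (the six scenarios)."""

    id: int
    dynamic_ppdk: bool
    dynamic_rubisco: bool
    dynamic_other_enzymes: bool
    dynamic_stomata: bool

    @staticmethod
    def from_id(scenario_id: int) -> "ScenarioSpec":
        table = {
            1: (False, False, False, False),
            2: (True, False, False, False),
            3: (False, True, False, False),
            4: (True, True, False, False),
            5: (True, True, True, False),
            6: (True, True, True, True),
        }
        if scenario_id not in table:
            raise ValueError(f"unknown scenario id {scenario_id}; valid: 1-6")
        return ScenarioSpec(scenario_id, *table[scenario_id])


FULL_DYNAMICS = ScenarioSpec.from_id(6)


@dataclass
class SimulationResult:
    """Dense time series of gas exchange, activation and metabolite states."""

    time: np.ndarray                 # s
    states: np.ndarray               # (n_t, N_STATE)
    fluxes: np.ndarray               # (n_t, N_RXN)
    a_net: np.ndarray                # umol m-2 s-1
    network: C4Network
    scenario: ScenarioSpec
    forcing: EnvForcing
    phi_pepc_floor: float = 0.1      # umol m-2 s-1

    def __getitem__(self, name: str) -> np.ndarray:
        if name in _SI:
            return self.states[:, _SI[name]]
        if name in _RI:
            return self.fluxes[:, _RI[name]]
        raise KeyError(name)

    @property
    def gs(self) -> np.ndarray:
        return self["GS"]

    @property
    def ci(self) -> np.ndarray:
        return self["Ci"]

    @property
    def t_leaf(self) -> np.ndarray:
        return self["TLEAF"]

    @property
    def phi(self) -> np.ndarray:
        """Bundle-sheath leakiness v_leak / v_PEPC.

        Reported as 0 where the PEPC velocity is below a small floor
        (e.g. darkness), where the ratio is not meaningful.
        """
        v_pepc = self["v_PEPC"]
        v_leak = self["v_CO2_leak"]
        out = np.zeros_like(v_pepc)
        ok = v_pepc >= self.phi_pepc_floor
        out[ok] = v_leak[ok] / v_pepc[ok]
        return out

    @property
    def activation_fractions(self) -> dict[str, np.ndarray]:
        out = {f"a_{n}" if not n.startswith("a_") else n: self[n]
               for n in ("a_PEPC", "a_ATPase", "a_FBPase", "a_GAPDH",
                         "a_PRK", "a_SBPase", "a_Rca")}
        out["a_PPDK"] = self["E_PPDK"] / self.network.ppdk_total
        out["a_Rubisco"] = self["VMAX_RUB"] / self.network.vmax_rubisco
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_s": self.time,
            "A": self.a_net,
            "gs": self.gs,
            "Ci": self.ci,
            "Tleaf": self.t_leaf,
            "phi": self.phi,
        }
        cols.update(self.activation_fractions)
        for i, name in enumerate(METABOLITE_NAMES):
            cols[name] = self.states[:, i]
        return pd.DataFrame(cols)

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def steady_a(self, window_s: float = 300.0) -> float:
        """Mean A over the final window (default 5 min), the operational
        definition of the steady-state rate."""
        mask = self.time >= self.time[-1] - window_s
        return float(np.mean(self.a_net[mask]))


# --------------------------------------------------------------------- model


def build_initial_state(net: C4Network, t_air: float = 28.0) -> np.ndarray:
    """Reference state used to seed dark adaptation."""
    init = net.cfg["initial_state"]
    x = np.zeros(N_STATE)
    for name in METABOLITE_NAMES:
        x[_SI[name]] = init[name]
    x[_SI["E_PPDK"]] = 0.05 * net.ppdk_total
    x[_SI["VMAX_RUB"]] = 0.1 * net.vmax_rubisco
    for enz in _LIGHT_ENZYMES:
        x[_SI[f"a_{enz}"]] = net.light_act[enz]["c_a"]
    x[_SI["GS"]] = net.species.intercept_bb
    x[_SI["TLEAF"]] = t_air
    return x


def _rhs(t, x, net: C4Network, cond: EnvConditions, spec: ScenarioSpec,
         clamp_ci, closed, eb: EnergyBalanceParams):
    sp = net.species
    conc = x[:N_MET]
    e_ppdk = x[_SI["E_PPDK"]]
    vmax_rub = x[_SI["VMAX_RUB"]]
    gs = x[_SI["GS"]]
    t_leaf = x[_SI["TLEAF"]]

    act = np.ones(len(ACTIVITY_ORDER))
    act[_AI["PEPC"]] = x[_SI["a_PEPC"]]
    act[_AI["PPDK"]] = max(e_ppdk, 0.0) / net.ppdk_total
    act[_AI["Rubisco"]] = max(vmax_rub, 0.0) / net.vmax_rubisco
    act[_AI["GAPDH"]] = x[_SI["a_GAPDH"]]
    act[_AI["FBPase"]] = x[_SI["a_FBPase"]]
    act[_AI["SBPase"]] = x[_SI["a_SBPase"]]
    act[_AI["PRK"]] = x[_SI["a_PRK"]]
    act[_AI["ATPase"]] = x[_SI["a_ATPase"]]

    g_b = net.boundary_layer(cond, t_leaf, eb)
    fluxes = net.reaction_rates(conc, act, t_leaf, cond, gs, g_b,
                                clamp_ci=clamp_ci, closed=closed)
    if not np.all(np.isfinite(fluxes)):
        bad = REACTION_NAMES[int(np.flatnonzero(~np.isfinite(fluxes))[0])]
        raise IntegrationError(f"non-finite flux in reaction {bad}", t_last=t, state=x)

    dx = np.zeros(N_STATE)
    dx[:N_MET] = net.metabolite_derivatives(fluxes)
    if clamp_ci is not None or closed:
        dx[_SI["Ci"]] = 0.0

    if closed:
        a_net = 0.0
    elif clamp_ci is not None:
        a_net = fluxes[_RI["v_dissolution"]]
    else:
        a_net = fluxes[_RI["v_stomatal_CO2_influx"]]

    # --- PPDK regulation (PDRP)
    if spec.dynamic_ppdk:
        from .regulation import PPDKState, pdrp_rates

        ppdk_state = PPDKState(max(e_ppdk, 0.0),
                               max(net.ppdk_total - e_ppdk, 0.0))
        v_i, v_a = pdrp_rates(
            net.pdrp, ppdk_state,
            adp_mchl=max(net.pools["adenylate_mc"] - conc[_SI["ATP_mc"]], 0.0),
            pyr_mchl=max(conc[_SI["PYR_mchl"]], 0.0),
            pi_mchl=max(conc[_SI["Pi_mc"]], 0.0),
        )
        dx[_SI["E_PPDK"]] = v_a - v_i
    else:
        dx[_SI["E_PPDK"]] = (net.ppdk_total - e_ppdk) / TAU_FAST_S

    # --- Rubisco activation (Rca)
    if spec.dynamic_rubisco:
        a_rca = x[_SI["a_Rca"]]
        rca_active = net.rubisco_act.rca_total * max(a_rca, 0.0)
        target = net.vmax_rubisco * rca_active / (
            net.rubisco_act.k_activase + rca_active
        )
        dx[_SI["VMAX_RUB"]] = (target - vmax_rub) / (sp.tau_rubisco * 60.0)
        la = net.light_act["Rca"]
        a_rca_target = steady_activation_fraction(cond.par, la["k_a"], la["c_a"])
        dx[_SI["a_Rca"]] = (a_rca_target - a_rca) / (la["tau"] * 60.0)
    else:
        dx[_SI["VMAX_RUB"]] = (net.vmax_rubisco - vmax_rub) / TAU_FAST_S
        dx[_SI["a_Rca"]] = (1.0 - x[_SI["a_Rca"]]) / TAU_FAST_S

    # --- generic light activation
    for enz in ("PEPC", "ATPase", "FBPase", "GAPDH", "PRK", "SBPase"):
        idx = _SI[f"a_{enz}"]
        la = net.light_act[enz]
        target = steady_activation_fraction(cond.par, la["k_a"], la["c_a"])
        if spec.dynamic_other_enzymes:
            dx[idx] = (target - x[idx]) / (la["tau"] * 60.0)
        else:
            dx[idx] = (target - x[idx]) / TAU_FAST_S

    # --- stomata
    # The Ball-Berry index is driven by the mesophyll demand signal: the
    # Rubisco-side potential assimilation at the current activation state
    # (light-gated, at a reference bundle-sheath CO2 saturation), not by
    # the instantaneous supply-limited A.  This reproduces the sigmoidal
    # opening observed during induction: a lag while the enzymes activate,
    # then rapid opening toward the steady Ball-Berry value.
    bb = BallBerryParams(sp.slope_bb, sp.intercept_bb)
    s_light = cond.par / (cond.par + net.k_sat)
    ft_rub = net.temperature_factors(t_leaf)["Rubisco"]
    rd_t = sp.rd * net.rd_q10 ** ((t_leaf - 25.0) / 10.0)
    a_demand = (
        s_light * max(vmax_rub, 0.0) * ft_rub * net.gs_demand_saturation - rd_t
    )
    # the larger of realised and potential assimilation drives the index,
    # so the steady state satisfies the plain Ball-Berry relation gs(A)
    gs_target = ball_berry_steady(max(a_net, a_demand), cond.rh, cond.ca, bb)
    if spec.dynamic_stomata:
        k = sp.gs_ki if gs_target > gs else sp.gs_kd
        dx[_SI["GS"]] = k * (gs_target - gs) / 60.0
    else:
        dx[_SI["GS"]] = (gs_target - gs) / TAU_FAST_S

    # --- leaf energy balance
    dx[_SI["TLEAF"]] = leaf_temperature_rate(
        t_leaf, cond.t_air, cond.par, cond.rh, cond.wind, cond.pa,
        max(gs, 0.0), a_net, eb,
    )
    return dx


def integrate(
    net: C4Network,
    initial: np.ndarray,
    forcing: EnvForcing,
    duration: float,
    scenario: ScenarioSpec = FULL_DYNAMICS,
    dt_out: float = 2.0,
    clamp_ci: float | None = None,
    closed: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    eb: EnergyBalanceParams | None = None,
) -> SimulationResult:
    """Integrate the full dynamic model over [0, duration] seconds.

    The stiff LSODA solver is used; the time grid includes every forcing
    breakpoint.  Raises IntegrationError (with the last accepted state) on
    solver failure or a negative-concentration excursion beyond tolerance.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    eb = eb or EnergyBalanceParams()
    x = np.asarray(initial, dtype=float).copy()
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    for t0, t1, cond in forcing.segments(duration):
        grid = np.arange(t0, t1, dt_out)
        if grid.size == 0 or grid[-1] < t1:
            grid = np.append(grid, t1)
        sol = solve_ivp(
            _rhs, (t0, t1), x, method="LSODA", t_eval=grid,
            rtol=rtol, atol=atol,
            args=(net, cond, scenario, clamp_ci, closed, eb),
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed at t={sol.t[-1] if sol.t.size else t0:.1f}s: "
                f"{sol.message}",
                t_last=float(sol.t[-1]) if sol.t.size else t0,
                state=sol.y[:, -1] if sol.t.size else x,
            )
        times.append(sol.t)
        states.append(sol.y.T)
        x = sol.y[:, -1].copy()

    t_all = np.concatenate(times)
    x_all = np.vstack(states)
    # drop duplicated segment endpoints
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, x_all = t_all[keep], x_all[keep]

    min_conc = float(x_all[:, :N_MET].min())
    if min_conc < -1e-6:
        raise IntegrationError(
            f"negative concentration excursion {min_conc:.3g} beyond solver "
            "tolerance; tighten rtol/atol"
        )

    # recompute fluxes and A on the output grid
    fluxes = np.empty((t_all.size, N_RXN))
    a_net = np.empty(t_all.size)
    for i, (t, xi) in enumerate(zip(t_all, x_all)):
        cond = forcing.at(min(t, duration - 1e-9))
        act = np.ones(len(ACTIVITY_ORDER))
        act[_AI["PEPC"]] = xi[_SI["a_PEPC"]]
        act[_AI["PPDK"]] = max(xi[_SI["E_PPDK"]], 0.0) / net.ppdk_total
        act[_AI["Rubisco"]] = max(xi[_SI["VMAX_RUB"]], 0.0) / net.vmax_rubisco
        act[_AI["GAPDH"]] = xi[_SI["a_GAPDH"]]
        act[_AI["FBPase"]] = xi[_SI["a_FBPase"]]
        act[_AI["SBPase"]] = xi[_SI["a_SBPase"]]
        act[_AI["PRK"]] = xi[_SI["a_PRK"]]
        act[_AI["ATPase"]] = xi[_SI["a_ATPase"]]
        g_b = net.boundary_layer(cond, xi[_SI["TLEAF"]], eb)
        fluxes[i] = net.reaction_rates(
            xi[:N_MET], act, xi[_SI["TLEAF"]], cond, xi[_SI["GS"]], g_b,
            clamp_ci=clamp_ci, closed=closed,
        )
        if closed:
            a_net[i] = 0.0
        elif clamp_ci is not None:
            a_net[i] = fluxes[i, _RI["v_dissolution"]]
        else:
            a_net[i] = fluxes[i, _RI["v_stomatal_CO2_influx"]]

    return SimulationResult(
        time=t_all, states=x_all, fluxes=fluxes, a_net=a_net,
        network=net, scenario=scenario, forcing=forcing,
    )


def dark_adapt(
    net: C4Network,
    duration: float = 1800.0,
    t_air: float = 28.0,
    ca: float = 400.0,
    dt_out: float = 10.0,
) -> np.ndarray:
    """30-min dark pre-simulation from the stored reference state.

    Returns the dark-adapted full state vector used as the initial
    condition of every induction simulation.
    """
    x0 = build_initial_state(net, t_air=t_air)
    forcing = EnvForcing.constant(chamber(0.0, ca=ca, t_air=t_air))
    res = integrate(net, x0, forcing, duration, scenario=FULL_DYNAMICS,
                    dt_out=dt_out)
    return res.final_state()


_DARK_CACHE: dict = {}


def dark_adapted_state(net: C4Network, t_air: float = 28.0,
                       ca: float = 400.0) -> np.ndarray:
    """Cached dark-adapted state per (species, conditions)."""
    key = (net.species, t_air, ca)
    cached = _DARK_CACHE.get(key)
    if cached is None:
        cached = dark_adapt(net, t_air=t_air, ca=ca)
        _DARK_CACHE[key] = cached
    return cached.copy()


def simulate_induction(
    net: C4Network,
    scenario_id: int = 6,
    par_high: float = 1800.0,
    duration: float = 1800.0,
    ca: float = 400.0,
    t_air: float = 28.0,
    dt_out: float = 2.0,
    dark_pre: bool = True,
) -> SimulationResult:
    """Dark-to-high-light induction under one of the six scenarios."""
    spec = ScenarioSpec.from_id(scenario_id)
    x0 = (dark_adapted_state(net, t_air=t_air, ca=ca) if dark_pre
          else build_initial_state(net, t_air=t_air))
    forcing = EnvForcing.constant(chamber(par_high, ca=ca, t_air=t_air))
    return integrate(net, x0, forcing, duration, scenario=spec, dt_out=dt_out)
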
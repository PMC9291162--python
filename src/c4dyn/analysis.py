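"""Scenario runs, sensitivity and flux-control analysis, leakiness and
induction summary metrics.

The six regulation scenarios switch the dynamic mechanisms on
incrementally (1: none — the steady-state metabolic model; 2: PPDK via
PDRP; 3: Rubisco via Rca; 4: both; 5: all light-regulated enzymes;
6: all plus stomatal dynamics).  Sensitivity coefficients follow the
central-difference definition SC_p(t) = (A+ - A-) / (0.02 A(t)) for a
+-1% perturbation of a parameter; flux control coefficients apply the
same formula to an enzyme's maximal activity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .forcing import EnvForcing, chamber
from .network import C4Network
from .params import SpeciesParams
from .simulate import (
    ScenarioSpec,
    SimulationResult,
    dark_adapt,
    dark_adapted_state,
    integrate,
)

__all__ = [
    "ScenarioSpec", "InductionMetrics", "run_scenario", "leakiness",
    "induction_metrics", "sensitivity_coefficient", "flux_control_coefficient",
    "scaled_network", "SENSITIVITY_PARAMS",
]

#: species parameters commonly perturbed in the sensitivity analysis
SENSITIVITY_PARAMS = (
    "pdrp", "tau_rubisco", "gs_ki", "gs_kd", "vpmax", "vcmax", "rd",
    "slope_bb", "intercept_bb",
)


@dataclass
class InductionMetrics:
    """Summary metrics of a dark-to-light induction simulation."""

    it50_s: float                  # time to 50% of steady-state A
    mean_a_reduction_pct: float    # induction loss vs steady state, %
    min_ci: float                  # umol mol-1, after light-on
    steady_a: float                # umol m-2 s-1
    iwue: np.ndarray               # A/gs series, umol mol-1


def run_scenario(
    scenario: int | ScenarioSpec,
    species: SpeciesParams,
    forcing: EnvForcing | None = None,
    duration: float = 1800.0,
    dark_pre: bool = True,
    dt_out: float = 2.0,
    cfg: dict | None = None,
) -> SimulationResult:
    """Run one of the six regulation scenarios for a species.

    Default forcing is the dark-to-1800 umol m-2 s-1 step; disabled
    mechanisms are held at their light-on steady values from t=0 while
    enabled ones start from the dark-adapted state.
    """
    spec = scenario if isinstance(scenario, ScenarioSpec) else ScenarioSpec.from_id(scenario)
    net = C4Network(species, cfg)
    if forcing is None:
        forcing = EnvForcing.constant(chamber(1800.0))
    x0 = dark_adapted_state(net) if dark_pre else None
    if x0 is None:
        from .simulate import build_initial_state

        x0 = build_initial_state(net)
    return integrate(net, x0, forcing, duration, scenario=spec, dt_out=dt_out)


def leakiness(result: SimulationResult) -> np.ndarray:
    """Bundle-sheath leakiness time course phi(t) = v_leak / v_PEPC.

    Reported as 0 where the PEPC velocity is below the documented floor
    (0.1 umol m-2 s-1, e.g. darkness).
    """
    return result.phi


def induction_metrics(result: SimulationResult) -> InductionMetrics:
    """IT50, induction loss, minimum Ci and iWUE from an induction run.

    The steady state is the mean A over the final 5 min; IT50 is the first
    crossing of half that value with linear interpolation between samples.
    """
    t, a, ci, gs = result.time, result.a_net, result.ci, result.gs
    a_ss = result.steady_a()
    half = 0.5 * a_ss
    above = a >= half
    if not above.any():
        raise ValueError("A never reaches 50% of the steady-state rate")
    i = int(np.argmax(above))
    if i == 0:
        it50 = 0.0
    else:
        it50 = float(t[i - 1] + (half - a[i - 1]) * (t[i] - t[i - 1]) / (a[i] - a[i - 1]))
    mean_a = float(np.trapezoid(a, t) / (t[-1] - t[0]))
    reduction = 100.0 * (1.0 - mean_a / a_ss)
    min_ci = float(ci[t > 0].min())
    iwue = np.divide(a, gs, out=np.zeros_like(a), where=gs > 1e-6)
    return InductionMetrics(
        it50_s=it50, mean_a_reduction_pct=reduction, min_ci=min_ci,
        steady_a=a_ss, iwue=iwue,
    )


def _induction_a(species: SpeciesParams, duration: float, dt_out: float,
                 scenario: int, cfg: dict | None = None,
                 net: C4Network | None = None) -> tuple[np.ndarray, np.ndarray]:
    net = net or C4Network(species, cfg)
    x0 = dark_adapt(net)
    res = integrate(
        net, x0, EnvForcing.constant(chamber(1800.0)), duration,
        scenario=ScenarioSpec.from_id(scenario), dt_out=dt_out,
    )
    return res.time, res.a_net


def sensitivity_coefficient(
    param: str,
    species: SpeciesParams,
    t_grid: np.ndarray | None = None,
    duration: float = 1800.0,
    dt_out: float = 10.0,
    rel: float = 0.01,
    scenario: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Time course of the relative sensitivity of A to a species parameter.

    Runs two full simulations with the parameter moved +-1% and returns
    (t, SC(t)) with SC = (A+ - A-) / (2 * rel * A).  A parameter that does
    not enter the active configuration yields 0 everywhere.
    """
    if param not in SpeciesParams.__dataclass_fields__ or param == "name":
        raise ValueError(f"unknown species parameter {param!r}")
    base = getattr(species, param)
    t, a0 = _induction_a(species, duration, dt_out, scenario)
    _, ap = _induction_a(replace(species, **{param: base * (1 + rel)}),
                         duration, dt_out, scenario)
    _, am = _induction_a(replace(species, **{param: base * (1 - rel)}),
                         duration, dt_out, scenario)
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = (ap - am) / (2.0 * rel * a0)
    sc[~np.isfinite(sc)] = 0.0
    if t_grid is not None:
        sc = np.interp(t_grid, t, sc)
        t = np.asarray(t_grid, float)
    return t, sc


def scaled_network(
    species: SpeciesParams, enzyme: str, factor: float, cfg: dict | None = None
) -> C4Network:
    """A network with one enzyme's maximal activity scaled by ``factor``.

    PEPC and Rubisco are scaled through the species-level capacities so the
    C4/C3 group scalings stay consistent; other enzymes are scaled in the
    kinetic defaults (the lumped mutase+enolase step scales its rate
    constant).
    """
    from .params import load_network

    if enzyme == "PEPC":
        sp = replace(species, vpmax=species.vpmax * factor)
        return C4Network(sp, cfg)
    if enzyme == "Rubisco":
        sp = replace(species, vcmax=species.vcmax * factor)
        return C4Network(sp, cfg)
    cfg2 = copy.deepcopy(cfg or load_network())
    if enzyme == "mutase_enolase":
        cfg2["enzymes"]["mutase_enolase"]["rate_constant"] *= factor
    elif enzyme == "GAPDH":
        cfg2["enzymes"]["GAPDH_bs"]["vmax"] *= factor
        cfg2["enzymes"]["GAPDH_mc"]["vmax"] *= factor
    elif enzyme in cfg2["enzymes"]:
        cfg2["enzymes"][enzyme]["vmax"] *= factor
    else:
        raise ValueError(f"enzyme {enzyme!r} not present in the network")
    return C4Network(species, cfg2)


def flux_control_coefficient(
    enzyme: str,
    species: SpeciesParams,
    t_grid: np.ndarray | None = None,
    duration: float = 1800.0,
    dt_out: float = 10.0,
    rel: float = 0.01,
    scenario: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Time course of the flux control coefficient of one enzyme's Vmax.

    Same central-difference formula as the parameter sensitivity, applied
    to the enzyme's maximal activity.
    """
    t, a0 = _induction_a(species, duration, dt_out, scenario)
    _, ap = _induction_a(species, duration, dt_out, scenario,
                         net=scaled_network(species, enzyme, 1 + rel))
    _, am = _induction_a(species, duration, dt_out, scenario,
                         net=scaled_network(species, enzyme, 1 - rel))
    with np.errstate(divide="ignore", invalid="ignore"):
        fcc = (ap - am) / (2.0 * rel * a0)
    fcc[~np.isfinite(fcc)] = 0.0
    if t_grid is not None:
        fcc = np.interp(t_grid, t, fcc)
        t = np.asarray(t_grid, float)
    return t, fcc
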
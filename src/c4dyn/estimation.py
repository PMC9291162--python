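"""Estimation of the species parameter set from gas-exchange data.

Implements the measurement-analysis workflow that produces the 11 species
inputs of the dynamic model:

* ``fit_aci`` — Vpmax and Vcmax from an A-Ci curve using the enzyme-limited
  C4 model of von Caemmerer (PEP-carboxylation-limited initial slope,
  Rubisco-limited plateau).
* ``estimate_f_scalars`` — the measured-to-model capacity ratios f_VmPEPC
  and f_VmRubisco, by least-squares matching of the dynamic model's
  steady-state A to the measured curve on the initial-slope region
  (Ca 120...10) and the CO2-saturated region (Ca 800...1500).
* ``fit_ball_berry`` — slope and intercept by ordinary least squares of
  gs on A*RH/Ca over an A-Q (light-response) curve.
* ``estimate_tau_rubisco`` — the Rubisco activation time constant from the
  semilogarithmic induction plot: regress ln(A_f - A(t)) on t over the
  3-7 min window; tau = -1/slope.
* ``estimate_pdrp`` — [PDRP] by one-dimensional least squares of simulated
  against measured A over the 1-3 min induction window.
* ``estimate_rd`` — mitochondrial respiration from the dark CO2 efflux.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import lmfit
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .params import SpeciesParams
from .stomata import BallBerryParams

__all__ = [
    "VonCaemmererConstants", "aci_forward", "fit_aci", "fit_ball_berry",
    "estimate_tau_rubisco", "estimate_rd", "estimate_f_scalars",
    "estimate_pdrp", "steady_state_a",
]


# ------------------------------------------------------------- A-Ci fitting


@dataclass(frozen=True)
class VonCaemmererConstants:
    """Enzyme-limited C4 model constants at 25 C (von Caemmerer defaults).

    Pressure-based units: Kc, Kp in ubar; Ko, O in mbar; gbs in
    mol m-2 s-1 bar-1; gamma_star dimensionless (per mbar O2 basis).
    """

    kc: float = 650.0
    ko: float = 450.0
    kp: float = 80.0
    gbs: float = 3.0e-3
    o_mesophyll: float = 210.0
    gamma_star: float = 1.93e-4
    vpr: float = 80.0          # PEP-regeneration cap, umol m-2 s-1

    @property
    def kc_eff(self) -> float:
        """Kc (1 + O/Ko), ubar."""
        return self.kc * (1.0 + self.o_mesophyll / self.ko)


def aci_forward(
    ci: np.ndarray,
    vpmax: float,
    vcmax: float,
    rd: float = 1.0,
    k: VonCaemmererConstants | None = None,
) -> np.ndarray:
    """Enzyme-limited net CO2 uptake A(Ci), umol m-2 s-1.

    The quadratic solution coupling the PEP-carboxylation CO2 supply
    (Vp + gbs Cm - Rm) to the Rubisco demand in the bundle sheath; Ci in
    umol mol-1 (~ubar), Rm = Rd/2.
    """
    k = k or VonCaemmererConstants()
    cm = np.asarray(ci, dtype=float)
    vp = np.minimum(cm * vpmax / (cm + k.kp), k.vpr)
    rm = 0.5 * rd
    supply = vp + k.gbs * cm - rm
    b = -(supply + (vcmax - rd) + k.gbs * k.kc_eff)
    c = (vcmax - rd) * supply - (
        vcmax * k.gamma_star * k.o_mesophyll + rd * k.kc_eff
    ) * k.gbs
    return (-b - np.sqrt(b**2 - 4.0 * c)) / 2.0


def fit_aci(
    ci: np.ndarray,
    a: np.ndarray,
    rd: float = 1.0,
    k: VonCaemmererConstants | None = None,
) -> lmfit.model.ModelResult:
    """Estimate (Vpmax, Vcmax) from an A-Ci curve.

    The curve must cover the initial slope (low Ci) and the CO2-saturated
    plateau; standard errors are reported by the fit.

    Raises
    ------
    ValueError
        If the curve lacks a low-Ci or saturated region, or if A decreases
        with Ci overall (degenerate input).
    """
    ci = np.asarray(ci, dtype=float)
    a = np.asarray(a, dtype=float)
    if ci.size < 6:
        raise ValueError("A-Ci curve needs at least 6 points")
    if ci.min() > 80.0:
        raise ValueError("A-Ci curve missing the initial-slope region (low Ci)")
    if ci.max() < 300.0:
        raise ValueError("A-Ci curve missing the CO2-saturated plateau region")
    slope_all = linregress(ci, a).slope
    if slope_all <= 0:
        raise ValueError("A decreases with Ci: not a valid A-Ci response")

    k = k or VonCaemmererConstants()
    model = lmfit.Model(
        lambda ci, vpmax, vcmax: aci_forward(ci, vpmax, vcmax, rd=rd, k=k),
        independent_vars=["ci"],
    )
    params = model.make_params(
        vpmax=dict(value=100.0, min=5.0, max=400.0),
        vcmax=dict(value=max(a.max() + rd, 10.0), min=5.0, max=300.0),
    )
    result = model.fit(a, params, ci=ci)
    if not result.success:
        raise ValueError(f"A-Ci fit failed: {result.message}")
    return result


# ------------------------------------------------ Ball-Berry regression


def fit_ball_berry(
    a: np.ndarray, gs: np.ndarray, rh: np.ndarray, ca: np.ndarray
) -> tuple[BallBerryParams, dict]:
    """Slope and intercept of gs against the Ball-Berry index A*RH/Ca.

    Plain (unweighted) ordinary least squares; returns the parameters and
    a dict with standard errors and R^2.
    """
    a, gs = np.asarray(a, float), np.asarray(gs, float)
    rh, ca = np.asarray(rh, float), np.asarray(ca, float)
    if a.size < 2:
        raise ValueError("Ball-Berry regression needs at least 2 points")
    index = a * rh / ca
    res = linregress(index, gs)
    params = BallBerryParams(slope=float(res.slope), intercept=float(res.intercept))
    stats = {
        "slope_se": float(res.stderr),
        "intercept_se": float(res.intercept_stderr),
        "r2": float(res.rvalue**2),
    }
    return params, stats


# -------------------------------------------- induction-series estimators


def estimate_tau_rubisco(
    time_s: np.ndarray,
    a: np.ndarray,
    window: tuple[float, float] = (180.0, 420.0),
    final_window_s: float = 300.0,
) -> tuple[float, dict]:
    """Rubisco activation time constant (minutes) from a dark-to-light
    induction series.

    The steady-state rate A_f is the mean over the final 5 minutes; the
    semilog deficit ln(A_f - A(t)) is regressed on t over the 3-7 min
    window and tau = -1/slope.  Points where the deficit is non-positive
    are dropped; more than half dropped is an error.  The estimate is
    invariant to adding a constant to A.
    """
    t = np.asarray(time_s, float)
    a = np.asarray(a, float)
    a_f = float(np.mean(a[t >= t[-1] - final_window_s]))
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 4:
        raise ValueError("induction series has too few points in the fit window")
    deficit = a_f - a[m]
    keep = deficit > 0
    if keep.sum() < 0.5 * m.sum():
        raise ValueError(
            "more than half of the 3-7 min window is at or above the "
            "steady-state rate; tau_Rubisco is unidentifiable"
        )
    res = linregress(t[m][keep], np.log(deficit[keep]))
    if res.slope >= 0:
        raise ValueError("semilog induction slope is non-negative")
    tau_min = -1.0 / res.slope / 60.0
    return tau_min, {"r2": float(res.rvalue**2), "slope_per_s": float(res.slope),
                     "a_final": a_f, "n_used": int(keep.sum())}


def estimate_rd(a_dark: np.ndarray) -> tuple[float, bool]:
    """Mitochondrial respiration from the dark CO2 efflux.

    Rd = -mean(A) over the dark tail; returns (rd, suspect) where
    ``suspect`` flags physically questionable positive A in darkness.
    """
    a_dark = np.asarray(a_dark, float)
    if a_dark.size == 0:
        raise ValueError("empty dark record")
    rd = -float(np.mean(a_dark))
    return rd, bool(rd <= 0)


# ------------------------------------- model-coupled estimators (f, PDRP)


def steady_state_a(
    net,
    ci: float,
    par: float = 1800.0,
    t_air: float = 28.0,
    duration: float = 400.0,
) -> float:
    """Steady-state net CO2 uptake with Ci clamped (A-Ci forward model).

    Runs the metabolic core with all regulation at its light-on steady
    values and the intercellular CO2 held at ``ci`` until A settles.
    """
    from .forcing import EnvForcing, chamber
    from .simulate import ScenarioSpec, _SI, build_initial_state, integrate

    x0 = build_initial_state(net, t_air=t_air)
    x0[_SI["GS"]] = 0.3  # open; exact value irrelevant when Ci is clamped
    forcing = EnvForcing.constant(chamber(par, t_air=t_air))
    res = integrate(
        net, x0, forcing, duration, scenario=ScenarioSpec.from_id(1),
        clamp_ci=ci, dt_out=duration / 4,
    )
    return float(res.a_net[-1])


def estimate_f_scalars(
    species: SpeciesParams,
    ci: np.ndarray,
    a_measured: np.ndarray,
    ca_set: np.ndarray,
    slope_ca: tuple = (120.0, 70.0, 40.0, 20.0, 10.0),
    plateau_ca: tuple = (800.0, 1200.0, 1500.0),
    xatol: float = 1e-3,
) -> tuple[float, float]:
    """Estimate (f_VmPEPC, f_VmRubisco) by least squares against an A-Ci curve.

    The dynamic model forward-simulates steady-state A at the measured Ci
    values; f_VmRubisco minimises the squared mismatch on the CO2-saturated
    points (model Vmax_Rubisco = Vcmax / f), then f_VmPEPC on the
    initial-slope points (model Vmax_PEPC = Vpmax / f).  All other C4 and
    C3 capacities scale with the respective f.
    """
    from .network import C4Network

    ci = np.asarray(ci, float)
    a_measured = np.asarray(a_measured, float)
    ca_set = np.asarray(ca_set, float)

    def sse(f_pepc: float, f_rub: float, ca_levels) -> float:
        trial = replace(species, f_vmpepc=f_pepc, f_vmrubisco=f_rub)
        net = C4Network(trial)
        err = 0.0
        for ca in ca_levels:
            i = int(np.argmin(np.abs(ca_set - ca)))
            a_mod = steady_state_a(net, ci=float(ci[i]))
            err += (a_mod - a_measured[i]) ** 2
        return err

    res_r = minimize_scalar(
        lambda f: sse(species.f_vmpepc, f, plateau_ca),
        bounds=(0.2, 1.5), method="bounded", options={"xatol": xatol},
    )
    if not res_r.success:
        raise RuntimeError(f"f_VmRubisco optimisation failed: {res_r}")
    f_rub = float(res_r.x)
    res_p = minimize_scalar(
        lambda f: sse(f, f_rub, slope_ca),
        bounds=(0.2, 1.5), method="bounded", options={"xatol": xatol},
    )
    if not res_p.success:
        raise RuntimeError(f"f_VmPEPC optimisation failed: {res_p}")
    return float(res_p.x), f_rub


def _make_pdrp_sse(species, time_s, a_measured, window, x0_dark):
    """Closure computing the squared A mismatch over the early window."""
    from .network import C4Network
    from .simulate import ScenarioSpec, integrate
    from .forcing import EnvForcing, chamber

    t = np.asarray(time_s, float)
    a_measured = np.asarray(a_measured, float)
    m = (t >= window[0]) & (t <= window[1])

    def sse(pdrp: float) -> float:
        trial = replace(species, pdrp=float(pdrp))
        net = C4Network(trial)
        res = integrate(
            net, x0_dark.copy(), EnvForcing.constant(chamber(1800.0)),
            window[1] + 10.0, scenario=ScenarioSpec.from_id(6), dt_out=5.0,
            rtol=1e-5, atol=1e-8,
        )
        a_sim = np.interp(t[m], res.time, res.a_net)
        return float(np.sum((a_sim - a_measured[m]) ** 2))

    return sse


def _pdrp_objective(species, time_s, a_measured, grid,
                    window=(60.0, 180.0)) -> np.ndarray:
    """Grid evaluation of the PDRP least-squares objective."""
    from .network import C4Network
    from .simulate import dark_adapt

    x0 = dark_adapt(C4Network(species))
    sse = _make_pdrp_sse(species, time_s, a_measured, window, x0)
    return np.array([sse(p) for p in grid])


def estimate_pdrp(
    species: SpeciesParams,
    time_s: np.ndarray,
    a_measured: np.ndarray,
    window: tuple[float, float] = (60.0, 180.0),
    bracket: tuple[float, float] = (0.005, 0.4),
    xatol: float = 1e-4,
    dark_state: np.ndarray | None = None,
) -> float:
    """[PDRP] (umol) by least squares on the early induction window.

    ``dark_state`` optionally supplies a precomputed dark-adapted state
    (reusable across replicates: the dark equilibrium is [PDRP]-invariant).

    Simulates the full dynamic induction (scenario 6) for candidate PDRP
    concentrations and minimises the squared A mismatch over 1-3 min.

    Raises
    ------
    ValueError
        If the window carries no information (zero variance in A).
    """
    from .network import C4Network
    from .simulate import dark_adapt

    t = np.asarray(time_s, float)
    a_measured = np.asarray(a_measured, float)
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 3 or np.ptp(a_measured[m]) < 1e-9:
        raise ValueError("induction window carries no PDRP information")

    # The dark-adapted state is computed once and reused: both PDRP rates
    # scale linearly with [PDRP], so the dark equilibrium activation state
    # is independent of it (only the approach rate changes).
    x0_cache = dark_state if dark_state is not None else dark_adapt(
        C4Network(replace(species, pdrp=float(np.sqrt(bracket[0] * bracket[1])))))
    sse = _make_pdrp_sse(species, time_s, a_measured, window, x0_cache)

    # coarse log-spaced scan to bracket the global basin (the objective can
    # develop a shallow secondary basin at high [PDRP] where activation is
    # no longer limiting), then a bounded local refinement
    grid = np.geomspace(bracket[0], bracket[1], 9)
    obj = [sse(p) for p in grid]
    i = int(np.argmin(obj))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"PDRP optimisation failed: {res}")
    return float(res.x)
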
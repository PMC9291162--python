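"""Synthetic gas-exchange data generator.

Produces LI-6800-style tables (A-Ci, A-Q, dark-to-light induction and
fluctuating-light protocols) by forward-simulating the full dynamic model
from known ground-truth species parameters, sampling at the 10-s logging
interval and applying multiplicative measurement noise.  The generated
tables use the measurement designs of the study: the A-Ci sequence
400, 300, 200, 120, 70, 40, 20, 10, 400, 400, 400, 600, 800, 1200,
1500 umol mol-1; the A-Q sequence 2000 ... 50 umol m-2 s-1; a 30-min
dark adaptation followed by a 30-min 1800 umol m-2 s-1 induction; and
1800/200/1800 umol m-2 s-1 steps of 30 min each.  Chamber conditions:
28 C air, VPD 1.32 kPa, Ca 400 umol mol-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import EnvForcing, chamber
from .gas_exchange import GasExchangeSeries, series_from_simulation
from .network import C4Network
from .params import SpeciesParams
from .simulate import ScenarioSpec, dark_adapt, integrate

ACI_CA_SEQUENCE = (400, 300, 200, 120, 70, 40, 20, 10,
                   400, 400, 400, 600, 800, 1200, 1500)
AQ_PAR_SEQUENCE = (2000, 1500, 1000, 500, 300, 200, 100, 50)
PROTOCOL_KINDS = ("aci", "aq", "induction", "fluctuating")


@dataclass(frozen=True)
class ProtocolSpec:
    """A measurement protocol: which curve to drive and its levels/timing."""

    kind: str = "induction"
    ca_levels: tuple = ACI_CA_SEQUENCE
    par_levels: tuple = AQ_PAR_SEQUENCE
    fluct_levels: tuple = (1800.0, 200.0, 1800.0)
    step_s: float = 300.0          # settling time per A-Ci / A-Q level
    fluct_step_s: float = 1800.0
    induction_s: float = 1800.0
    dark_s: float = 1800.0
    log_interval_s: float = 10.0
    t_air: float = 28.0
    vpd_kpa: float = 1.32
    ca: float = 400.0
    par_high: float = 1800.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; "
                             f"valid: {PROTOCOL_KINDS}")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, reproducible by seed."""

    sigma_a_rel: float = 0.02
    sigma_gs_rel: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a_rel < 0 or self.sigma_gs_rel < 0:
            raise ValueError("noise sigmas must be >= 0")


def _apply_noise(frame: pd.DataFrame, noise: NoiseModel) -> pd.DataFrame:
    rng = np.random.default_rng(noise.seed)
    out = frame.copy()
    if noise.sigma_a_rel > 0:
        out["A"] = out["A"] * (1.0 + noise.sigma_a_rel * rng.standard_normal(len(out)))
    if noise.sigma_gs_rel > 0:
        factor = 1.0 + noise.sigma_gs_rel * rng.standard_normal(len(out))
        # truncate so conductance stays positive
        out["gs"] = np.maximum(out["gs"] * factor, 1e-4)
    return out


def generate(
    protocol: ProtocolSpec,
    truth: SpeciesParams,
    noise: NoiseModel | None = None,
    cfg: dict | None = None,
) -> GasExchangeSeries:
    """Forward-simulate a protocol and return the noisy logged series.

    The ground-truth parameters are recorded in the series metadata so
    recovery tests can compare estimates against them.
    """
    noise = noise or NoiseModel()
    net = C4Network(truth, cfg)
    full = ScenarioSpec.from_id(6)
    meta = {
        "species": truth.name,
        "protocol": protocol.kind,
        "t_air_C": protocol.t_air,
        "vpd_kPa": protocol.vpd_kpa,
        "seed": noise.seed,
        **{f"truth_{k}": getattr(truth, k)
           for k in ("slope_bb", "intercept_bb", "gs_ki", "gs_kd", "vpmax",
                     "vcmax", "tau_rubisco", "f_vmpepc", "f_vmrubisco",
                     "pdrp", "rd")},
    }

    def ch(par, ca=protocol.ca):
        return chamber(par, ca=ca, t_air=protocol.t_air, vpd=protocol.vpd_kpa)

    if protocol.kind == "induction":
        x0 = dark_adapt(net, duration=protocol.dark_s, t_air=protocol.t_air,
                        ca=protocol.ca)
        forcing = EnvForcing.constant(ch(protocol.par_high))
        res = integrate(net, x0, forcing, protocol.induction_s,
                        scenario=full, dt_out=protocol.log_interval_s)
        series = series_from_simulation(res, meta=meta)
    elif protocol.kind == "fluctuating":
        x0 = dark_adapt(net, duration=protocol.dark_s, t_air=protocol.t_air,
                        ca=protocol.ca)
        times = [i * protocol.fluct_step_s for i in range(len(protocol.fluct_levels))]
        forcing = EnvForcing.steps(times, [ch(p) for p in protocol.fluct_levels])
        res = integrate(net, x0, forcing,
                        protocol.fluct_step_s * len(protocol.fluct_levels),
                        scenario=full, dt_out=protocol.log_interval_s)
        series = series_from_simulation(res, meta=meta)
    else:
        # stepped response curves: acclimated start, one settling period per
        # level, log the final sample of each step
        if protocol.kind == "aci":
            levels = [(protocol.par_high, float(ca)) for ca in protocol.ca_levels]
        else:
            levels = [(float(par), protocol.ca) for par in protocol.par_levels]
        times = [i * protocol.step_s for i in range(len(levels))]
        forcing = EnvForcing.steps(times, [ch(par, ca) for par, ca in levels])
        x0 = dark_adapt(net, t_air=protocol.t_air, ca=protocol.ca)
        # acclimate to the first level before starting the sequence
        pre = integrate(net, x0, EnvForcing.constant(ch(*levels[0])), 900.0,
                        scenario=full, dt_out=100.0)
        res = integrate(net, pre.final_state(), forcing,
                        protocol.step_s * len(levels),
                        scenario=full, dt_out=protocol.log_interval_s)
        frame = series_from_simulation(res, meta=meta).data
        # keep the last logged record of each settling period
        idx = [np.searchsorted(res.time, (i + 1) * protocol.step_s) - 1
               for i in range(len(levels))]
        frame = frame.iloc[idx].reset_index(drop=True)
        frame["time_s"] = np.arange(len(frame), dtype=float) * protocol.step_s
        # record the setpoint alongside the realised values
        frame["Ca_set" if protocol.kind == "aci" else "PAR_set"] = [
            lv[1] if protocol.kind == "aci" else lv[0] for lv in levels
        ]
        series = GasExchangeSeries(data=frame, meta=meta)

    series.data = _apply_noise(series.data, noise)
    return series


def ball_berry_line(
    species: SpeciesParams,
    a_levels: np.ndarray | tuple = (35.0, 30.0, 25.0, 18.0, 12.0, 7.0, 3.0, 0.5),
    rh: float = 0.65,
    ca: float = 400.0,
) -> pd.DataFrame:
    """Residual-free A-Q records lying exactly on the Ball-Berry line.

    Useful as the degenerate (noise-free, fully settled) limit of a light
    response curve: gs = slope * A * RH / Ca + intercept exactly.
    """
    a = np.asarray(a_levels, dtype=float)
    gs = species.slope_bb * a * rh / ca + species.intercept_bb
    return pd.DataFrame({
        "time_s": np.arange(a.size, dtype=float) * 300.0,
        "A": a, "gs": gs, "Ci": np.full_like(a, 150.0),
        "Ca": np.full_like(a, ca), "PAR": np.linspace(2000, 50, a.size),
        "Tleaf": np.full_like(a, 28.0), "RH": np.full_like(a, rh),
    })
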
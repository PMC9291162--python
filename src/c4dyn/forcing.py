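"""Environmental forcing: piecewise-constant time courses of PAR, air
temperature, relative humidity, CO2, wind speed and pressure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EnvConditions:
    """Instantaneous environmental driving variables."""

    par: float          # umol photons m-2 s-1
    t_air: float        # C
    rh: float           # fraction [0, 1]
    ca: float           # umol mol-1
    wind: float = 2.0   # m s-1
    pa: float = 101.325  # kPa

    def __post_init__(self) -> None:
        if self.par < 0 or self.ca <= 0 or self.wind < 0 or self.pa <= 0:
            raise ValueError(f"invalid environmental conditions: {self}")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"RH must be in [0, 1], got {self.rh}")


@dataclass(frozen=True)
class EnvForcing:
    """Piecewise-constant forcing: segment i spans [breakpoints[i],
    breakpoints[i+1]) with conditions[i]."""

    breakpoints: tuple[float, ...]      # segment start times, s; begins at 0
    conditions: tuple[EnvConditions, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.conditions):
            raise ValueError("breakpoints and conditions must have equal length")
        if self.breakpoints[0] != 0.0:
            raise ValueError("forcing must start at t=0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def at(self, t: float) -> EnvConditions:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.conditions[max(idx, 0)]

    def segments(self, duration: float):
        """Yield (t_start, t_end, conditions) covering [0, duration]."""
        bps = [b for b in self.breakpoints if b < duration] + [duration]
        for i in range(len(bps) - 1):
            yield bps[i], bps[i + 1], self.conditions[min(i, len(self.conditions) - 1)]

    @staticmethod
    def constant(cond: EnvConditions) -> "EnvForcing":
        return EnvForcing((0.0,), (cond,))

    @staticmethod
    def steps(times: list[float], conds: list[EnvConditions]) -> "EnvForcing":
        return EnvForcing(tuple(times), tuple(conds))


#: Chamber conditions used throughout: 28 C air, VPD 1.32 kPa
#: (RH such that esat(28) - e_air = 1.32), 400 umol mol-1 CO2.
def chamber(par: float, ca: float = 400.0, t_air: float = 28.0,
            vpd: float = 1.32, wind: float = 2.0) -> EnvConditions:
    from .energy_balance import saturation_vapor_pressure

    esat = saturation_vapor_pressure(t_air)
    rh = max(0.0, 1.0 - vpd / esat)
    return EnvConditions(par=par, t_air=t_air, rh=rh, ca=ca, wind=wind)


def induction_step(par_high: float = 1800.0, dark_s: float = 0.0,
                   duration_s: float = 1800.0, ca: float = 400.0) -> EnvForcing:
    """Dark (optional) then a step to high light."""
    if dark_s > 0:
        return EnvForcing.steps([0.0, dark_s], [chamber(0.0, ca), chamber(par_high, ca)])
    return EnvForcing.constant(chamber(par_high, ca))


def fluctuating_light(levels=(1800.0, 200.0, 1800.0), step_s: float = 1800.0,
                      ca: float = 400.0) -> EnvForcing:
    """The fluctuating-light protocol: 30-min steps of high/low/high light."""
    times = [i * step_s for i in range(len(levels))]
    return EnvForcing.steps(times, [chamber(p, ca) for p in levels])
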
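"""Stomatal conductance: Ball-Berry steady state, first-order dynamics,
and kinetic-constant fitting from measured conductance time series.

The steady-state target follows Ball-Berry,
``gs_steady = slope * A * RH / Ca + intercept`` (floored at the intercept
when A <= 0, e.g. in darkness), and the actual conductance relaxes toward
the target first-order with distinct rate constants for opening (k_i,
target above current gs) and closing (k_d).  All conductances here are to
water vapour; the metabolic coupling divides by 1.6 for CO2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit


@dataclass(frozen=True)
class BallBerryParams:
    slope: float              # dimensionless
    intercept: float          # mol m-2 s-1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("Ball-Berry slope must be positive")


@dataclass
class StomatalKinetics:
    """First-order stomatal rate constants (min-1) and current gs."""

    k_i: float
    k_d: float
    gs: float = 0.05

    def __post_init__(self) -> None:
        if self.k_i <= 0 or self.k_d <= 0:
            raise ValueError("stomatal rate constants must be positive")
        if self.gs < 0:
            raise ValueError("gs must be >= 0")


def ball_berry_steady(a: float, rh: float, ca: float, p: BallBerryParams) -> float:
    """Steady-state stomatal conductance to water, mol m-2 s-1."""
    if ca <= 0:
        raise ValueError(f"Ca must be positive, got {ca}")
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"RH must be a fraction in [0, 1], got {rh}")
    if a <= 0:
        return p.intercept
    return p.slope * a * rh / ca + p.intercept


def gs_rate(gs: float, gs_steady: float, kin: StomatalKinetics) -> float:
    """d(gs)/dt in mol m-2 s-1 min-1.

    Opening (target above current) uses k_i, closing uses k_d; the switch
    at target crossings is instantaneous with no hysteresis band.
    """
    k = kin.k_i if gs_steady > gs else kin.k_d
    return k * (gs_steady - gs)


def _exp_transient(t: np.ndarray, g_max: float, g_0: float, k: float) -> np.ndarray:
    return (g_max - g_0) * np.exp(-k * t) + g_0


def fit_gs_kinetics(time_min: np.ndarray, gs: np.ndarray) -> lmfit.minimizer.MinimizerResult:
    """Fit gs(t) = (g_max - g_0) exp(-k t) + g_0 by nonlinear least squares.

    For closing transients the series decays from g_max toward g_0; for
    opening transients the same three-parameter form rises toward g_max
    (g_0 above g_max simply mirrors the exponential), so a single
    parametrisation covers both directions.

    Parameters
    ----------
    time_min : array, minutes (monotone increasing)
    gs : array, mol m-2 s-1

    Returns
    -------
    lmfit ModelResult with parameters ``g_max`` (the asymptote-side start
    value), ``g_0`` (the asymptote) and ``k`` (min-1), plus residuals.

    Raises
    ------
    ValueError
        For degenerate (constant or too-short) series where k is
        unidentifiable.
    """
    time_min = np.asarray(time_min, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if time_min.size < 10:
        raise ValueError("need at least 10 points to fit stomatal kinetics")
    if np.ptp(gs) < 1e-12 * max(1.0, abs(gs[0])):
        raise ValueError("constant gs series: rate constant k is unidentifiable")

    model = lmfit.Model(_exp_transient, independent_vars=["t"])
    params = model.make_params(
        g_max=gs[0],
        g_0=gs[-1],
        k=dict(value=max(0.2, 2.0 / max(time_min[-1], 1e-9)), min=1e-6),
    )
    result = model.fit(gs, params, t=time_min - time_min[0])
    if not result.success:
        raise ValueError(
            "stomatal kinetics fit did not converge; "
            f"last parameters {result.params.valuesdict()}, "
            f"residual {float(np.sum(result.residual ** 2)):.3g}"
        )
    return result
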
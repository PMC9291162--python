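"""Shared fixtures: parameter sets, networks, and cached simulations.

Simulation-heavy fixtures are session-scoped so the induction runs that
several test modules inspect are computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

import c4dyn
from c4dyn.forcing import EnvForcing, chamber
from c4dyn.network import C4Network
from c4dyn.simulate import ScenarioSpec, dark_adapt, integrate


@pytest.fixture(scope="session")
def original():
    return c4dyn.get_species("original")


@pytest.fixture(scope="session")
def maize():
    return c4dyn.get_species("maize")


@pytest.fixture(scope="session")
def net_original(original):
    return C4Network(original)


@pytest.fixture(scope="session")
def net_maize(maize):
    return C4Network(maize)


@pytest.fixture(scope="session")
def dark_state_original(net_original):
    return dark_adapt(net_original)


@pytest.fixture(scope="session")
def dark_state_maize(net_maize):
    return dark_adapt(net_maize)


@pytest.fixture(scope="session")
def scenario_runs(net_original, dark_state_original):
    """All six scenario inductions for the reference parameter set."""
    forcing = EnvForcing.constant(chamber(1800.0))
    return {
        sid: integrate(
            net_original, dark_state_original.copy(), forcing, 1800.0,
            scenario=ScenarioSpec.from_id(sid), dt_out=2.0,
        )
        for sid in range(1, 7)
    }


@pytest.fixture(scope="session")
def maize_induction(net_maize, dark_state_maize):
    """Scenario-6 maize induction (the species-validation run)."""
    forcing = EnvForcing.constant(chamber(1800.0))
    return integrate(net_maize, dark_state_maize.copy(), forcing, 1800.0,
                     scenario=ScenarioSpec.from_id(6), dt_out=2.0)


@pytest.fixture(scope="session")
def clean_maize_induction_series(maize):
    """Noise-free synthetic induction table with maize ground truth."""
    from c4dyn.synthetic import NoiseModel, ProtocolSpec, generate

    return generate(ProtocolSpec(kind="induction"), maize,
                    NoiseModel(sigma_a_rel=0.0, sigma_gs_rel=0.0, seed=0))


def settle_time(t: np.ndarray, a: np.ndarray, a_ss: float, frac: float = 0.05):
    """First time A enters and stays within ``frac`` of the steady value."""
    ok = np.abs(a - a_ss) <= frac * abs(a_ss)
    for i in range(len(t)):
        if ok[i:].all():
            return t[i]
    return np.inf
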
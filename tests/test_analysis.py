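"""Scenario comparisons, leakiness, induction metrics, sensitivity and
flux-control coefficients."""

import numpy as np
import pytest

from c4dyn.analysis import (
    flux_control_coefficient,
    induction_metrics,
    leakiness,
    run_scenario,
    sensitivity_coefficient,
)
from c4dyn.network import N_RXN, _RI
from c4dyn.simulate import ScenarioSpec, SimulationResult
from c4dyn.forcing import EnvForcing, chamber


def _fake_result(net, t, a, v_pepc=None, v_leak=None, ci=None, gs=None):
    n = len(t)
    states = np.zeros((n, 34))
    states[:, -12] = ci if ci is not None else 150.0   # Ci column
    from c4dyn.simulate import _SI

    states[:, _SI["Ci"]] = ci if ci is not None else 150.0
    states[:, _SI["GS"]] = gs if gs is not None else 0.2
    fluxes = np.zeros((n, N_RXN))
    if v_pepc is not None:
        fluxes[:, _RI["v_PEPC"]] = v_pepc
    if v_leak is not None:
        fluxes[:, _RI["v_CO2_leak"]] = v_leak
    return SimulationResult(
        time=np.asarray(t, float), states=states, fluxes=fluxes,
        a_net=np.asarray(a, float), network=net,
        scenario=ScenarioSpec.from_id(1),
        forcing=EnvForcing.constant(chamber(1800.0)),
    )


class TestRunScenario:
    def test_unknown_scenario_rejected(self, original):
        with pytest.raises(ValueError):
            run_scenario(0, original)

    def test_early_induction_speed_ordering(self, scenario_runs):
        # instant activation (1) is fastest; each added dynamic mechanism
        # slows the first minute of induction further
        a60 = {sid: float(np.interp(60.0, r.time, r.a_net))
               for sid, r in scenario_runs.items()}
        assert a60[1] > a60[2]
        assert a60[1] > a60[3]
        assert a60[2] > a60[4]
        assert a60[3] > a60[4]
        assert a60[4] >= a60[5] - 0.02 * a60[1]
        assert a60[5] > a60[6]

    def test_dynamic_other_enzymes_change_little(self, scenario_runs):
        # beyond the first minute (the held-vs-ramped activation transient)
        # scenarios 4 and 5 are nearly identical
        r4, r5 = scenario_runs[4], scenario_runs[5]
        m = r4.time >= 60.0
        a5 = np.interp(r4.time[m], r5.time, r5.a_net)
        assert np.max(np.abs(r4.a_net[m] - a5)) < 0.03 * r4.steady_a()

    def test_cumulative_carbon_ordering(self, scenario_runs):
        cum = {sid: np.trapezoid(r.a_net, r.time)
               for sid, r in scenario_runs.items()}
        assert cum[6] <= cum[5] <= cum[1]

    def test_scenario_two_keeps_scenario_one_steady_state(self, scenario_runs):
        assert scenario_runs[2].steady_a() == pytest.approx(
            scenario_runs[1].steady_a(), rel=0.01)

    def test_dynamic_rubisco_lowers_steady_state(self, scenario_runs):
        # with Rca regulation a fraction of Rubisco stays inactive at steady
        # state, lowering A relative to the fully activated model
        assert scenario_runs[3].steady_a() < 0.95 * scenario_runs[1].steady_a()


class TestLeakiness:
    def test_ratio_of_fluxes(self, net_original):
        t = np.arange(5)
        res = _fake_result(net_original, t, np.full(5, 30.0),
                           v_pepc=np.full(5, 40.0), v_leak=np.full(5, 8.8))
        assert leakiness(res) == pytest.approx(np.full(5, 0.22))

    def test_reported_zero_below_pepc_floor(self, net_original):
        t = np.arange(5)
        res = _fake_result(net_original, t, np.zeros(5),
                           v_pepc=np.full(5, 0.05), v_leak=np.full(5, 1.0))
        assert np.all(leakiness(res) == 0.0)

    def test_steady_leakiness_bounded(self, scenario_runs):
        for sid, r in scenario_runs.items():
            phi = r.phi
            assert np.all(phi > -0.05), sid
            assert np.all(phi < 1.0), sid
            assert phi[-1] > 0.0, sid


class TestInductionMetrics:
    def test_exponential_closed_form(self, net_original):
        # A(t) = A_s (1 - e^{-t/tau}) with tau = 283 s has IT50 = tau ln 2
        tau, a_s = 283.0, 30.0
        t = np.arange(0.0, 1801.0, 2.0)
        a = a_s * (1.0 - np.exp(-t / tau))
        res = _fake_result(net_original, t, a, ci=np.full(t.size, 120.0))
        m = induction_metrics(res)
        a_ss = np.mean(a[t >= 1500.0])
        expected_it50 = -tau * np.log(1 - 0.5 * a_ss / a_s)
        assert m.it50_s == pytest.approx(expected_it50, abs=2.0)
        assert m.it50_s == pytest.approx(tau * np.log(2), rel=0.02)

    def test_instant_saturation(self, net_original):
        t = np.arange(0.0, 1801.0, 2.0)
        a = np.full(t.size, 25.0)
        m = induction_metrics(_fake_result(net_original, t, a))
        assert m.it50_s == 0.0
        assert m.mean_a_reduction_pct == pytest.approx(0.0, abs=1e-9)

    def test_maize_metrics_near_measured_values(self, maize_induction):
        m = induction_metrics(maize_induction)
        assert m.it50_s == pytest.approx(196.0, rel=0.20)
        assert m.mean_a_reduction_pct == pytest.approx(17.7, abs=4.0)
        assert m.min_ci == pytest.approx(66.0, abs=15.0)


class TestSensitivity:
    def test_inert_parameter_has_zero_sensitivity(self, maize):
        # stomatal closing rate never acts during a monotone opening
        t, sc = sensitivity_coefficient("gs_kd", maize, duration=900.0,
                                        dt_out=30.0)
        # zero up to ODE-solver noise; genuine sensitivities are O(0.1)
        assert np.max(np.abs(sc)) < 1e-3

    def test_unknown_parameter_rejected(self, maize):
        with pytest.raises(ValueError):
            sensitivity_coefficient("leaf_area", maize)

    def test_pdrp_limits_earlier_than_rubisco_activation(self, maize):
        # the PDRP sensitivity peaks in the first phase of induction,
        # before the tau_Rubisco sensitivity peak
        t, sc_pdrp = sensitivity_coefficient("pdrp", maize, duration=1500.0,
                                             dt_out=10.0)
        _, sc_tau = sensitivity_coefficient("tau_rubisco", maize,
                                            duration=1500.0, dt_out=10.0)
        t_peak_pdrp = t[np.argmax(np.abs(sc_pdrp))]
        t_peak_tau = t[np.argmax(np.abs(sc_tau))]
        assert t_peak_pdrp < t_peak_tau
        assert t_peak_pdrp <= 300.0


class TestFluxControl:
    def test_mutase_control_decays_after_first_minute(self, original):
        t, fcc = flux_control_coefficient("mutase_enolase", original,
                                          duration=600.0, dt_out=10.0,
                                          scenario=1)
        early = np.abs(fcc[(t > 5) & (t <= 45)]).max()
        late = np.abs(fcc[t >= 120]).max()
        assert late < 0.05
        assert early > late

    def test_unknown_enzyme_rejected(self, original):
        with pytest.raises(ValueError):
            flux_control_coefficient("hexokinase", original)
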
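"""Enzyme regulation kinetics: PDRP/PPDK switching, Rca-mediated Rubisco
activation, clamped-linear light activation, temperature responses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from c4dyn.regulation import (
    PDRPParams,
    PPDKState,
    RubiscoActivationParams,
    TempResponse,
    first_order_activation,
    pdrp_rates,
    rca_total_from_tau,
    rubisco_target_vmax,
    steady_activation_fraction,
    temperature_scale,
)


class TestPDRP:
    def test_no_phosphoryl_donor_no_inactivation(self):
        p = PDRPParams()
        v_i, v_a = pdrp_rates(p, PPDKState(0.2, 0.1), adp_mchl=0.0,
                              pyr_mchl=1.0, pi_mchl=10.0)
        assert v_i == 0.0
        assert v_a > 0.0

    def test_no_inactive_pool_no_activation(self):
        p = PDRPParams()
        v_i, v_a = pdrp_rates(p, PPDKState(0.3, 0.0), adp_mchl=0.5,
                              pyr_mchl=1.0, pi_mchl=10.0)
        assert v_a == 0.0
        assert v_i > 0.0

    def test_rates_linear_in_pdrp_concentration(self):
        base = PDRPParams(pdrp_mchl=4e-5)
        doubled = PDRPParams(pdrp_mchl=8e-5)
        state = PPDKState(0.15, 0.15)
        args = dict(adp_mchl=0.3, pyr_mchl=0.8, pi_mchl=9.0)
        v1 = pdrp_rates(base, state, **args)
        v2 = pdrp_rates(doubled, state, **args)
        assert v2[0] == pytest.approx(2 * v1[0], rel=1e-12)
        assert v2[1] == pytest.approx(2 * v1[1], rel=1e-12)

    def test_total_ppdk_conserved_by_ode_pair(self):
        # explicit Euler on dE = va - vi, dEP = vi - va keeps E + EP fixed
        p = PDRPParams()
        e, ep = 0.25, 0.05
        total = e + ep
        for _ in range(2000):
            v_i, v_a = pdrp_rates(p, PPDKState(e, ep), 0.4, 0.5, 10.0)
            e += 0.1 * (v_a - v_i)
            ep += 0.1 * (v_i - v_a)
        assert e + ep == pytest.approx(total, abs=1e-12)
        assert 0.0 <= e <= total

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pdrp_rates(PDRPParams(), PPDKState(0.1, 0.1), -0.1, 0.0, 1.0)


class TestRubiscoActivation:
    @pytest.mark.parametrize(
        "tau, expected",
        [(216.9, 1.0), (3.881, 216.9 / 3.881), (9.714, 216.9 / 9.714)],
    )
    def test_rca_pool_from_time_constant(self, tau, expected):
        assert rca_total_from_tau(tau) == pytest.approx(expected, rel=1e-12)
        # hand values from the ratio: maize 55.89, sorghum 22.33 mg m-2
        if tau == 3.881:
            assert rca_total_from_tau(tau) == pytest.approx(55.89, abs=0.01)
        if tau == 9.714:
            assert rca_total_from_tau(tau) == pytest.approx(22.33, abs=0.01)

    def test_rca_pool_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            rca_total_from_tau(0.0)

    def test_target_zero_in_darkness(self):
        p = RubiscoActivationParams(tau_rubisco_min=5.0, vmax_rubisco_full=70.0)
        assert rubisco_target_vmax(p, a_rca=0.0) == 0.0

    def test_half_saturation_at_k_activase(self):
        # an active-Rca pool equal to K_activase gives half the full capacity
        p = RubiscoActivationParams(
            tau_rubisco_min=5.0, vmax_rubisco_full=70.0, rca_total=12.3
        )
        assert rubisco_target_vmax(p, a_rca=1.0) == pytest.approx(35.0)

    def test_saturation_limit(self):
        p = RubiscoActivationParams(
            tau_rubisco_min=5.0, vmax_rubisco_full=70.0, rca_total=1e9
        )
        assert rubisco_target_vmax(p, 1.0) == pytest.approx(70.0, rel=1e-6)

    @given(st.floats(0, 1), st.floats(0.5, 60))
    @settings(max_examples=50, deadline=None)
    def test_target_monotone_in_activation_and_pool(self, a_rca, tau):
        p_small = RubiscoActivationParams(tau_rubisco_min=tau, vmax_rubisco_full=70.0)
        p_large = RubiscoActivationParams(
            tau_rubisco_min=tau, vmax_rubisco_full=70.0,
            rca_total=2 * p_small.rca_total,
        )
        lo = rubisco_target_vmax(p_small, a_rca)
        hi = rubisco_target_vmax(p_large, a_rca)
        assert 0.0 <= lo <= hi <= 70.0
        assert rubisco_target_vmax(p_small, min(a_rca + 0.1, 1.0)) >= lo


class TestFirstOrderActivation:
    def test_fixed_point(self):
        assert first_order_activation(42.0, 42.0, 5.0) == 0.0

    def test_exponential_closed_form(self):
        # integrate dV/dt = (target - V)/tau and compare with the closed form
        tau, target, dt = 5.0, 10.0, 0.001
        v = 0.0
        n_tau = int(tau / dt)
        values = {}
        for i in range(1, 3 * n_tau + 1):
            v += dt * first_order_activation(v, target, tau)
            if i in (n_tau, 3 * n_tau):
                values[i // n_tau] = v
        assert values[1] == pytest.approx(target * (1 - math.e**-1), rel=1e-3)
        assert values[3] == pytest.approx(target * (1 - math.e**-3), rel=1e-3)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            first_order_activation(0.0, 1.0, 0.0)


class TestLightActivation:
    def test_dark_value_is_intercept(self):
        assert steady_activation_fraction(0.0, 2e-3, 0.15) == 0.15

    def test_clamped_at_one_for_bright_light(self):
        assert steady_activation_fraction(5000.0, 2e-3, 0.15) == 1.0

    def test_clamp_boundary(self):
        k, c = 2e-3, 0.2
        i_star = (1 - c) / k
        assert steady_activation_fraction(i_star, k, c) == pytest.approx(1.0)

    @given(st.floats(0, 3000), st.floats(1e-5, 5e-3), st.floats(0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_fraction_bounded(self, irradiance, k, c):
        a = steady_activation_fraction(irradiance, k, c)
        assert min(c, 1.0) <= a <= 1.0


class TestTemperatureScale:
    @pytest.mark.parametrize("tr", [
        TempResponse(form="q10", q10=2.0),
        TempResponse(form="arrhenius", ea=67000.0),
        TempResponse(form="peaked_arrhenius", ea=64800.0, hd=149250.0,
                     delta_s=486.0),
    ], ids=["q10", "arrhenius", "peaked"])
    def test_unity_at_reference_temperature(self, tr):
        assert temperature_scale(tr, 25.0) == pytest.approx(1.0, abs=1e-12)

    def test_q10_doubles_over_ten_degrees(self):
        assert temperature_scale(TempResponse(form="q10", q10=2.0), 35.0) == \
            pytest.approx(2.0, rel=1e-12)

    def test_arrhenius_monotone_increasing(self):
        tr = TempResponse(form="arrhenius", ea=58000.0)
        temps = np.linspace(0, 50, 26)
        factors = [temperature_scale(tr, t) for t in temps]
        assert np.all(np.diff(factors) > 0)

    def test_peaked_form_declines_above_optimum(self):
        tr = TempResponse(form="peaked_arrhenius", ea=64800.0, hd=149250.0,
                          delta_s=486.0)
        temps = np.linspace(0, 55, 56)
        factors = np.array([temperature_scale(tr, t) for t in temps])
        i_opt = int(np.argmax(factors))
        assert 0 < i_opt < len(temps) - 1          # interior optimum
        assert np.all(np.diff(factors[i_opt + 1:]) < 0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            TempResponse(form="linear")

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValueError):
            temperature_scale(TempResponse(), 80.0)
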
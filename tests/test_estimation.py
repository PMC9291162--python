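"""Parameter-estimation workflow: every estimator is a round trip —
noise-free synthetic inputs are recovered to numerical precision, and
noisy inputs are recovered with small median bias."""

import numpy as np
import pytest

from c4dyn.estimation import (
    aci_forward,
    estimate_pdrp,
    estimate_rd,
    estimate_tau_rubisco,
    fit_aci,
    fit_ball_berry,
)
from c4dyn.synthetic import ball_berry_line

ACI_CI = np.array([240, 180, 120, 72, 42, 24, 12, 6, 240, 240, 240,
                   360, 480, 720, 900], dtype=float)


class TestFitAci:
    def test_round_trip_reference_capacities(self):
        a = aci_forward(ACI_CI, vpmax=120.0, vcmax=60.0, rd=1.0)
        res = fit_aci(ACI_CI, a, rd=1.0)
        assert res.params["vpmax"].value == pytest.approx(120.0, rel=1e-6)
        assert res.params["vcmax"].value == pytest.approx(60.0, rel=1e-6)

    def test_noisy_recovery_low_bias(self):
        a = aci_forward(ACI_CI, vpmax=120.0, vcmax=60.0, rd=1.0)
        rng = np.random.default_rng(7)
        vp, vc = [], []
        for _ in range(100):
            noisy = a * (1 + 0.02 * rng.standard_normal(a.size))
            res = fit_aci(ACI_CI, noisy, rd=1.0)
            vp.append(res.params["vpmax"].value)
            vc.append(res.params["vcmax"].value)
        assert abs(np.median(vp) / 120.0 - 1) < 0.03
        assert abs(np.median(vc) / 60.0 - 1) < 0.03

    def test_decreasing_response_rejected(self):
        a = np.linspace(30.0, 5.0, ACI_CI.size)
        with pytest.raises(ValueError, match="decreases"):
            fit_aci(ACI_CI, a)

    def test_missing_regions_rejected(self):
        high_only = np.linspace(300, 900, 8)
        with pytest.raises(ValueError, match="initial-slope"):
            fit_aci(high_only, aci_forward(high_only, 120, 60))
        low_only = np.linspace(5, 100, 8)
        with pytest.raises(ValueError, match="plateau"):
            fit_aci(low_only, aci_forward(low_only, 120, 60))


class TestBallBerryRegression:
    def test_exact_recovery_from_residual_free_line(self, original):
        frame = ball_berry_line(original)
        bb, stats = fit_ball_berry(frame["A"], frame["gs"], frame["RH"],
                                   frame["Ca"])
        assert bb.slope == pytest.approx(original.slope_bb, abs=1e-8)
        assert bb.intercept == pytest.approx(original.intercept_bb, abs=1e-8)
        assert stats["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        a = np.array([10.0, 30.0])
        rh = np.array([0.6, 0.6])
        ca = np.array([400.0, 400.0])
        gs = 4.53 * a * rh / ca + 0.02
        bb, _ = fit_ball_berry(a, gs, rh, ca)
        assert bb.slope == pytest.approx(4.53, rel=1e-12)
        assert bb.intercept == pytest.approx(0.02, rel=1e-9)

    def test_noisy_recovery_monte_carlo(self, maize):
        frame = ball_berry_line(maize)
        rng = np.random.default_rng(11)
        slopes, icpts = [], []
        for _ in range(50):
            gs = np.maximum(
                frame["gs"] * (1 + 0.05 * rng.standard_normal(len(frame))),
                1e-4,
            )
            bb, _ = fit_ball_berry(frame["A"], gs, frame["RH"], frame["Ca"])
            slopes.append(bb.slope)
            icpts.append(bb.intercept)
        assert abs(np.median(slopes) / maize.slope_bb - 1) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ball_berry([1.0], [0.1], [0.6], [400.0])


class TestTauRubisco:
    @staticmethod
    def _exponential_series(tau_min=5.0, a_f=30.0, a_0=-2.0,
                            duration_s=3600.0):
        t = np.arange(0.0, duration_s + 1e-9, 10.0)
        return t, a_f - (a_f - a_0) * np.exp(-t / (tau_min * 60.0))

    def test_exact_exponential_recovery(self):
        t, a = self._exponential_series()
        tau, stats = estimate_tau_rubisco(t, a)
        assert tau == pytest.approx(5.0, abs=0.005)
        assert stats["r2"] > 0.999999

    def test_slope_to_tau_arithmetic(self):
        # a semilog slope of -0.2 min-1 corresponds to tau = 5 min
        t, a = self._exponential_series(tau_min=5.0)
        _, stats = estimate_tau_rubisco(t, a)
        assert stats["slope_per_s"] * 60.0 == pytest.approx(-0.2, rel=1e-3)

    def test_invariant_to_additive_offset(self):
        t, a = self._exponential_series()
        tau1, _ = estimate_tau_rubisco(t, a)
        tau2, _ = estimate_tau_rubisco(t, a + 7.5)
        assert tau1 == pytest.approx(tau2, rel=1e-12)

    def test_noisy_recovery_monte_carlo(self):
        t, a = self._exponential_series(duration_s=1800.0)
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(50):
            noisy = a * (1 + 0.02 * rng.standard_normal(a.size))
            taus.append(estimate_tau_rubisco(t, noisy)[0])
        assert abs(np.median(taus) / 5.0 - 1) < 0.05

    def test_saturated_window_rejected(self):
        t = np.arange(0.0, 1801.0, 10.0)
        a = np.full_like(t, 30.0)  # flat: window sits at the steady rate
        with pytest.raises(ValueError):
            estimate_tau_rubisco(t, a)


class TestRd:
    def test_constant_dark_efflux(self):
        rd, suspect = estimate_rd(np.full(30, -2.282))
        assert rd == pytest.approx(2.282, rel=1e-12)
        assert not suspect

    def test_noise_averages_out(self):
        rng = np.random.default_rng(5)
        a = -1.0 + 0.1 * rng.standard_normal(360)
        rd, _ = estimate_rd(a)
        assert rd == pytest.approx(1.0, abs=3 * 0.1 / np.sqrt(360))

    def test_positive_dark_uptake_flagged(self):
        rd, suspect = estimate_rd(np.full(10, +0.5))
        assert suspect

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            estimate_rd(np.array([]))


class TestPdrp:
    def test_round_trip_from_model_generated_induction(
            self, maize, clean_maize_induction_series):
        s = clean_maize_induction_series
        est = estimate_pdrp(maize, s["time_s"], s["A"], bracket=(0.01, 0.3),
                            xatol=5e-4)
        assert est == pytest.approx(maize.pdrp, rel=0.02)

    def test_objective_unimodal_in_main_basin(self, maize,
                                              clean_maize_induction_series):
        # grid scan over a 10x bracket around the truth: the objective
        # decreases to the truth and increases after it
        from dataclasses import replace

        from c4dyn.estimation import _pdrp_objective

        s = clean_maize_induction_series
        grid = np.geomspace(maize.pdrp / 3.0, maize.pdrp * 3.0, 7)
        obj = _pdrp_objective(maize, s["time_s"], s["A"], grid)
        i_min = int(np.argmin(obj))
        assert grid[i_min] == pytest.approx(maize.pdrp, rel=0.35)
        # strictly decreasing into the basin, and nothing on the far side
        # comes back near it
        assert np.all(np.diff(obj[: i_min + 1]) < 0)
        assert np.all(obj[i_min + 1:] > obj[i_min] + 1.0)

    def test_flat_window_rejected(self, maize):
        t = np.arange(0.0, 300.0, 10.0)
        with pytest.raises(ValueError, match="no PDRP information"):
            estimate_pdrp(maize, t, np.full_like(t, 12.0))
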
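"""Henson responder, Full Threshold staircase, field simulation, GVE."""

import numpy as np
import pytest

import sfsim.vfnoise as vn
from sfsim.grid import location_index, normative_thresholds
from sfsim.vfnoise import (ResponderParams, apply_gve, ft_staircase,
                           henson_sigma, prob_seen, simulate_field)


def deterministic_responder(threshold):
    """Ideal observer: sees a stimulus iff it is at least as bright (<=)."""
    def _respond(stimulus, true_t, params, rng):
        return stimulus <= threshold
    return _respond


class TestHensonSigma:
    def test_value_at_normal_sensitivity(self):
        # exp(-0.081 * 30 + 3.27) = exp(0.84)
        assert henson_sigma(30.0) == pytest.approx(np.exp(0.84), rel=1e-6)

    def test_cap_binds_at_low_sensitivity(self):
        # exp(3.27) ~ 26.3 dB, so the 6 dB cap binds at t = 0
        assert henson_sigma(0.0) == 6.0

    def test_spread_grows_as_sensitivity_falls(self):
        assert henson_sigma(20.0) > henson_sigma(30.0)


class TestRespond:
    def test_probability_at_threshold_is_midpoint_plus_fp(self):
        p = ResponderParams(fp_rate=0.03, fn_rate=0.01)
        assert prob_seen(30.0, 30.0, p) == pytest.approx(0.03 + 0.96 / 2)

    def test_tail_limits_are_the_false_response_rates(self):
        p = ResponderParams(fp_rate=0.15, fn_rate=0.03)
        assert prob_seen(60.0, 10.0, p) == pytest.approx(0.15, abs=1e-3)
        assert prob_seen(-30.0, 30.0, p) == pytest.approx(1 - 0.03, abs=1e-3)

    def test_empirical_frequency_of_seeing_matches_closed_form(self, rng):
        p = ResponderParams()
        for stim, true_t in [(28.0, 30.0), (33.0, 30.0), (15.0, 12.0)]:
            expected = prob_seen(stim, true_t, p)
            hits = sum(vn.respond(stim, true_t, p, rng) for _ in range(4000))
            se = np.sqrt(expected * (1 - expected) / 4000)
            assert hits / 4000 == pytest.approx(expected, abs=4 * se)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ResponderParams(fp_rate=0.7, fn_rate=0.5)


class TestFTStaircase:
    def test_hand_traced_presentation_sequence(self, monkeypatch):
        # t=30, start 25: 25 seen, 29 seen, 33 not (reversal, step 2),
        # 31 not, 29 seen (second reversal) -> estimate 29
        calls = []

        def responder(stimulus, true_t, params, rng):
            calls.append(stimulus)
            return stimulus <= 30

        monkeypatch.setattr(vn, "respond", responder)
        est = ft_staircase(25.0, 30.0, None, None)
        assert calls == [25.0, 29.0, 33.0, 31.0, 29.0]
        assert est == 29.0

    def test_start_at_threshold_lands_within_two_db(self, monkeypatch):
        monkeypatch.setattr(vn, "respond", deterministic_responder(30))
        assert abs(ft_staircase(30.0, 30.0, None, None) - 30.0) <= 2.0

    def test_blind_location_floors_at_zero(self, monkeypatch):
        monkeypatch.setattr(vn, "respond",
                            lambda *a: False)
        assert ft_staircase(30.0, 0.0, None, None) == 0.0

    @pytest.mark.parametrize("true_t", [0, 3, 17, 30, 38, 40])
    @pytest.mark.parametrize("start", [0, 10, 25, 40])
    def test_deterministic_estimate_within_two_db(self, true_t, start,
                                                  monkeypatch):
        presentations = []

        def responder(stimulus, t, params, rng):
            presentations.append(stimulus)
            return stimulus <= true_t
        monkeypatch.setattr(vn, "respond", responder)
        est = ft_staircase(float(start), float(true_t), None, None)
        assert abs(est - true_t) <= 2.0
        assert len(presentations) <= 25

    def test_estimates_stay_in_instrument_range(self, rng):
        p = ResponderParams(fp_rate=0.15, fn_rate=0.03)
        for t in (0.0, 5.0, 35.0, 45.0):
            ests = [ft_staircase(30.0, t, p, rng) for _ in range(100)]
            assert min(ests) >= 0.0 and max(ests) <= 40.0


class TestSimulateField:
    def test_deterministic_responder_recovers_field_within_staircase_step(
            self, monkeypatch):
        true_vf = np.clip(normative_thresholds() - 2.0, 0, 40)

        def responder(stimulus, t, params, rng):
            return stimulus <= t
        monkeypatch.setattr(vn, "respond", responder)
        measured = simulate_field(true_vf, ResponderParams(),
                                  np.random.default_rng(0))
        assert np.all(np.abs(measured - true_vf) <= 2.0)

    def test_same_rng_seed_reproduces_the_field(self):
        true_vf = np.full(52, 28.0)
        p = ResponderParams()
        m1 = simulate_field(true_vf, p, np.random.default_rng(42))
        m2 = simulate_field(true_vf, p, np.random.default_rng(42))
        assert np.array_equal(m1, m2)

    def test_retest_variability_grows_with_field_damage(self, rng):
        p = ResponderParams()
        idx = location_index(9, 9)
        sds = []
        for level in (30.0, 15.0):
            vals = []
            for _ in range(150):
                field = np.full(52, level)
                vals.append(simulate_field(field, p, rng)[idx])
            sds.append(np.std(vals))
        assert sds[1] > sds[0]

    def test_floor_bias_is_positive_near_zero_sensitivity(self, rng):
        p = ResponderParams()
        vals = [simulate_field(np.full(52, 1.0), p, rng)[10]
                for _ in range(80)]
        assert np.mean(vals) > 1.0  # direction only


class TestApplyGVE:
    def test_exactly_one_visit_shifted_by_two_db(self, rng):
        series = np.tile(np.linspace(30, 21, 52), (10, 1))
        out = apply_gve(series, rng)
        diff = out - series
        changed = np.flatnonzero(np.ptp(diff, axis=1) + np.abs(diff).max(1))
        assert len(changed) == 1
        assert np.all(np.isin(diff[changed[0]], [2.0])) or \
            np.all(np.isin(diff[changed[0]], [-2.0]))
        assert np.all(diff[np.setdiff1d(np.arange(10), changed)] == 0)

    def test_visit_choice_is_uniform_and_sign_balanced(self, rng):
        counts = np.zeros(10)
        signs = []
        series = np.zeros((10, 52))
        for _ in range(3000):
            out = apply_gve(series, rng)
            v = int(np.flatnonzero(out.any(axis=1))[0])
            counts[v] += 1
            signs.append(np.sign(out[v, 0]))
        assert np.all(np.abs(counts / 3000 - 0.1) < 0.03)
        assert abs(np.mean(signs)) < 0.06
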
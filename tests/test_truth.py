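"""Progression criteria, anti-progression, and stable-series construction."""

import numpy as np
import pytest

import sfsim
from sfsim.grid import location_index
from sfsim.truth import (DAYS_PER_YEAR, aging_correct_vf, antiprogress,
                         build_truth, detect_oct_progression,
                         detect_vf_progression, make_stable, vf_slope_cutoff)

DT = 183 / DAYS_PER_YEAR


def flat_field_series(n_visits, level=28.0):
    return np.full((n_visits, 52), level)


def with_location_ramp(series, years, index, slope, final=28.0):
    series = series.copy()
    series[:, index] = final + slope * (years - years[-1])
    return series


class TestCutoffTable:
    @pytest.mark.parametrize("n, cutoff", [
        (4, -1.6), (5, -1.1), (6, -0.9), (7, -0.7), (8, -0.5),
        (9, -0.4), (10, -0.4), (14, -0.4),
    ])
    def test_published_cutoffs(self, n, cutoff):
        assert vf_slope_cutoff(n) == cutoff

    def test_cutoffs_relax_toward_zero_with_length(self):
        cuts = [vf_slope_cutoff(n) for n in range(4, 10)]
        assert cuts == sorted(cuts)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            vf_slope_cutoff(3)


@pytest.mark.parametrize("raw, corrected", [
    (-0.5, -0.4), (-0.05, 0.0), (0.2, 0.0),
])
def test_aging_correction_adds_then_clamps(raw, corrected):
    assert aging_correct_vf(raw) == pytest.approx(corrected)


class TestVFCriteria:
    years4 = np.arange(4.0)

    def test_steep_linear_decline_flagged_by_criterion_1(self):
        # slope -2.0, perm p = 2/25 < 0.5, corrected -1.9 < cutoff -1.6
        series = with_location_ramp(flat_field_series(4), self.years4,
                                    10, -2.0)
        res = detect_vf_progression(series, self.years4)
        assert res[10].criterion == 1
        assert res[10].slope == pytest.approx(-1.9)

    def test_moderate_decline_without_neighbor_not_flagged(self):
        # slope -1.0 (corrected -0.9) misses the length-4 cutoff of -1.6
        series = with_location_ramp(flat_field_series(4), self.years4,
                                    10, -1.0)
        res = detect_vf_progression(series, self.years4)
        assert res[10].criterion == 0
        assert res[10].slope == 0.0

    def test_shallow_decline_next_to_flagged_location_joins_by_criterion_2(self):
        a = location_index(3, 9)
        b = location_index(9, 9)        # neighbour of a
        c = location_index(-21, -9)     # far away
        series = flat_field_series(4)
        series = with_location_ramp(series, self.years4, a, -3.0)
        series = with_location_ramp(series, self.years4, b, -0.4)
        series = with_location_ramp(series, self.years4, c, -0.4)
        res = detect_vf_progression(series, self.years4)
        assert res[a].criterion == 1
        assert res[b].criterion == 2
        assert res[b].slope == pytest.approx(-0.3)
        assert res[c].criterion == 0  # eligible but isolated

    def test_criterion_2_chains_through_bridging_locations(self):
        a = location_index(3, 9)
        b = location_index(9, 9)
        c = location_index(15, 9)   # touches b but not a
        series = flat_field_series(4)
        series = with_location_ramp(series, self.years4, a, -3.0)
        series = with_location_ramp(series, self.years4, b, -0.4)
        series = with_location_ramp(series, self.years4, c, -0.4)
        res = detect_vf_progression(series, self.years4)
        assert res[b].criterion == 2
        assert res[c].criterion == 2

    def test_stable_field_yields_no_flags(self):
        res = detect_vf_progression(flat_field_series(6), np.arange(6.0))
        assert all(r.criterion == 0 and r.slope == 0.0 for r in res)


class TestOCTCriterion:
    def test_slope_above_cutoff_not_flagged_despite_significance(self):
        years = np.arange(8.0)
        series = np.tile(90.0 + -0.05 * years[:, None], (1, 6))
        res = detect_oct_progression(series, years)
        assert not any(r.progressing for r in res)

    def test_steep_significant_decline_flagged(self):
        years = np.arange(6.0)
        series = np.full((6, 6), 90.0)
        series[:, 2] = 90.0 - 2.0 * years
        res = detect_oct_progression(series, years)
        assert res[2].progressing
        assert res[2].slope == pytest.approx(-2.0)
        assert not res[0].progressing

    def test_nonsignificant_decline_not_flagged(self, rng):
        # slope below cutoff but both p-values large
        years = np.arange(5.0)
        series = np.full((5, 6), 90.0)
        series[:, 0] = [95.0, 70.0, 98.0, 60.0, 88.0]
        res = detect_oct_progression(series, years)
        assert min(res[0].p_t, res[0].p_perm) >= 0.05
        assert not res[0].progressing

    def test_no_aging_correction_applied(self):
        # a -0.15 micron/y decline passes the slope gate untouched
        years = np.arange(10.0)
        series = np.tile(90.0 - 0.15 * years[:, None], (1, 6))
        res = detect_oct_progression(series, years)
        assert all(r.progressing for r in res)
        assert res[0].slope == pytest.approx(-0.15)


class TestAntiprogress:
    def test_backward_step_arithmetic(self):
        series = antiprogress(np.array([-5.0]), np.array([-1.0]))
        assert series[-1, 0] == -5.0
        assert series[-2, 0] == pytest.approx(-5.0 + DT)  # ~ -4.499
        assert series[0, 0] == pytest.approx(-5.0 + 9 * DT)

    def test_td_cap_freezes_at_zero(self):
        series = antiprogress(np.array([-0.3]), np.array([-2.0]),
                              cap_at_zero=True)
        assert series[-1, 0] == -0.3
        assert np.all(series[:-1, 0] == 0.0)

    def test_zero_slope_repeats_final_visit(self):
        series = antiprogress(np.array([-4.0, 0.0]), np.zeros(2))
        assert np.all(series == series[-1])

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            antiprogress(np.array([0.0]), np.array([0.5]))

    def test_supranormal_final_td_is_left_alone(self):
        series = antiprogress(np.array([1.5]), np.array([-1.0]),
                              cap_at_zero=True)
        assert np.all(series == 1.5)

    def test_forward_round_trip_exact_where_cap_never_engaged(self):
        final = np.array([-5.0, -12.0, 0.0])
        slopes = np.array([-1.0, -0.4, 0.0])
        series = antiprogress(final, slopes, cap_at_zero=True)
        forward = series[0] + np.outer(np.arange(10) * DT, slopes)
        assert np.allclose(forward, series)

    def test_capped_series_matches_closed_form(self):
        final = np.array([-0.8])
        slopes = np.array([-0.7])
        series = antiprogress(final, slopes, cap_at_zero=True)
        linear = final[0] - slopes[0] * (9 - np.arange(10)) * DT
        assert np.allclose(series[:, 0], np.minimum(0.0, linear))


class TestBuildTruthAndStable:
    def test_truth_series_internally_consistent(self, small_truths):
        truths, _ = small_truths
        for t in truths:
            assert np.allclose(t.true_td[-1], t.final_td.values)
            assert np.allclose(t.true_vf - t.true_td,
                               t.normative_offset[None, :])
            assert np.all(np.diff(t.true_td, axis=0) <= 1e-9)
            capped = (t.vf_slopes < 0) & (t.final_td.values <= 0)
            assert np.all(t.true_td[:-1, capped] <= 1e-12)

    def test_make_stable_repeats_final_visit(self, small_truths):
        truths, _ = small_truths
        s = make_stable(truths[0])
        assert np.all(s.true_td == s.true_td[-1])
        assert np.all(s.true_oct == s.true_oct[-1])
        assert np.all(s.vf_slopes == 0) and np.all(s.oct_slopes == 0)

    def test_make_stable_is_idempotent(self, small_truths):
        truths, _ = small_truths
        s1 = make_stable(truths[1])
        s2 = make_stable(s1)
        assert np.array_equal(s1.true_td, s2.true_td)
        assert np.array_equal(s1.true_vf, s2.true_vf)

    def test_zero_slope_means_constant_true_series(self, small_truths):
        truths, _ = small_truths
        for t in truths:
            stable_locs = t.vf_slopes == 0
            assert np.allclose(np.ptp(t.true_td[:, stable_locs], axis=0), 0)
            stable_sectors = t.oct_slopes == 0
            assert np.allclose(
                np.ptp(t.true_oct[:, stable_sectors], axis=0), 0)


def test_derive_truth_from_series_recovers_strong_slopes(rng):
    """End-to-end clinical-style derivation on low-noise input."""
    years = np.arange(7.0)
    vf = np.full((7, 52), 30.0) + rng.normal(0, 0.15, (7, 52))
    target = location_index(-3, 9)
    vf[:, target] = 30.0 - 1.5 * years
    oct_series = np.full((7, 6), 90.0) + rng.normal(0, 0.1, (7, 6))
    oct_series[:, 5] = 90.0 - 1.2 * years
    truth = sfsim.derive_truth_from_series(
        "e1", vf, years, vf[-1] - 31.0, oct_series, years, rng=rng)
    assert truth.vf_slopes[target] == pytest.approx(-1.4, abs=0.15)
    assert truth.oct_slopes[5] == pytest.approx(-1.2, abs=0.1)
    assert (truth.vf_slopes < 0).sum() <= 4
    assert truth.has_series
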
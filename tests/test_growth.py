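"""Growth enhancement statistic, dependence threshold, and replicate voting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrikit.growth import (
    GrowthCurve,
    PassageSeries,
    classify_replicate,
    dependence_threshold,
    growth_enhancement,
    time_to_saturation_group,
    vote_dependence,
)


class TestEnhancement:
    @pytest.mark.parametrize("ow, on, expected", [
        (0.2, 0.2, 0.0),
        (0.4, 0.1, 2.0),
        (0.3, 0.1, math.log2(3)),   # 1.585
    ])
    def test_examples(self, ow, on, expected):
        assert growth_enhancement(ow, on) == pytest.approx(expected, abs=1e-3)

    def test_blank_floor_clamps_near_zero_noc(self):
        # OD below the blank floor is clamped, preventing division blow-ups
        assert growth_enhancement(0.4, 0.0) == growth_enhancement(0.4, 0.01)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            growth_enhancement(-0.1, 0.2)

    @settings(derandomize=True, max_examples=100)
    @given(
        ow=st.floats(min_value=0.02, max_value=2.0),
        on=st.floats(min_value=0.02, max_value=2.0),
        delta=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_monotone_and_zero_iff_equal(self, ow, on, delta):
        e = growth_enhancement(ow, on)
        assert growth_enhancement(ow + delta, on) > e
        assert growth_enhancement(ow, on + delta) < e
        assert (e == 0) == (ow == on)


class TestThreshold:
    def test_examples(self):
        assert dependence_threshold([0, 0, 0]) == 0.0
        assert dependence_threshold([0.1, 0.2, 0.3]) == pytest.approx(0.4)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            dependence_threshold([0.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=2, max_size=8))
    def test_permutation_invariant(self, vals):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(vals))
        assert dependence_threshold(vals) == pytest.approx(
            dependence_threshold(shuffled))

    def test_sample_sd_denominator(self):
        # n-1 denominator: sd of {0.1, 0.2, 0.3} is exactly 0.1
        assert dependence_threshold([0.1, 0.2, 0.3]) == pytest.approx(0.3 + 0.1)


def _series(od_with, od_noc):
    k = len(od_with)
    return PassageSeries("iso", 1, np.array(od_with, float), np.array(od_noc, float))


class TestReplicateClassification:
    def test_dependent_when_enhancement_exceeds_tau(self):
        call, e = classify_replicate(_series([0.5] * 4, [0.4, 0.2, 0.1, 0.05]),
                                     tau=0.6)
        assert call == "dependent"
        assert e == pytest.approx(math.log2(10), abs=1e-6)

    def test_non_dependent_when_both_arms_grow(self):
        call, e = classify_replicate(_series([0.5] * 4, [0.5] * 4), tau=0.6)
        assert call == "non-dependent"
        assert e == 0.0

    def test_no_growth_below_floor(self):
        call, _ = classify_replicate(_series([0.02] * 4, [0.02] * 4), tau=0.6)
        assert call == "no-growth"

    def test_missing_final_reading_is_incomplete(self):
        call, _ = classify_replicate(_series([0.5, 0.5, 0.5, np.nan],
                                             [0.1] * 4), tau=0.6)
        assert call == "incomplete"


class TestVote:
    @pytest.mark.parametrize("calls, expected", [
        (["dependent", "dependent", "non-dependent"], "dependent"),
        (["dependent", "non-dependent", "non-dependent"], "non-dependent"),
        (["dependent", "dependent", "dependent"], "dependent"),
        (["no-growth", "no-growth", "dependent"], "no-growth"),
    ])
    def test_two_of_three_rule(self, calls, expected):
        assert vote_dependence(calls) == expected

    def test_incomplete_decided_by_remaining_calls(self):
        # two dependents already decide the >=2 rule
        assert vote_dependence(["dependent", "dependent", "incomplete"]) == "dependent"
        # one non-dependent plus incomplete cannot reach 2 dependents either way
        assert vote_dependence(
            ["non-dependent", "non-dependent", "incomplete"]) == "non-dependent"
        # genuinely undecided
        assert vote_dependence(
            ["dependent", "incomplete", "incomplete"]) == "inconclusive"

    def test_unknown_call_rejected(self):
        with pytest.raises(ValueError):
            vote_dependence(["dependent", "maybe", "dependent"])


class TestSaturationGroup:
    def _logistic_curve(self, midpoint_h, top=0.8, rate=0.5, t_max=168):
        times = np.array([0, 6, 12, 24, 36, 48, 72, 96, 120, 144, t_max], float)
        times = times[times <= t_max]
        od = top / (1 + np.exp(-rate * (times - midpoint_h)))
        return GrowthCurve("iso", "B12", times, od)

    def test_fast_grower_in_24h_group(self):
        # logistic with midpoint 10 h reaches ~99% of plateau by 20 h
        curve = self._logistic_curve(midpoint_h=10)
        assert time_to_saturation_group(curve).group == 24

    def test_slow_grower_in_168h_group(self):
        curve = self._logistic_curve(midpoint_h=100, rate=0.1)
        assert time_to_saturation_group(curve).group == 168

    def test_still_rising_unassigned(self):
        times = np.array([0, 24, 48, 168, 240, 336], float)
        od = 0.002 * times  # monotone, never saturating
        g = time_to_saturation_group(GrowthCurve("iso", "B12", times, od))
        assert g.group is None

    def test_blank_curve_unassigned(self):
        times = np.array([0, 24, 48, 168], float)
        g = time_to_saturation_group(
            GrowthCurve("iso", "B12", times, np.zeros(4)))
        assert g.group is None


def test_growth_curve_validation():
    with pytest.raises(ValueError):
        GrowthCurve("iso", "B12", [0, 10, 5], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        GrowthCurve("iso", "B12", [0, 10, 20], [0.1, -0.2, 0.3])
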
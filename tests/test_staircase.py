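"""Staircase rules, bounds and closed-loop convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacog.observers import ObserverParams
from metacog.staircase import (
    BrightnessStaircase,
    SetSizeStaircase,
    run_titration,
    setsize_update,
)


class TestBrightnessRules:
    def test_incorrect_increases_by_four(self):
        s = BrightnessStaircase(level=200)
        s.update(0)
        assert s.level == 204

    def test_rule1_pair_fires_two_step_decrease(self):
        s = BrightnessStaircase(level=200, active_rule=1)
        s.streaks = [1, 0]
        s.update(1)
        assert s.streaks[0] == 2
        assert s.level == 198

    def test_rule2_needs_three_correct(self):
        s = BrightnessStaircase(level=200, active_rule=2)
        s.streaks = [0, 1]
        s.update(1)  # streak 2 of 3: no decrease yet
        assert s.level == 200
        s.active_rule = 2
        s.update(1)  # streak 3: fires -3
        assert s.level == 197

    def test_counter_not_reset_after_firing(self):
        # once the streak has reached the quota, every further correct fires
        s = BrightnessStaircase(level=200, active_rule=1)
        s.streaks = [2, 0]
        s.update(1)
        assert s.level == 198

    def test_error_breaks_streak(self):
        s = BrightnessStaircase(level=200, active_rule=1)
        s.streaks = [5, 0]
        s.update(0)
        assert s.streaks[0] == 0
        assert s.level == 204

    def test_rules_alternate_strictly(self):
        s = BrightnessStaircase(level=192)
        seen = []
        for acc in (1, 0, 1, 1, 0):
            seen.append(s.active_rule)
            s.update(acc)
        assert seen == [1, 2, 1, 2, 1]

    def test_clamped_at_bounds(self):
        s = BrightnessStaircase(level=255)
        s.update(0)
        assert s.level == 256
        lo = BrightnessStaircase(level=129)
        lo.streaks = [2, 0]
        lo.update(1)
        assert lo.level == 128

    def test_rejects_out_of_range_state(self):
        with pytest.raises(ValueError):
            BrightnessStaircase(level=127)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=400))
    @settings(deadline=None, max_examples=50)
    def test_level_never_leaves_legal_range(self, accs):
        s = BrightnessStaircase(level=128)
        for a in accs:
            s.update(a)
            assert 128 <= s.level <= 256


class TestSetSize:
    def test_above_band_adds_image(self):
        s = SetSizeStaircase(value=6)
        s.record_block(0.85).record_block(0.75)  # mean 0.80 > 0.75
        assert s.value == 7

    def test_dead_band_unchanged(self):
        s = SetSizeStaircase(value=6)
        s.record_block(0.72).record_block(0.72)
        assert s.value == 6

    def test_exactly_075_is_no_change(self):
        s = SetSizeStaircase(value=6)
        s.record_block(0.75).record_block(0.75)
        assert s.value == 6

    def test_displayed_floor_with_unbounded_underlying(self):
        s = SetSizeStaircase(value=1)
        for _ in range(3):
            s.record_block(0.4)
        assert s.value < 2
        assert s.displayed == 2

    def test_functional_wrapper_noop_below_two_blocks(self):
        s = SetSizeStaircase(value=5)
        setsize_update(s, [0.9])
        assert s.value == 5
        setsize_update(s, [0.9, 0.9])
        assert s.value == 6


class TestTitration:
    def test_converges_near_75_percent(self):
        params = ObserverParams()
        res = run_titration(params, 2000, rng=np.random.default_rng(1))
        assert abs(res.percent_correct - 0.75) <= 0.03

    def test_asymptote_independent_of_start(self):
        params = ObserverParams()
        accs = []
        for start in (128, 256):
            res = run_titration(
                params, 3000, rng=np.random.default_rng(2), start_level=start
            )
            accs.append(res.correct[-1500:].mean())
        assert abs(accs[0] - accs[1]) < 0.03

    def test_flat_psychometric_untitratable(self):
        # slope ~ 0: accuracy pinned at 90% regardless of level
        res = run_titration(
            ObserverParams(), 2000, rng=np.random.default_rng(3),
            accuracy_fn=lambda level: 0.9,
        )
        assert abs(res.percent_correct - 0.9) < 0.03

    def test_converges_to_root_of_psychometric(self):
        # equilibrium level should sit near where the two interleaved
        # rules balance; locate that root numerically and compare
        from scipy.optimize import brentq

        params = ObserverParams()
        from metacog.observers import psychometric_accuracy

        def drift(level):
            p = psychometric_accuracy(params, level)
            # expected level change per trial, averaged over the two rules
            r1 = -2 * p * p + 4 * (1 - p)
            r2 = -3 * p * p**2 + 4 * (1 - p)
            return 0.5 * (r1 + r2)

        root = brentq(drift, 128, 256)
        res = run_titration(params, 4000, rng=np.random.default_rng(4))
        assert abs(np.mean(res.levels[-2000:]) - root) < 6

    def test_requires_minimum_block(self):
        with pytest.raises(ValueError):
            run_titration(ObserverParams(), 30)
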
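"""Behavior statistics: counts, paired tests, ANOVA, bootstrap estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pawtrigger import (
    CriterionConfig,
    SessionConfig,
    anova_digits,
    bootstrap_mean_difference,
    count_digit_movements,
    count_post_trigger_contralateral,
    count_triggers,
    generate_pose_trace,
    offline_oracle,
    run_trial_from_trace,
)
from pawtrigger.errors import ConfigurationError, InputError, InsufficientDataError
from pawtrigger.runner import TrialRecord
from pawtrigger.stats import cell_means, paired_t_bonferroni
from pawtrigger.synthetic import PoseTrace, random_script


def _manual_trace(n_frames, dt_ms=20.0):
    """Flat trace at the nominal digit layout; mutate positions per test."""
    positions = np.zeros((n_frames, 8, 2))
    positions[:, :4, 0] = (70, 82, 94, 106)
    positions[:, 4:, 0] = (150, 162, 174, 186)
    positions[:, :, 1] = 190.0
    return PoseTrace(
        frame_indices=np.arange(n_frames),
        timestamps_ms=dt_ms * np.arange(n_frames),
        positions=positions,
        confidences=np.ones((n_frames, 8)),
        frame_rate=1000.0 / dt_ms,
        n_total=n_frames,
    )


def _record(n_events, mouse="m1", day=1, mode="training", trial=0):
    from pawtrigger.engine import TriggerEvent

    events = [
        TriggerEvent(i, 2 * i + 1, 1000.0 * i, 1000.0 * i, 1000.0 * i + 40.0,
                     7.0, 1.0, 0.95)
        for i in range(n_events)
    ]
    return TrialRecord(mouse_id=mouse, day=day, mode=mode, trial=trial, events=events)


class TestCountTriggers:
    def test_per_trial_counts_and_day_means(self):
        trials = [
            _record(3, trial=0),
            _record(5, trial=1),
            _record(1, mouse="m2", trial=0),
        ]
        table = count_triggers(trials)
        assert table["count"].tolist() == [3, 5, 1]
        cells = cell_means(table)
        m1 = cells.query("mouse == 'm1'")["mean"].item()
        assert m1 == pytest.approx(4.0)

    def test_excluded_trials_omitted(self):
        bad = _record(7, trial=1)
        bad.excluded = True
        table = count_triggers([_record(3), bad])
        assert len(table) == 1

    def test_counts_agree_with_offline_oracle(self, rng, short_session_config):
        for _ in range(5):
            trace, _ = generate_pose_trace(random_script(rng))
            rec = run_trial_from_trace(trace, short_session_config, mode="training")
            armed = 2100.0
            oracle = offline_oracle(
                trace.positions, trace.timestamps_ms, armed_from_ms=armed
            )
            assert count_triggers([rec])["count"].item() == len(oracle)


class TestPostTriggerContralateral:
    def _trace_with_triggers(self, right_jump_after=(), jump=15.0):
        """Left 8 px jumps on pairs 5/15/25/35; optional right jumps on the next pair."""
        trace = _manual_trace(100)
        trigger_pairs = [5, 15, 25, 35]
        for p in trigger_pairs:
            trace.positions[2 * p + 1, :4, 1] -= 8.0
        for p in right_jump_after:
            trace.positions[2 * p + 3, 4:, 1] += jump
        events = offline_oracle(trace.positions, trace.timestamps_ms)
        assert len(events) == 4
        return trace, events

    def test_left_only_reaches_zero(self):
        trace, events = self._trace_with_triggers()
        assert count_post_trigger_contralateral(trace, events) == 0

    def test_scripted_right_jumps_counted(self):
        trace, events = self._trace_with_triggers(right_jump_after=[5, 15, 25, 35])
        assert count_post_trigger_contralateral(trace, events) == 4

    def test_infinite_threshold_zero(self):
        trace, events = self._trace_with_triggers(right_jump_after=[5, 15])
        assert count_post_trigger_contralateral(trace, events, threshold=np.inf) == 0

    def test_trigger_at_trace_end_skipped(self):
        trace = _manual_trace(12)
        trace.positions[11, :4, 1] -= 8.0  # trigger on the final pair
        events = offline_oracle(trace.positions, trace.timestamps_ms)
        assert len(events) == 1
        assert count_post_trigger_contralateral(trace, events) == 0


class TestDigitMovements:
    def test_coherent_reach_counts_all_digits(self):
        trace = _manual_trace(40)
        trace.positions[11, :4, 1] -= 20.0
        counts = count_digit_movements(trace, "left")
        assert counts.tolist() == [1, 1, 1, 1]

    def test_single_digit_jitter_counts_one(self):
        trace = _manual_trace(40)
        trace.positions[21, 2, 1] += 20.0
        counts = count_digit_movements(trace, "left")
        assert counts.tolist() == [0, 0, 1, 0]

    def test_zero_movement_all_zero(self):
        counts = count_digit_movements(_manual_trace(40), "right")
        assert counts.tolist() == [0, 0, 0, 0]

    def test_left_threshold_inclusive_right_exclusive(self):
        trace = _manual_trace(8)
        trace.positions[1, :4, 1] += 5.0  # exactly 5 px: counts for left
        trace.positions[3, 4:, 1] += 10.0  # exactly 10 px: not for right
        assert count_digit_movements(trace, "left").sum() == 4
        assert count_digit_movements(trace, "right").sum() == 0


class TestPairedTBonferroni:
    def _cells(self, a_vals, b_vals, day_a=2, day_b=1):
        rows = []
        for i, (a, b) in enumerate(zip(a_vals, b_vals)):
            rows.append({"mouse": f"m{i}", "day": day_a, "mode": "training", "mean": a})
            rows.append({"mouse": f"m{i}", "day": day_b, "mode": "training", "mean": b})
        return pd.DataFrame(rows)

    def test_closed_form(self):
        cells = self._cells([2.0, 3.0, 4.0, 2.0], [1.0, 1.0, 2.0, 1.0])
        (res,) = paired_t_bonferroni(
            cells,
            [({"day": 2, "mode": "training"}, {"day": 1, "mode": "training"})],
        )
        assert res.t == pytest.approx(5.196, abs=0.001)
        assert res.df == 3

    def test_family_size_multiplies_p(self):
        cells = pd.concat(
            [
                self._cells([2.0, 3.0, 4.0, 2.0], [1.0, 1.0, 2.0, 1.0], day_a=d)
                for d in (2, 3, 4, 5)
            ]
        ).drop_duplicates(subset=["mouse", "day", "mode"])
        fam = [
            ({"day": d, "mode": "training"}, {"day": 1, "mode": "training"})
            for d in (2, 3, 4, 5)
        ]
        results = paired_t_bonferroni(cells, fam)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 4))

    def test_identical_cells_zero_variance_not_significant(self):
        cells = self._cells([2.0, 3.0], [2.0, 3.0])
        (res,) = paired_t_bonferroni(
            cells,
            [({"day": 2, "mode": "training"}, {"day": 1, "mode": "training"})],
        )
        assert res.zero_variance and not res.significant

    def test_unpaired_mouse_named_in_error(self):
        cells = self._cells([2.0, 3.0], [1.0, 1.0])
        cells = cells[~((cells["mouse"] == "m1") & (cells["day"] == 1))]
        with pytest.raises(InputError, match="m1"):
            paired_t_bonferroni(
                cells,
                [({"day": 2, "mode": "training"}, {"day": 1, "mode": "training"})],
            )


class TestAnovaDigits:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            groups = rng.normal(10.0, 2.0, size=(4, 8))
            rejections += anova_digits(list(groups)).p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_shifted_digit_detected(self):
        rng = np.random.default_rng(2)
        groups = list(rng.normal(10.0, 1.0, size=(4, 10)))
        groups[2] = groups[2] + 15.0
        res = anova_digits(groups)
        assert res.p < 0.001
        assert (res.df_between, res.df_within) == (3, 36)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(5, 1, 12), rng.normal(6, 1, 12)
        res = anova_digits([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, rel=1e-9)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_digits([[1.0, 2.0]])


class TestBootstrapMeanDifference:
    def test_degenerate_equal_differences_point_ci(self):
        res = bootstrap_mean_difference([(5.0, 2.0)] * 6, seed=0)
        assert (res.mean_difference, res.ci_low, res.ci_high) == (3.0, 3.0, 3.0)

    def test_seed_determinism(self):
        pairs = [(10.0, 3.0), (12.0, 5.0), (9.0, 2.0), (11.0, 6.0), (10.0, 4.0)]
        r1 = bootstrap_mean_difference(pairs, seed=7)
        r2 = bootstrap_mean_difference(pairs, seed=7)
        r3 = bootstrap_mean_difference(pairs, seed=8)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert (r1.ci_low, r1.ci_high) != (r3.ci_low, r3.ci_high)

    def test_large_effect_excludes_zero(self):
        rng = np.random.default_rng(4)
        for rep in range(40):
            a = rng.normal(20.0, 1.0, 7)
            b = rng.normal(10.0, 1.0, 7)
            res = bootstrap_mean_difference(list(zip(a, b)), seed=rep)
            assert res.excludes_zero
            assert res.ci_low <= res.mean_difference <= res.ci_high

    def test_ci_width_shrinks_with_resamples(self):
        """Variance of the CI bounds across seeds shrinks as resamples grow."""
        rng = np.random.default_rng(5)
        pairs = list(zip(rng.normal(5, 2, 10), rng.normal(4, 2, 10)))

        def bound_sd(n_res):
            lows = [
                bootstrap_mean_difference(pairs, n_resamples=n_res, seed=s).ci_low
                for s in range(12)
            ]
            return np.std(lows)

        assert bound_sd(4000) < bound_sd(200)

    def test_config_errors(self):
        with pytest.raises(ConfigurationError):
            bootstrap_mean_difference([(1.0, 0.0)] * 5, n_resamples=50)
        with pytest.raises(InsufficientDataError):
            bootstrap_mean_difference([(1.0, 0.0)])
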
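"""Behavioural scoring, exclusion rules and trial subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gripdecode.behavior import (
    ForceTrace,
    TrialScore,
    apply_exclusions,
    downsample_trace,
    filter_and_subsample,
    score_trial,
)
from gripdecode.simulate import draw_applied_forces


def make_trace(value=0.0, delay_value=None, fs=100.0, trial_index=0):
    """Constant-force trace over a standard experimental trial timeline."""
    delay_start, delay_end = 3.0, 12.0
    go, end = 12.5, 14.0
    n = int(end * fs)
    t = np.arange(n) / fs
    samples = np.full(n, float(value))
    if delay_value is not None:
        samples[(t >= delay_start) & (t < delay_end)] = delay_value
    return ForceTrace(
        trial_index=trial_index,
        samples=samples,
        sample_rate_hz=fs,
        delay_start_s=delay_start,
        delay_end_s=delay_end,
        go_onset_s=go,
        response_end_s=end,
    )


class TestDownsample:
    def test_decimation_by_three(self):
        trace = make_trace(0.5, fs=4000.0)
        down = downsample_trace(trace, 3)
        assert down.sample_rate_hz == pytest.approx(4000.0 / 3)
        assert down.samples.size == int(np.ceil(trace.samples.size / 3))
        assert down.delay_start_s == trace.delay_start_s

    def test_identity_factor(self):
        trace = make_trace(0.3)
        assert downsample_trace(trace, 1) is trace

    def test_constant_signal_mean_preserved(self):
        trace = make_trace(0.5, fs=12.0 / 14.0)  # tiny trace
        samples = np.full(12, 0.5)
        trace = ForceTrace(0, samples, 1.0, 1.0, 5.0, 8.0, 11.0)
        down = downsample_trace(trace, 3)
        assert down.samples.size == 4
        assert down.samples.mean() == pytest.approx(0.5)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            downsample_trace(make_trace(0.1), 0)


class TestScoreTrial:
    def test_interior_point_accurate(self):
        score = score_trial(make_trace(0.40), condition=2)
        assert score.accurate
        assert score.applied_force == pytest.approx(0.40)
        assert score.precision == pytest.approx(abs(0.40 - 0.375))

    def test_zero_force_inaccurate_no_press(self):
        score = score_trial(make_trace(0.0), condition=2)
        assert not score.accurate
        assert not score.delay_press_flag

    def test_delay_press_cutoff_inclusive(self):
        score = score_trial(make_trace(0.0, delay_value=0.05), condition=1)
        assert score.delay_press_flag
        below = score_trial(make_trace(0.0, delay_value=0.049), condition=1)
        assert not below.delay_press_flag

    def test_tolerance_extends_window(self):
        # level-2 window [0.30, 0.45] with +/-0.05 tolerance
        assert score_trial(make_trace(0.24), 2).accurate is False
        assert score_trial(make_trace(0.26), 2).accurate is True
        assert score_trial(make_trace(0.49), 2).accurate is True
        assert score_trial(make_trace(0.51), 2).accurate is False

    def test_missing_response_window_errors(self):
        trace = make_trace(0.4)
        short = ForceTrace(
            0, trace.samples[: int(10 * trace.sample_rate_hz)], trace.sample_rate_hz,
            3.0, 12.0, 12.5, 14.0,
        )
        with pytest.raises(ValueError, match="cover"):
            score_trial(short, 2)

    def test_scoring_invariant_to_downsampling_constant_trace(self):
        trace = make_trace(0.62)
        a = score_trial(trace, 3)
        b = score_trial(downsample_trace(trace, 3), 3)
        assert a.applied_force == pytest.approx(b.applied_force)
        assert a.accurate == b.accurate


def _score(idx, condition, accurate, press=False, precision=0.01):
    return TrialScore(
        trial_index=idx, condition=condition, applied_force=0.4,
        accurate=accurate, delay_mean_force=0.06 if press else 0.0,
        delay_press_flag=press, precision=precision,
    )


class TestExclusions:
    def test_clean_participant_included(self):
        scores = {
            (r, c): [_score(i, c, True) for i in range(12)]
            for r in (1, 2) for c in (1, 2, 3, 4)
        }
        assert apply_exclusions(scores).included

    def test_low_accuracy_cell_cited(self):
        scores = {(1, c): [_score(i, c, True) for i in range(13)] for c in (1, 2, 3)}
        scores[(1, 4)] = [_score(i, 4, i < 3) for i in range(13)]  # 3/13 = 23.1%
        status = apply_exclusions(scores)
        assert not status.included
        assert status.reasons[0]["run"] == 1 and status.reasons[0]["condition"] == 4
        assert status.reasons[0]["value"] == pytest.approx(3 / 13)

    def test_exactly_25_percent_included(self):
        scores = {(1, 1): [_score(i, 1, i < 1) for i in range(4)]}  # exactly 25%
        assert apply_exclusions(scores).included

    def test_delay_press_ceiling_strict(self):
        at = {(1, 1): [_score(i, 1, True, press=i < 3) for i in range(4)]}  # 75%
        assert apply_exclusions(at).included
        above = {(1, 1): [_score(i, 1, True, press=True) for i in range(4)]}
        assert not apply_exclusions(above).included

    def test_empty_cell_errors(self):
        with pytest.raises(ValueError, match="empty cell"):
            apply_exclusions({(1, 1): []})

    @settings(max_examples=50, deadline=None)
    @given(n_acc=st.integers(0, 10), n_inacc=st.integers(0, 10))
    def test_exclusion_monotone_in_inaccurate_trials(self, n_acc, n_inacc):
        cell = [_score(i, 1, i < n_acc) for i in range(n_acc + n_inacc + 1)]
        scores = {(1, 1): list(cell)}
        included_before = apply_exclusions(scores).included
        scores[(1, 1)].append(_score(99, 1, False))
        included_after = apply_exclusions(scores).included
        assert included_before or not included_after


class TestSubsample:
    def test_keeps_five_most_precise(self):
        cell = [_score(i, 1, True, precision=0.01 * (i + 1)) for i in range(12)]
        selected = filter_and_subsample({(1, 1): cell}, 5)
        assert selected[(1, 1)] == [0, 1, 2, 3, 4]

    def test_exactly_n_keep_candidates(self):
        cell = [_score(i, 1, True, precision=0.02) for i in range(5)]
        assert filter_and_subsample({(1, 1): cell}, 5)[(1, 1)] == [0, 1, 2, 3, 4]

    def test_tie_broken_by_earlier_trial(self):
        cell = [_score(i, 1, True, precision=0.01) for i in range(4)]
        cell += [_score(7, 1, True, precision=0.05), _score(5, 1, True, precision=0.05)]
        assert filter_and_subsample({(1, 1): cell}, 5)[(1, 1)] == [0, 1, 2, 3, 5]

    def test_press_and_inaccurate_trials_filtered_out(self):
        cell = [_score(i, 1, True, press=True) for i in range(5)]
        cell += [_score(9, 1, False)]
        cell += [_score(10 + i, 1, True) for i in range(2)]
        with pytest.raises(ValueError, match="run=1 condition=1"):
            filter_and_subsample({(1, 1): cell}, 5)

    def test_accuracy_requirement_configurable(self):
        cell = [_score(i, 1, False) for i in range(5)]
        selected = filter_and_subsample({(1, 1): cell}, 5, require_accurate=False)
        assert selected[(1, 1)] == [0, 1, 2, 3, 4]


def test_level_one_easiest_under_weber_scaling():
    """Constant-width targets + multiplicative spread: low levels are easier."""
    rng = np.random.default_rng(11)
    windows = ((0.05, 0.20), (0.30, 0.45), (0.55, 0.70), (0.80, 0.95))
    conditions = np.repeat([1, 2, 3, 4], 400)
    forces = draw_applied_forces(conditions, (0.12, 0.37, 0.62, 0.87), 0.10, rng)
    acc = []
    for level, (lo, hi) in enumerate(windows, start=1):
        f = np.minimum(forces[conditions == level], 1.0)
        acc.append(np.mean((f >= lo - 0.05) & (f <= hi + 0.05)))
    assert acc[0] == max(acc)
    assert acc[0] > acc[3]
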
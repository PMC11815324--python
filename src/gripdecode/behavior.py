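"""Behavioural scoring of grip-force traces and trial/participant selection.

A trial is scored from its continuous force trace (force on a 0-1 scale,
fraction of the participant's maximum grip force). Accuracy is judged from
the mean force over the final portion of the response window against the
cued target window, delay-period presses are flagged from the mean force
during the retention delay, and participants showing floor performance or
habitual delay presses in any run x condition cell are excluded. Finally the
trial count is equalised across conditions by keeping the most precise
trials, so that downstream beta estimates are equally reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_TARGET_WINDOWS",
    "ForceTrace",
    "TrialScore",
    "ParticipantStatus",
    "downsample_trace",
    "score_trial",
    "score_trials",
    "apply_exclusions",
    "filter_and_subsample",
]

#: Cued force windows for levels 1-4 as fractions of maximum grip force.
DEFAULT_TARGET_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.05, 0.20),
    (0.30, 0.45),
    (0.55, 0.70),
    (0.80, 0.95),
)

#: Delay-press criterion: mean delay-period force at or above this flags the trial.
DELAY_PRESS_CUTOFF = 0.05

#: Accuracy tolerance around the target window (5% of maximum grip force).
DEFAULT_TOLERANCE = 0.05

#: Length of the response window evaluated for accuracy.
DEFAULT_EVAL_WINDOW_S = 0.75


@dataclass(frozen=True)
class ForceTrace:
    """One trial's sampled grip force with its event landmarks.

    ``samples`` hold force on [0, 1] from trial (cue) onset onward;
    landmark times are in seconds relative to the same origin.
    """

    trial_index: int
    samples: np.ndarray
    sample_rate_hz: float
    delay_start_s: float
    delay_end_s: float
    go_onset_s: float
    response_end_s: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("force samples must be one-dimensional")
        if samples.size and (samples.min() < -1e-9 or samples.max() > 1 + 1e-9):
            raise ValueError("force samples must lie on [0, 1]")
        if not (0 <= self.delay_start_s < self.delay_end_s <= self.go_onset_s < self.response_end_s):
            raise ValueError("trace landmarks must be ordered")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def window_mean(self, start_s: float, end_s: float) -> float:
        """Mean force over [start_s, end_s); errors if samples are missing."""
        i0 = int(math.floor(start_s * self.sample_rate_hz))
        i1 = int(math.ceil(end_s * self.sample_rate_hz))
        i0 = max(i0, 0)
        if i1 > self.samples.size or i1 <= i0:
            raise ValueError(
                f"trial {self.trial_index}: trace does not cover "
                f"[{start_s:.2f}, {end_s:.2f}] s"
            )
        return float(self.samples[i0:i1].mean())


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    condition: int
    applied_force: float
    accurate: bool
    delay_mean_force: float
    delay_press_flag: bool
    precision: float


@dataclass(frozen=True)
class ParticipantStatus:
    """Inclusion decision with every rule violation that triggered it."""

    included: bool
    reasons: tuple[dict, ...] = field(default_factory=tuple)


def downsample_trace(trace: ForceTrace, factor: int) -> ForceTrace:
    """Decimate a trace, keeping every ``factor``-th sample.

    The sampling rate is divided by ``factor``; landmark times are
    unchanged (they are expressed in seconds, not samples).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("downsampling factor must be an integer >= 1")
    if factor == 1:
        return trace
    return replace(
        trace,
        samples=trace.samples[::factor],
        sample_rate_hz=trace.sample_rate_hz / factor,
    )


def score_trial(
    trace: ForceTrace,
    condition: int,
    target_windows: Sequence[tuple[float, float]] = DEFAULT_TARGET_WINDOWS,
    eval_window_s: float = DEFAULT_EVAL_WINDOW_S,
    tol: float = DEFAULT_TOLERANCE,
) -> TrialScore:
    """Score one trial for accuracy, precision and delay-period pressing.

    The applied force is the mean over the last ``eval_window_s`` of the
    response window; a trial is accurate when that force falls within the
    cued target window extended symmetrically by ``tol``. The delay-press
    flag uses an inclusive cutoff on the mean delay-period force.
    """
    if not 1 <= condition <= len(target_windows):
        raise ValueError(f"condition {condition} has no target window")
    lo, hi = target_windows[condition - 1]
    applied = trace.window_mean(trace.response_end_s - eval_window_s, trace.response_end_s)
    delay_mean = trace.window_mean(trace.delay_start_s, trace.delay_end_s)
    return TrialScore(
        trial_index=trace.trial_index,
        condition=condition,
        applied_force=applied,
        accurate=bool(lo - tol <= applied <= hi + tol),
        delay_mean_force=delay_mean,
        delay_press_flag=bool(delay_mean >= DELAY_PRESS_CUTOFF),
        precision=abs(applied - (lo + hi) / 2.0),
    )


def score_trials(
    traces: Sequence[ForceTrace],
    conditions: Sequence[int],
    target_windows: Sequence[tuple[float, float]] = DEFAULT_TARGET_WINDOWS,
    eval_window_s: float = DEFAULT_EVAL_WINDOW_S,
    tol: float = DEFAULT_TOLERANCE,
) -> list[TrialScore]:
    if len(traces) != len(conditions):
        raise ValueError("one condition per trace required")
    return [
        score_trial(t, c, target_windows, eval_window_s, tol)
        for t, c in zip(traces, conditions)
    ]


def apply_exclusions(
    scores: Mapping[tuple[int, int], Sequence[TrialScore]],
    acc_floor: float = 0.25,
    press_ceiling: float = 0.75,
) -> ParticipantStatus:
    """Evaluate the participant-level exclusion rules per run x condition cell.

    A participant is excluded when any cell has an accuracy proportion
    strictly below ``acc_floor`` or a delay-press proportion strictly above
    ``press_ceiling``.
    """
    reasons: list[dict] = []
    for (run, condition), cell in sorted(scores.items()):
        if len(cell) == 0:
            raise ValueError(f"empty cell run={run} condition={condition}")
        acc = sum(s.accurate for s in cell) / len(cell)
        press = sum(s.delay_press_flag for s in cell) / len(cell)
        if acc < acc_floor:
            reasons.append(
                {"rule": "accuracy_below_floor", "run": run, "condition": condition, "value": acc}
            )
        if press > press_ceiling:
            reasons.append(
                {"rule": "delay_press_above_ceiling", "run": run, "condition": condition, "value": press}
            )
    return ParticipantStatus(included=not reasons, reasons=tuple(reasons))


def filter_and_subsample(
    scores: Mapping[tuple[int, int], Sequence[TrialScore]],
    n_keep: int = 5,
    require_accurate: bool = True,
) -> dict[tuple[int, int], list[int]]:
    """Equalise trial counts: keep the ``n_keep`` most precise candidates per cell.

    Candidates are non-delay-press trials (and, by default, accurate ones).
    Precision is the distance of the applied force from the target-window
    centre; ties are broken toward the earlier trial.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    selected: dict[tuple[int, int], list[int]] = {}
    for (run, condition), cell in sorted(scores.items()):
        candidates = [
            s
            for s in cell
            if not s.delay_press_flag and (s.accurate or not require_accurate)
        ]
        if len(candidates) < n_keep:
            raise ValueError(
                f"run={run} condition={condition}: only {len(candidates)} "
                f"candidate trials after filtering, need {n_keep}"
            )
        candidates.sort(key=lambda s: (s.precision, s.trial_index))
        selected[(run, condition)] = sorted(s.trial_index for s in candidates[:n_keep])
    return selected
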
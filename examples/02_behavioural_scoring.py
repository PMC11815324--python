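"""Score grip-force traces, apply exclusion rules and pick analysis trials.

A trial is accurate when the mean force in the last 0.75 s of the response
window lands in the cued target window +/-5%; delay presses (mean delay
force >= 0.05) are flagged and removed; the 5 most precise trials per
run x condition enter the GLM.
"""

from gripdecode import (
    apply_exclusions,
    downsample_trace,
    filter_and_subsample,
    make_trial_schedule,
    score_trial,
    simulate_force_traces,
)

(schedule,) = make_trial_schedule(n_runs=1, n_experimental=48, n_catch=0, seed=4)
traces = simulate_force_traces(schedule, p_delay_press=0.05, sample_rate_hz=300, seed=5)

scores = {}
for trial, trace in zip(schedule.trials, traces):
    trace = downsample_trace(trace, 3)  # acquisition at 4 kHz is decimated by 3
    s = score_trial(trace, trial.condition)
    scores.setdefault((schedule.run_id, trial.condition), []).append(s)

for cond in (1, 2, 3, 4):
    cell = scores[(1, cond)]
    acc = sum(s.accurate for s in cell) / len(cell)
    press = sum(s.delay_press_flag for s in cell)
    print(f"level {cond}: accuracy {acc:.0%}, delay presses {press}/12")

status = apply_exclusions(scores)
print(f"participant included: {status.included}  (accuracy floor 25%, press ceiling 75%)")

selected = filter_and_subsample(scores, n_keep=5)
print(f"selected per cell: { {k: len(v) for k, v in selected.items()} }")
print("Lower levels are easier: constant-width targets with multiplicative "
      "(Weber) force noise make high forces harder to place.")
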
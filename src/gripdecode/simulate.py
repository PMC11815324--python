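"""Synthetic delayed grip-force fMRI datasets with known ground truth.

Generates everything the analysis consumes: balanced trial schedules
(four cued force levels, catch trials with shortened delays), grip-force
traces whose applied force follows a level-dependent log-normal
(multiplicative, Weber-like) distribution, and 4D BOLD runs in which a
parametric multivoxel code -- voxel weights times the trial's force label --
is embedded in chosen regions during chosen trial periods, on top of AR(1)
noise, slow sinusoidal drift and motion-coupled confounds. Because the
embedded code, its regions and its periods are known exactly, every stage of
the decoding pipeline can be validated for recovery and for calibration
under the null (zero amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
from nilearn.glm.first_level import spm_hrf
from scipy.signal import lfilter

from .behavior import ForceTrace
from .periods import DEFAULT_PERIODS, PeriodDef

__all__ = [
    "Trial",
    "TrialSchedule",
    "Region",
    "EffectSpec",
    "NoiseSpec",
    "SimulatedBold",
    "make_trial_schedule",
    "draw_applied_forces",
    "simulate_force_traces",
    "simulate_bold",
    "CUE_S",
    "DELAY_EXPERIMENTAL_S",
    "CATCH_DELAYS_S",
    "PRE_GO_S",
    "RESPONSE_S",
    "FEEDBACK_S",
    "VOXEL_MM",
]

# Trial phase durations (seconds).
CUE_S = 3.0
DELAY_EXPERIMENTAL_S = 9.0
CATCH_DELAYS_S = (6.0, 4.5, 3.0, 1.5)
PRE_GO_S = 0.5
RESPONSE_S = 1.5
FEEDBACK_S = 1.5

#: Isotropic voxel size of the simulated acquisition (mm).
VOXEL_MM = 2.5

#: Scans appended after the last trial so every FIR bin has data.
_TAIL_SCANS = 20
#: Rest before the first trial (seconds).
_LEAD_IN_S = 6.0


@dataclass(frozen=True)
class Trial:
    trial_index: int
    condition: int
    noncued_condition: int
    is_catch: bool
    delay_s: float
    onset_s: float
    onset_scan: int

    @property
    def duration_s(self) -> float:
        return CUE_S + self.delay_s + PRE_GO_S + RESPONSE_S + FEEDBACK_S

    @property
    def delay_start_s(self) -> float:
        """Delay onset relative to trial onset."""
        return CUE_S

    @property
    def go_onset_s(self) -> float:
        return CUE_S + self.delay_s + PRE_GO_S

    @property
    def response_end_s(self) -> float:
        return self.go_onset_s + RESPONSE_S


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trials of one run with scan-locked onsets."""

    run_id: int
    trials: tuple[Trial, ...]
    tr_s: float
    n_scans: int

    def experimental_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.is_catch)

    def condition_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.experimental_trials():
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts

    def pair_counts(self) -> dict[frozenset, int]:
        counts: dict[frozenset, int] = {}
        for t in self.experimental_trials():
            key = frozenset((t.condition, t.noncued_condition))
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class Region:
    """One spherical region carrying a parametric code in given periods."""

    name: str
    center_voxel: tuple[int, int, int]
    radius_voxels: float
    active_periods: frozenset[str]
    pattern_seed: int
    amplitude: float
    shared_pattern_with: str | None = None
    #: True: neural boxcar convolved with the canonical HRF (physiological
    #: timing; the BOLD-level code lags the period by several seconds).
    #: False: the pattern is written into the BOLD signal exactly at the
    #: period's scans, giving bin-exact ground truth for recovery tests.
    convolve_hrf: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"region {self.name}: amplitude must be >= 0")
        if self.radius_voxels < 1:
            raise ValueError(f"region {self.name}: radius must be >= 1 voxel")


@dataclass(frozen=True)
class EffectSpec:
    regions: tuple[Region, ...] = ()


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    drift_period_s: float = 200.0
    motion_leak: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("noise sigma must be > 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass(frozen=True)
class SimulatedBold:
    runs: tuple[nib.Nifti1Image, ...]
    motion: tuple[np.ndarray, ...]
    mask: nib.Nifti1Image
    affine: np.ndarray = field(repr=False, default=None)


def _balanced_noncued(condition: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Non-cued levels for `n` trials of one condition, as even as possible."""
    others = np.array([c for c in (1, 2, 3, 4) if c != condition])
    reps = int(math.ceil(n / 3))
    arr = np.tile(others, reps)[:n]
    rng.shuffle(arr)
    return arr


def make_trial_schedule(
    n_runs: int,
    n_experimental: int = 48,
    n_catch: int = 12,
    tr_s: float = 1.5,
    seed: int = 0,
    iti_range_s: tuple[float, float] = (3.0, 6.0),
) -> list[TrialSchedule]:
    """Build fully randomized, balanced trial schedules.

    Each run holds ``n_experimental`` experimental trials (each of the four
    force levels equally often, and -- when counts permit -- every unordered
    (cued, non-cued) level pair equally often) plus ``n_catch`` catch trials
    with shortened delays drawn balanced from {6.0, 4.5, 3.0, 1.5} s. Trial
    order is a seeded full permutation; onsets are time-locked to volume
    acquisition (onset_s = onset_scan x tr_s) with an inter-trial interval
    jittered in TR multiples over ``iti_range_s``.
    """
    if n_experimental % 4:
        raise ValueError("n_experimental must be divisible by 4")
    if n_catch % 4:
        raise ValueError("n_catch must be divisible by 4")
    rng = np.random.default_rng(seed)
    iti_lo, iti_hi = iti_range_s
    iti_choices = np.arange(math.ceil(iti_lo / tr_s), math.floor(iti_hi / tr_s) + 1) * tr_s
    if iti_choices.size == 0:
        raise ValueError("iti_range_s contains no TR multiple")

    schedules = []
    for run_id in range(1, n_runs + 1):
        records: list[tuple[int, int, bool, float]] = []
        per_cond = n_experimental // 4
        for condition in (1, 2, 3, 4):
            noncued = _balanced_noncued(condition, per_cond, rng)
            records.extend((condition, int(nc), False, DELAY_EXPERIMENTAL_S) for nc in noncued)
        catch_conditions = np.tile([1, 2, 3, 4], n_catch // 4)
        rng.shuffle(catch_conditions)
        catch_delays = np.tile(CATCH_DELAYS_S, n_catch // 4)
        rng.shuffle(catch_delays)
        for condition, delay in zip(catch_conditions, catch_delays):
            noncued = int(rng.choice([c for c in (1, 2, 3, 4) if c != condition]))
            records.append((int(condition), noncued, True, float(delay)))

        order = rng.permutation(len(records))
        trials = []
        onset_scan = int(round(_LEAD_IN_S / tr_s))
        for trial_index, rec_i in enumerate(order):
            condition, noncued, is_catch, delay = records[rec_i]
            trial = Trial(
                trial_index=trial_index,
                condition=condition,
                noncued_condition=noncued,
                is_catch=is_catch,
                delay_s=delay,
                onset_s=onset_scan * tr_s,
                onset_scan=onset_scan,
            )
            trials.append(trial)
            iti = float(rng.choice(iti_choices))
            next_t = trial.onset_s + trial.duration_s + iti
            onset_scan = int(math.ceil(next_t / tr_s - 1e-9))
        n_scans = trials[-1].onset_scan + _TAIL_SCANS + int(round(18.0 / tr_s))
        schedules.append(
            TrialSchedule(run_id=run_id, trials=tuple(trials), tr_s=tr_s, n_scans=n_scans)
        )
    return schedules


def draw_applied_forces(
    conditions: Sequence[int],
    level_mu: Sequence[float],
    level_cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw applied forces log-normally around each trial's level target.

    The log-force SD, sqrt(log(1 + cv^2)), is shared across levels, so the
    absolute spread grows proportionally with the target force -- the
    Weber/Fechner structure that motivates log-spaced decoding labels.
    """
    mu = np.asarray(level_mu, dtype=float)
    if mu.shape != (4,) or np.any(np.diff(mu) <= 0) or mu[0] <= 0 or mu[-1] >= 1:
        raise ValueError("level_mu must be 4 strictly increasing forces in (0, 1)")
    if level_cv <= 0:
        raise ValueError("level_cv must be > 0")
    sigma_log = math.sqrt(math.log(1.0 + level_cv**2))
    cond = np.asarray(conditions, dtype=int)
    return np.exp(rng.normal(np.log(mu[cond - 1]), sigma_log))


def simulate_force_traces(
    schedule: TrialSchedule,
    level_mu: Sequence[float] = (0.12, 0.37, 0.62, 0.87),
    level_cv: float = 0.10,
    p_delay_press: float = 0.0,
    sample_rate_hz: float = 4000.0,
    seed: int = 0,
) -> list[ForceTrace]:
    """Simulate one force trace per trial of a schedule.

    Traces are near-zero (small absolute-Gaussian baseline jitter) outside
    press windows; the response press ramps up after the Go cue to a plateau
    at the drawn applied force (clipped at the device maximum of 1), and with
    probability ``p_delay_press`` a sustained delay-period press with mean
    force >= 0.05 is injected so the downstream delay-press filter fires.
    """
    if not 0.0 <= p_delay_press <= 1.0:
        raise ValueError("p_delay_press must be a probability")
    rng = np.random.default_rng(seed)
    conditions = [t.condition for t in schedule.trials]
    applied = draw_applied_forces(conditions, level_mu, level_cv, rng)
    traces = []
    for trial, force in zip(schedule.trials, applied):
        delay_start = trial.delay_start_s
        delay_end = delay_start + trial.delay_s
        go = trial.go_onset_s
        end = trial.response_end_s
        n = int(round((end + 0.25) * sample_rate_hz))
        t = np.arange(n) / sample_rate_hz
        samples = np.abs(rng.normal(0.0, 0.002, size=n))
        plateau = min(float(force), 1.0)
        ramp_len = 0.1
        in_ramp = (t >= go + 0.05) & (t < go + 0.05 + ramp_len)
        samples[in_ramp] = plateau * (t[in_ramp] - go - 0.05) / ramp_len
        in_plateau = t >= go + 0.05 + ramp_len
        samples[in_plateau] = plateau + rng.normal(0.0, 0.002, size=int(in_plateau.sum()))
        if rng.random() < p_delay_press:
            amp = rng.uniform(0.06, 0.2)
            in_delay = (t >= delay_start) & (t < delay_end)
            samples[in_delay] = amp + rng.normal(0.0, 0.002, size=int(in_delay.sum()))
        traces.append(
            ForceTrace(
                trial_index=trial.trial_index,
                samples=np.clip(samples, 0.0, 1.0),
                sample_rate_hz=sample_rate_hz,
                delay_start_s=delay_start,
                delay_end_s=delay_end,
                go_onset_s=go,
                response_end_s=end,
            )
        )
    return traces


def _sphere_voxels(
    center: tuple[int, int, int], radius: float, shape: tuple[int, int, int], name: str
) -> np.ndarray:
    r = int(math.floor(radius))
    offsets = np.stack(
        np.meshgrid(*([np.arange(-r, r + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    offsets = offsets[(offsets**2).sum(axis=1) <= radius**2]
    voxels = offsets + np.asarray(center)
    if np.any(voxels < 0) or np.any(voxels >= np.asarray(shape)):
        raise ValueError(f"region {name!r} extends outside the mask {shape}")
    return voxels


def simulate_bold(
    schedules: Sequence[TrialSchedule],
    effect: EffectSpec,
    noise: NoiseSpec,
    labels: Sequence[float],
    mask_shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    periods: Sequence[PeriodDef] = DEFAULT_PERIODS,
) -> SimulatedBold:
    """Simulate per-run 4D BOLD data with an embedded parametric code.

    For every non-catch trial and every region active in a period, the
    neural time course gains the trial's force label over that period's
    time-bins; the course is convolved with the canonical double-gamma
    haemodynamic response and scattered over the region's voxels through a
    fixed random weight pattern scaled by the region amplitude. AR(1)
    Gaussian noise, a slow sinusoidal drift with voxelwise phase, and a
    random-walk motion confound leaking into the data are added on top.
    Catch trials carry no signal. Voxels are 2.5 mm isotropic.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (4,):
        raise ValueError("labels must hold one SVR target per condition")
    shape = tuple(int(s) for s in mask_shape)
    period_bins = {p.name: p.bins for p in periods}
    tr = schedules[0].tr_s
    osf = 10
    # Sum-normalized kernel: a sustained unit boxcar settles at amplitude 1,
    # so region amplitudes are in BOLD a.u. per unit label.
    hrf = spm_hrf(tr, oversampling=osf)
    hrf = hrf / hrf.sum()

    # Region voxel sets and weight patterns (shared patterns copy weights).
    region_voxels: dict[str, np.ndarray] = {}
    region_weights: dict[str, np.ndarray] = {}
    for region in effect.regions:
        region_voxels[region.name] = _sphere_voxels(
            region.center_voxel, region.radius_voxels, shape, region.name
        )
    for region in effect.regions:
        if region.shared_pattern_with is not None:
            ref = region.shared_pattern_with
            if ref not in region_voxels:
                raise ValueError(f"region {region.name!r} shares pattern with unknown {ref!r}")
            if len(region_voxels[ref]) != len(region_voxels[region.name]):
                raise ValueError(
                    f"region {region.name!r} cannot share a pattern with {ref!r}: "
                    "voxel counts differ"
                )
    for region in effect.regions:
        source = region.shared_pattern_with or region.name
        if source not in region_weights:
            w = np.random.default_rng(
                next(
                    r.pattern_seed for r in effect.regions if r.name == source
                )
            ).standard_normal(len(region_voxels[source]))
            region_weights[source] = w / w.std()

    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])
    mask = np.ones(shape, dtype=bool)
    n_vox = int(np.prod(shape))

    root = np.random.SeedSequence(seed)
    run_seeds = root.spawn(len(schedules))
    runs, motions = [], []
    for schedule, run_seed in zip(schedules, run_seeds):
        rng = np.random.default_rng(run_seed)
        n_scans = schedule.n_scans
        n_hi = n_scans * osf

        data = np.zeros((n_scans, n_vox))
        for region in effect.regions:
            if region.amplitude == 0:
                continue
            course = np.zeros(n_hi)
            for trial in schedule.trials:
                if trial.is_catch:
                    continue
                value = labels[trial.condition - 1]
                for pname in region.active_periods:
                    bins = period_bins[pname]
                    t0 = trial.onset_s + (bins[0] - 1) * tr
                    t1 = trial.onset_s + bins[-1] * tr
                    i0 = int(round(t0 / tr * osf))
                    i1 = min(int(round(t1 / tr * osf)), n_hi)
                    course[i0:i1] += value
            if region.convolve_hrf:
                bold_course = np.convolve(course, hrf)[:n_hi][::osf]
            else:
                bold_course = course[::osf]
            vox = region_voxels[region.name]
            flat = np.ravel_multi_index(vox.T, shape)
            w = region_weights[region.shared_pattern_with or region.name]
            data[:, flat] += region.amplitude * np.outer(bold_course, w)

        # AR(1) noise with stationary SD = sigma.
        innov_sd = noise.sigma * math.sqrt(1.0 - noise.ar1_rho**2)
        eps = rng.normal(0.0, innov_sd, size=(n_scans, n_vox))
        data += lfilter([1.0], [1.0, -noise.ar1_rho], eps, axis=0)

        if noise.drift_amplitude > 0:
            t = np.arange(n_scans) * tr
            phase = rng.uniform(0, 2 * np.pi, size=n_vox)
            data += noise.drift_amplitude * np.sin(
                2 * np.pi * t[:, None] / noise.drift_period_s + phase[None, :]
            )

        motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_scans, 6)), axis=0)
        if noise.motion_leak > 0:
            coefs = rng.standard_normal((6, n_vox))
            data += noise.motion_leak * motion @ coefs

        vol = np.asarray(
            data.reshape(n_scans, *shape).transpose(1, 2, 3, 0), dtype=np.float32
        )
        runs.append(nib.Nifti1Image(vol, affine))
        motions.append(motion)

    mask_img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    return SimulatedBold(runs=tuple(runs), motion=tuple(motions), mask=mask_img, affine=affine)
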
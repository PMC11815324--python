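"""First-level GLMs: FIR beta series for decoding and an HRF-convolved
univariate control model.

The decoding model assigns one 0/1 indicator regressor per (condition,
time-bin) per run -- 12 consecutive 1.5-s bins from cue onset: two cue bins,
six delay bins and four execution bins -- alongside six motion regressors
and a constant per run (220 columns in the default four-run layout). Betas
are estimated run-wise by ordinary least squares after projecting both data
and design onto the complement of a discrete-cosine high-pass basis
(128-s period cutoff). No prewhitening is applied: the betas are used as
multivoxel patterns, not as inferential statistics.

The univariate control model instead convolves period boxcars (cue, delay,
execution) with the canonical double-gamma HRF and adds, for the delay and
execution periods, parametric modulators weighted by each trial's
Fechner-adjusted force label (mean-centred within run).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from nilearn.glm.first_level import spm_hrf

from .labels import LabelScheme
from .simulate import CUE_S, TrialSchedule

__all__ = [
    "ColumnInfo",
    "FIRDesign",
    "BetaStack",
    "build_fir_design",
    "build_hrf_design",
    "highpass_dct",
    "fit_glm",
]

#: Width of one FIR time-bin (seconds); bins are TR-aligned.
BIN_S = 1.5


@dataclass(frozen=True)
class ColumnInfo:
    run: int
    kind: str  # fir | motion | constant | hrf | pmod
    condition: int | str | None = None
    time_bin: int | None = None

    def label(self) -> str:
        parts = [f"run{self.run}", self.kind]
        if self.condition is not None:
            parts.append(f"c{self.condition}")
        if self.time_bin is not None:
            parts.append(f"t{self.time_bin}")
        return "_".join(parts)


@dataclass(frozen=True)
class FIRDesign:
    matrix: np.ndarray
    columns: tuple[ColumnInfo, ...]
    run_blocks: dict[int, slice]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def run_columns(self, run: int) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.run == run]


@dataclass(frozen=True)
class BetaStack:
    """FIR beta images indexed by (run, condition, time-bin) over a mask.

    ``flat`` holds the in-mask voxel values with shape
    (n_runs, n_conditions, n_bins, n_mask_voxels); ``image`` reinflates one
    entry to a 3D volume with NaN outside the mask.
    """

    flat: np.ndarray
    runs: tuple[int, ...]
    conditions: tuple[int, ...]
    bins: tuple[int, ...]
    mask: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        expected = (len(self.runs), len(self.conditions), len(self.bins))
        if self.flat.shape[:3] != expected:
            raise ValueError("beta array shape does not match its index")
        if not np.all(np.isfinite(self.flat)):
            raise ValueError("beta values inside the mask must be finite")

    def image(self, run: int, condition: int, time_bin: int) -> np.ndarray:
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.flat[
            self.runs.index(run), self.conditions.index(condition), self.bins.index(time_bin)
        ]
        return out


def _as_array(img) -> np.ndarray:
    if isinstance(img, nib.spatialimages.SpatialImage):
        return np.asanyarray(img.dataobj)
    return np.asarray(img)


def _bin_scans(onset_scan: int, time_bin: int, tr_s: float) -> range:
    """Scans whose acquisition start lies in the trial's ``time_bin``-th bin.

    Bin t covers [onset + (t-1)*BIN_S, onset + t*BIN_S); onsets are
    scan-locked, so with TR = BIN_S this is exactly one scan.
    """
    start = onset_scan + int(math.ceil((time_bin - 1) * BIN_S / tr_s - 1e-9))
    stop = onset_scan + int(math.ceil(time_bin * BIN_S / tr_s - 1e-9))
    return range(start, max(stop, start + 1))


def build_fir_design(
    schedules: Sequence[TrialSchedule],
    selected_trials: Mapping[tuple[int, int], Sequence[int]],
    n_bins: int = 12,
    motion: Mapping[int, np.ndarray] | None = None,
    condition_field: str = "condition",
) -> FIRDesign:
    """Assemble the FIR indicator design across runs.

    ``selected_trials`` maps (run_id, condition) to the modelled trial
    indices (catch and unselected trials stay unmodelled). Setting
    ``condition_field='noncued_condition'`` builds the control design that
    models the presented-but-not-cued force level instead.
    """
    if condition_field not in ("condition", "noncued_condition"):
        raise ValueError("condition_field must be 'condition' or 'noncued_condition'")
    conditions = sorted({c for (_, c) in selected_trials})
    offsets = {}
    total = 0
    for s in schedules:
        offsets[s.run_id] = total
        total += s.n_scans

    cols: list[np.ndarray] = []
    infos: list[ColumnInfo] = []
    run_blocks: dict[int, slice] = {}
    overruns: list[str] = []
    for schedule in schedules:
        run = schedule.run_id
        off = offsets[run]
        run_blocks[run] = slice(off, off + schedule.n_scans)
        by_index = {t.trial_index: t for t in schedule.trials}
        for condition in conditions:
            chosen = selected_trials.get((run, condition), ())
            trials = [by_index[i] for i in chosen]
            for time_bin in range(1, n_bins + 1):
                col = np.zeros(total)
                for trial in trials:
                    if getattr(trial, condition_field) != condition:
                        raise ValueError(
                            f"trial {trial.trial_index} in run {run} does not have "
                            f"{condition_field}={condition}"
                        )
                    for scan in _bin_scans(trial.onset_scan, time_bin, schedule.tr_s):
                        if scan >= schedule.n_scans:
                            overruns.append(f"run {run} trial {trial.trial_index} bin {time_bin}")
                        else:
                            col[off + scan] = 1.0
                cols.append(col)
                infos.append(ColumnInfo(run=run, kind="fir", condition=condition, time_bin=time_bin))
        if motion is not None:
            mot = np.asarray(motion[run], dtype=float)
            if mot.shape != (schedule.n_scans, 6):
                raise ValueError(f"run {run}: motion table must be (n_scans, 6)")
            for j in range(6):
                col = np.zeros(total)
                col[off : off + schedule.n_scans] = mot[:, j]
                cols.append(col)
                infos.append(ColumnInfo(run=run, kind="motion", condition=j + 1))
        const = np.zeros(total)
        const[off : off + schedule.n_scans] = 1.0
        cols.append(const)
        infos.append(ColumnInfo(run=run, kind="constant"))
    if overruns:
        raise ValueError("trial bins extend past the run's last scan: " + "; ".join(overruns))
    return FIRDesign(matrix=np.column_stack(cols), columns=tuple(infos), run_blocks=run_blocks)


def build_hrf_design(
    schedules: Sequence[TrialSchedule],
    labels: LabelScheme,
    motion: Mapping[int, np.ndarray] | None = None,
    oversampling: int = 10,
) -> FIRDesign:
    """HRF-convolved design for the univariate parametric control.

    Per run: cue (3 s), delay (9 s) and execution (4.5 s) boxcars, each
    convolved with the canonical double-gamma HRF, plus delay and execution
    parametric modulators weighted by the trial's force label (mean-centred
    within run over the modelled trials), then motion and a constant.
    """
    offsets = {}
    total = 0
    for s in schedules:
        offsets[s.run_id] = total
        total += s.n_scans

    cols: list[np.ndarray] = []
    infos: list[ColumnInfo] = []
    run_blocks: dict[int, slice] = {}
    for schedule in schedules:
        run = schedule.run_id
        off = offsets[run]
        run_blocks[run] = slice(off, off + schedule.n_scans)
        tr = schedule.tr_s
        hrf = spm_hrf(tr, oversampling=oversampling)
        hrf = hrf / hrf.sum()
        n_hi = schedule.n_scans * oversampling
        trials = [t for t in schedule.trials if not t.is_catch]
        values = np.array([labels.value(t.condition) for t in trials])
        centred = values - values.mean()

        def convolved(intervals_weights) -> np.ndarray:
            course = np.zeros(n_hi)
            for (t0, t1), w in intervals_weights:
                i0 = int(round(t0 / tr * oversampling))
                i1 = min(int(round(t1 / tr * oversampling)), n_hi)
                course[i0:i1] += w
            sampled = np.convolve(course, hrf)[:n_hi][::oversampling]
            full = np.zeros(total)
            full[off : off + schedule.n_scans] = sampled
            return full

        def spans(t):
            # Cue 3 s; delay as cued; execution period 4.5 s (bins 9-11).
            cue = (t.onset_s, t.onset_s + CUE_S)
            delay = (t.onset_s + CUE_S, t.onset_s + CUE_S + t.delay_s)
            exec_start = t.onset_s + CUE_S + t.delay_s
            execution = (exec_start, exec_start + 4.5)
            return cue, delay, execution

        cue_iv = [(spans(t)[0], 1.0) for t in trials]
        delay_iv = [(spans(t)[1], 1.0) for t in trials]
        exec_iv = [(spans(t)[2], 1.0) for t in trials]
        cols.append(convolved(cue_iv))
        infos.append(ColumnInfo(run=run, kind="hrf", condition="cue"))
        cols.append(convolved(delay_iv))
        infos.append(ColumnInfo(run=run, kind="hrf", condition="delay"))
        cols.append(convolved([(iv, w) for (iv, _), w in zip(delay_iv, centred)]))
        infos.append(ColumnInfo(run=run, kind="pmod", condition="delay"))
        cols.append(convolved(exec_iv))
        infos.append(ColumnInfo(run=run, kind="hrf", condition="execution"))
        cols.append(convolved([(iv, w) for (iv, _), w in zip(exec_iv, centred)]))
        infos.append(ColumnInfo(run=run, kind="pmod", condition="execution"))

        if motion is not None:
            mot = np.asarray(motion[run], dtype=float)
            for j in range(6):
                col = np.zeros(total)
                col[off : off + schedule.n_scans] = mot[:, j]
                cols.append(col)
                infos.append(ColumnInfo(run=run, kind="motion", condition=j + 1))
        const = np.zeros(total)
        const[off : off + schedule.n_scans] = 1.0
        cols.append(const)
        infos.append(ColumnInfo(run=run, kind="constant"))
    return FIRDesign(matrix=np.column_stack(cols), columns=tuple(infos), run_blocks=run_blocks)


def highpass_dct(n_scans: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis spanning periods longer than ``cutoff_s``.

    Returns the non-constant DCT columns k for which the component period
    2 * n_scans * tr_s / k exceeds the cutoff, as an (n_scans, K) array.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed twice the TR")
    n_k = max(0, int(math.ceil(2.0 * n_scans * tr_s / cutoff_s - 1e-9)) - 1)
    s = np.arange(n_scans)
    basis = np.empty((n_scans, n_k))
    for k in range(1, n_k + 1):
        basis[:, k - 1] = math.sqrt(2.0 / n_scans) * np.cos(
            np.pi * (2 * s + 1) * k / (2 * n_scans)
        )
    return basis


def _residualize(arr: np.ndarray, basis: np.ndarray) -> np.ndarray:
    if basis.size == 0:
        return arr
    q, _ = np.linalg.qr(basis)
    return arr - q @ (q.T @ arr)


def fit_glm(
    bold_runs: Sequence,
    design: FIRDesign,
    drift: Mapping[int, np.ndarray] | None = None,
    mask=None,
) -> BetaStack:
    """Estimate run-wise OLS betas for the FIR columns of a design.

    ``bold_runs`` are 4D images (or arrays) ordered like the design's run
    blocks; ``drift`` maps run_id to that run's high-pass basis, against
    which both data and design are residualized before the fit. Rank
    deficiency falls back to the pseudoinverse with a warning.
    """
    run_ids = sorted(design.run_blocks)
    if len(bold_runs) != len(run_ids):
        raise ValueError("one 4D image per design run required")
    first = _as_array(bold_runs[0])
    if mask is None:
        mask_arr = np.ones(first.shape[:3], dtype=bool)
        affine = np.eye(4)
    else:
        mask_arr = _as_array(mask).astype(bool)
        affine = mask.affine if isinstance(mask, nib.spatialimages.SpatialImage) else np.eye(4)
    if not mask_arr.any():
        raise ValueError("mask is empty")
    if isinstance(bold_runs[0], nib.spatialimages.SpatialImage):
        affine = bold_runs[0].affine

    fir_cols = [
        (i, c) for i, c in enumerate(design.columns) if c.kind == "fir"
    ]
    zero = [c.label() for i, c in fir_cols if not np.any(design.matrix[:, i])]
    if zero:
        raise ValueError("FIR columns with no events: " + ", ".join(zero))

    conditions = tuple(sorted({c.condition for _, c in fir_cols}))
    bins = tuple(sorted({c.time_bin for _, c in fir_cols}))
    flat = np.empty((len(run_ids), len(conditions), len(bins), int(mask_arr.sum())))

    for r_i, (run, img) in enumerate(zip(run_ids, bold_runs)):
        block = design.run_blocks[run]
        col_idx = design.run_columns(run)
        X = design.matrix[block][:, col_idx]
        data = _as_array(img)
        if data.shape[3] != block.stop - block.start:
            raise ValueError(f"run {run}: scan count does not match the design")
        Y = data[mask_arr].T.astype(float)
        if drift is not None and run in drift and drift[run].size:
            basis = drift[run]
            X = X.copy()
            nonconst = [j for j, ci in enumerate(col_idx) if design.columns[ci].kind != "constant"]
            X[:, nonconst] = _residualize(X[:, nonconst], basis)
            Y = _residualize(Y, basis)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"run {run}: design is rank deficient ({rank}/{X.shape[1]}); using pseudoinverse",
                stacklevel=2,
            )
            betas = np.linalg.pinv(X) @ Y
        else:
            betas = np.linalg.lstsq(X, Y, rcond=None)[0]
        for j, ci in enumerate(col_idx):
            info = design.columns[ci]
            if info.kind != "fir":
                continue
            flat[r_i, conditions.index(info.condition), bins.index(info.time_bin)] = betas[j]

    return BetaStack(
        flat=flat,
        runs=tuple(run_ids),
        conditions=conditions,
        bins=bins,
        mask=mask_arr,
        affine=affine,
        tr_s=BIN_S,
    )
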
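"""End-to-end orchestration: simulate -> score -> label -> GLM -> decode ->
cross-regression -> permutation control -> group inference.

One top-level seed fans out into named per-stage, per-subject sub-seeds via
a hash, so any stage can be reproduced in isolation and a rerun with the
same configuration is bit-identical. Every run directory ends with a
manifest of SHA-256 hashes over all written files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as gio
from .behavior import (
    ParticipantStatus,
    TrialScore,
    apply_exclusions,
    downsample_trace,
    filter_and_subsample,
    score_trial,
)
from .config import PipelineConfig
from .crossreg import GenMatrix, temporal_generalization
from .glm import BetaStack, build_fir_design, fit_glm, highpass_dct
from .group import GroupResult, group_inference, period_inference
from .labels import LabelScheme, labels_from_forces
from .periods import PeriodDef
from .permutation import decode_per_class
from .searchlight import AccuracyMap, SearchlightSpec, decode_cells
from .simulate import (
    EffectSpec,
    NoiseSpec,
    Region,
    SimulatedBold,
    TrialSchedule,
    make_trial_schedule,
    simulate_bold,
    simulate_force_traces,
)

logger = logging.getLogger(__name__)

__all__ = [
    "subseed",
    "SubjectData",
    "SubjectAnalysis",
    "simulate_subject",
    "score_subject",
    "analyze_subject",
    "run_pipeline",
    "cluster_table",
]


def subseed(seed: int, name: str) -> int:
    """Derive a named, stable sub-seed below 2^31 from one top-level seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def effect_from_config(cfg: PipelineConfig) -> EffectSpec:
    return EffectSpec(
        regions=tuple(
            Region(
                name=r.name,
                center_voxel=tuple(r.center_voxel),
                radius_voxels=r.radius_voxels,
                active_periods=frozenset(r.active_periods),
                pattern_seed=r.pattern_seed,
                amplitude=r.amplitude,
                shared_pattern_with=r.shared_pattern_with,
                convolve_hrf=r.convolve_hrf,
            )
            for r in cfg.sim.regions
        )
    )


def noise_from_config(cfg: PipelineConfig) -> NoiseSpec:
    s = cfg.sim
    return NoiseSpec(
        sigma=s.sigma,
        ar1_rho=s.ar1_rho,
        drift_amplitude=s.drift_amplitude,
        drift_period_s=s.drift_period_s,
        motion_leak=s.motion_leak,
    )


def periods_from_config(cfg: PipelineConfig) -> tuple[PeriodDef, ...]:
    return tuple(PeriodDef(name, tuple(bins)) for name, bins in cfg.periods.items())


def true_label_scheme(cfg: PipelineConfig) -> LabelScheme:
    """The embedded parametric code: Fechner labels of the level targets."""
    return labels_from_forces([[mu] for mu in cfg.sim.level_mu])


@dataclass
class SubjectData:
    subject_id: str
    schedules: list[TrialSchedule]
    traces: list[list]  # per run
    bold: SimulatedBold


@dataclass
class SubjectAnalysis:
    subject_id: str
    status: ParticipantStatus
    scores: dict[tuple[int, int], list[TrialScore]]
    selected: dict[tuple[int, int], list[int]] | None = None
    labels: LabelScheme | None = None
    betas: BetaStack | None = None
    bin_maps: dict[int, AccuracyMap] | None = None
    gen: GenMatrix | None = None
    perm_maps: dict[int, AccuracyMap] | None = None


def simulate_subject(cfg: PipelineConfig, subject_seed: int, subject_id: str = "") -> SubjectData:
    s = cfg.sim
    schedules = make_trial_schedule(
        s.n_runs, s.n_experimental, s.n_catch, s.tr_s,
        seed=subseed(subject_seed, "schedule"), iti_range_s=s.iti_range_s,
    )
    traces = [
        simulate_force_traces(
            schedule, s.level_mu, s.level_cv, s.p_delay_press, s.sample_rate_hz,
            seed=subseed(subject_seed, f"force:{schedule.run_id}"),
        )
        for schedule in schedules
    ]
    bold = simulate_bold(
        schedules,
        effect_from_config(cfg),
        noise_from_config(cfg),
        labels=true_label_scheme(cfg).labels,
        mask_shape=s.mask_shape,
        seed=subseed(subject_seed, "bold"),
        periods=periods_from_config(cfg),
    )
    return SubjectData(subject_id=subject_id, schedules=schedules, traces=traces, bold=bold)


def score_subject(cfg: PipelineConfig, data: SubjectData):
    """Score all experimental trials; returns (scores, status, forces_by_level)."""
    b = cfg.behav
    scores: dict[tuple[int, int], list[TrialScore]] = {}
    for schedule, run_traces in zip(data.schedules, data.traces):
        by_index = {t.trial_index: t for t in run_traces}
        for trial in schedule.trials:
            if trial.is_catch:
                continue
            trace = downsample_trace(by_index[trial.trial_index], b.downsample_factor)
            score = score_trial(
                trace, trial.condition, eval_window_s=b.eval_window_s, tol=b.tol
            )
            scores.setdefault((schedule.run_id, trial.condition), []).append(score)
    status = apply_exclusions(scores, b.acc_floor, b.press_ceiling)
    forces_by_level = [
        [
            s.applied_force
            for (_, c), cell in scores.items()
            if c == level
            for s in cell
            if s.accurate and not s.delay_press_flag
        ]
        for level in (1, 2, 3, 4)
    ]
    return scores, status, forces_by_level


def analyze_subject(cfg: PipelineConfig, data: SubjectData) -> SubjectAnalysis:
    scores, status, forces_by_level = score_subject(cfg, data)
    result = SubjectAnalysis(subject_id=data.subject_id, status=status, scores=scores)
    if not status.included:
        logger.warning("subject %s excluded: %s", data.subject_id, status.reasons)
        return result

    if cfg.glm.condition_field == "noncued_condition":
        # control analysis: trials regrouped by the presented-but-not-cued
        # level (behavioural accuracy is still judged on the cued level)
        regrouped: dict[tuple[int, int], list[TrialScore]] = {}
        for schedule in data.schedules:
            noncued_of = {t.trial_index: t.noncued_condition for t in schedule.trials}
            for (run, _c), cell in scores.items():
                if run != schedule.run_id:
                    continue
                for s in cell:
                    regrouped.setdefault((run, noncued_of[s.trial_index]), []).append(s)
        result.selected = filter_and_subsample(
            regrouped, cfg.behav.n_keep, require_accurate=cfg.behav.require_accurate
        )
    else:
        result.selected = filter_and_subsample(
            scores, cfg.behav.n_keep, require_accurate=cfg.behav.require_accurate
        )
    expected = {(s.run_id, c) for s in data.schedules for c in (1, 2, 3, 4)}
    missing = expected - set(result.selected)
    if missing:
        raise ValueError(f"no candidate trials at all for cells {sorted(missing)}")
    result.labels = labels_from_forces(
        forces_by_level, cfg.labels.anchor_mode, cfg.labels.anchor_value
    )

    motion = {s.run_id: m for s, m in zip(data.schedules, data.bold.motion)}
    design = build_fir_design(
        data.schedules, result.selected, cfg.glm.n_bins, motion,
        condition_field=cfg.glm.condition_field,
    )
    drift = {
        s.run_id: highpass_dct(s.n_scans, s.tr_s, cfg.glm.cutoff_s) for s in data.schedules
    }
    result.betas = fit_glm(data.bold.runs, design, drift, mask=data.bold.mask)

    spec = SearchlightSpec(
        radius_voxels=cfg.decode.radius_voxels,
        min_voxels=cfg.decode.min_voxels,
        C=cfg.decode.C,
        epsilon=cfg.decode.epsilon,
    )
    periods = periods_from_config(cfg)
    if cfg.crossreg_enabled:
        result.gen = temporal_generalization(
            result.betas, result.labels, spec, cfg.decode.scaling, periods,
            subject_id=data.subject_id,
        )
        result.bin_maps = {b: result.gen.bin_cells[(b, b)] for b in result.betas.bins}
    else:
        cells = [((b,), (b,)) for b in result.betas.bins]
        maps = decode_cells(
            result.betas, result.labels, cells, spec, cfg.decode.scaling,
            subject_id=data.subject_id,
        )
        result.bin_maps = {b: m for b, m in zip(result.betas.bins, maps)}

    if cfg.permutation.enabled:
        bins = cfg.permutation.bins
        result.perm_maps = {
            class_id: decode_per_class(
                result.betas, result.labels, spec, class_id,
                train_bins=bins, test_bins=bins,
                n_draws=cfg.permutation.n_draws,
                seed=subseed(cfg.seed, f"perm:{data.subject_id}:{class_id}"),
                scaling=cfg.decode.scaling,
            )
            for class_id in range(5)
        }
    return result


def cluster_table(result: GroupResult) -> pd.DataFrame:
    """Summarise significant voxels as clusters (id, size, peak voxel, peak t)."""
    labelled, n = ndimage.label(result.threshold_mask)
    rows = []
    for cid in range(1, n + 1):
        where = labelled == cid
        t_vals = np.where(where, result.t_map, -np.inf)
        peak = np.unravel_index(np.argmax(t_vals), t_vals.shape)
        rows.append(
            {
                "cluster_id": cid,
                "size": int(where.sum()),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "peak_t": float(result.t_map[peak]),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z", "peak_t"]
    )


def _write_group(out: Path, tag: str, result: GroupResult) -> None:
    import nibabel as nib

    nib.Nifti1Image(result.t_map, result.affine).to_filename(out / f"{tag}_tmap.nii")
    nib.Nifti1Image(result.p_map, result.affine).to_filename(out / f"{tag}_pfwe.nii")
    nib.Nifti1Image(result.threshold_mask.astype(np.uint8), result.affine).to_filename(
        out / f"{tag}_sigmask.nii"
    )
    cluster_table(result).to_csv(out / f"{tag}_clusters.tsv", sep="\t", index=False)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    write_bold: bool = False,
    write_betas: bool = False,
) -> Path:
    """Run the full pipeline for ``cfg.n_subjects`` simulated participants.

    Per-subject artifacts (events, forces, motion, scores, labels, accuracy
    maps) and group-level statistics are written under ``out_dir``; the run
    ends with a manifest hashing every file. Identical configurations
    produce identical manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "config.yaml")
    periods = periods_from_config(cfg)

    included: list[SubjectAnalysis] = []
    for i in range(1, cfg.n_subjects + 1):
        subject_id = f"sub-{i:02d}"
        sdir = out_dir / subject_id
        sdir.mkdir(exist_ok=True)
        data = simulate_subject(cfg, subseed(cfg.seed, f"subject:{i}"), subject_id)
        for schedule, run_traces, motion in zip(data.schedules, data.traces, data.bold.motion):
            gio.write_schedule(sdir / f"run-{schedule.run_id:02d}_events.tsv", schedule)
            gio.write_force_traces(sdir / f"run-{schedule.run_id:02d}_forces.tsv", run_traces)
            gio.write_motion(sdir / f"rp_run-{schedule.run_id:02d}.txt", motion)
        if write_bold:
            for schedule, img in zip(data.schedules, data.bold.runs):
                img.to_filename(sdir / f"run-{schedule.run_id:02d}_bold.nii.gz")
            data.bold.mask.to_filename(sdir / "mask.nii.gz")

        analysis = analyze_subject(cfg, data)
        gio.write_scores(sdir / "scores.tsv", analysis.scores)
        (sdir / "exclusion.json").write_text(
            json.dumps(
                {"included": analysis.status.included, "reasons": list(analysis.status.reasons)},
                indent=1,
            )
        )
        if not analysis.status.included:
            continue
        gio.write_labels(sdir / "labels.json", analysis.labels)
        (sdir / "selected.json").write_text(
            json.dumps({f"{r}:{c}": v for (r, c), v in analysis.selected.items()}, indent=1)
        )
        if write_betas:
            gio.write_beta_stack(sdir / "betas", analysis.betas)
        (sdir / "accmaps").mkdir(exist_ok=True)
        for b, amap in analysis.bin_maps.items():
            gio.write_accuracy_map(sdir / "accmaps" / f"bin-{b:02d}.nii", amap)
        if analysis.gen is not None:
            (sdir / "crossreg").mkdir(exist_ok=True)
            for (p, q), amap in analysis.gen.cells.items():
                gio.write_accuracy_map(sdir / "crossreg" / f"train-{p}_test-{q}.nii", amap)
        if analysis.perm_maps is not None:
            (sdir / "perm").mkdir(exist_ok=True)
            for class_id, amap in analysis.perm_maps.items():
                gio.write_accuracy_map(sdir / "perm" / f"class-{class_id}.nii", amap)
        included.append(analysis)

    if len(included) < 3:
        raise RuntimeError(f"only {len(included)} subjects included; cannot run group stage")

    g = cfg.group
    voxel_mm = 2.5
    gdir = out_dir / "group"
    gdir.mkdir(exist_ok=True)
    period_results = period_inference(
        [a.bin_maps for a in included], periods,
        fwhm_mm=g.fwhm_mm, voxel_mm=voxel_mm, method=g.method, alpha=g.alpha,
        n_perm=g.n_perm, seed=subseed(cfg.seed, "group:periods"),
    )
    for name, result in period_results.items():
        _write_group(gdir, f"period-{name}", result)
    if cfg.crossreg_enabled:
        for p in periods:
            for q in periods:
                maps = [a.gen.cells[(p.name, q.name)] for a in included]
                result = group_inference(
                    maps, g.fwhm_mm, voxel_mm, g.method, g.alpha, g.n_perm,
                    seed=subseed(cfg.seed, f"group:cross:{p.name}:{q.name}"),
                )
                _write_group(gdir, f"cross_train-{p.name}_test-{q.name}", result)

    gio.write_manifest(out_dir)
    return out_dir
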
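"""Reading and writing of pipeline artifacts.

Events are BIDS-style TSV (onset/duration/trial_type plus task columns)
with a JSON sidecar holding run metadata; motion parameters use the
6-column whitespace text dialect of SPM's rp_*.txt files; force traces and
behavioural scores are TSV; label schemes and manifests are JSON;
accuracy/statistic maps and beta stacks are NIfTI with JSON sidecars. Every
writer has a reader that restores the object (floats to full precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import ForceTrace, TrialScore
from .glm import BetaStack, ColumnInfo, FIRDesign
from .labels import LabelScheme
from .searchlight import AccuracyMap
from .simulate import Trial, TrialSchedule

_FLOAT_FMT = "%.17g"


# -- trial schedules ---------------------------------------------------------

def write_schedule(path: str | Path, schedule: TrialSchedule) -> None:
    path = Path(path)
    rows = [
        {
            "onset": t.onset_s,
            "duration": t.duration_s,
            "trial_type": "catch" if t.is_catch else "experimental",
            "condition": t.condition,
            "noncued_condition": t.noncued_condition,
            "is_catch": int(t.is_catch),
            "delay_s": t.delay_s,
            "trial_index": t.trial_index,
            "onset_scan": t.onset_scan,
        }
        for t in schedule.trials
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {"run_id": schedule.run_id, "tr_s": schedule.tr_s, "n_scans": schedule.n_scans}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_schedule(path: str | Path) -> TrialSchedule:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trials = tuple(
        Trial(
            trial_index=int(r.trial_index),
            condition=int(r.condition),
            noncued_condition=int(r.noncued_condition),
            is_catch=bool(r.is_catch),
            delay_s=float(r.delay_s),
            onset_s=float(r.onset),
            onset_scan=int(r.onset_scan),
        )
        for r in df.itertuples()
    )
    return TrialSchedule(
        run_id=int(meta["run_id"]), trials=trials, tr_s=float(meta["tr_s"]),
        n_scans=int(meta["n_scans"]),
    )


# -- force traces ------------------------------------------------------------

def write_force_traces(path: str | Path, traces: Sequence[ForceTrace]) -> None:
    path = Path(path)
    frames = []
    meta = {}
    for trace in traces:
        t_s = np.arange(trace.samples.size) / trace.sample_rate_hz
        frames.append(
            pd.DataFrame(
                {"trial_index": trace.trial_index, "t_s": t_s, "force": trace.samples}
            )
        )
        meta[str(trace.trial_index)] = {
            "sample_rate_hz": trace.sample_rate_hz,
            "delay_start_s": trace.delay_start_s,
            "delay_end_s": trace.delay_end_s,
            "go_onset_s": trace.go_onset_s,
            "response_end_s": trace.response_end_s,
        }
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_force_traces(path: str | Path) -> list[ForceTrace]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    traces = []
    for trial_index, grp in df.groupby("trial_index", sort=True):
        m = meta[str(trial_index)]
        traces.append(
            ForceTrace(
                trial_index=int(trial_index),
                samples=grp["force"].to_numpy(),
                sample_rate_hz=float(m["sample_rate_hz"]),
                delay_start_s=float(m["delay_start_s"]),
                delay_end_s=float(m["delay_end_s"]),
                go_onset_s=float(m["go_onset_s"]),
                response_end_s=float(m["response_end_s"]),
            )
        )
    return traces


# -- motion parameters (SPM rp_*.txt dialect) --------------------------------

def write_motion(path: str | Path, motion: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt=_FLOAT_FMT)


def read_motion(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    return arr


# -- behavioural scores ------------------------------------------------------

def write_scores(path: str | Path, scores: Mapping[tuple[int, int], Sequence[TrialScore]]) -> None:
    rows = []
    for (run, condition), cell in sorted(scores.items()):
        for s in cell:
            rows.append(
                {
                    "run": run,
                    "condition": condition,
                    "trial_index": s.trial_index,
                    "applied_force": s.applied_force,
                    "accurate": int(s.accurate),
                    "delay_mean_force": s.delay_mean_force,
                    "delay_press_flag": int(s.delay_press_flag),
                    "precision": s.precision,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scores(path: str | Path) -> dict[tuple[int, int], list[TrialScore]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[tuple[int, int], list[TrialScore]] = {}
    for r in df.itertuples():
        out.setdefault((int(r.run), int(r.condition)), []).append(
            TrialScore(
                trial_index=int(r.trial_index),
                condition=int(r.condition),
                applied_force=float(r.applied_force),
                accurate=bool(r.accurate),
                delay_mean_force=float(r.delay_mean_force),
                delay_press_flag=bool(r.delay_press_flag),
                precision=float(r.precision),
            )
        )
    return out


# -- label schemes -----------------------------------------------------------

def write_labels(path: str | Path, scheme: LabelScheme) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "labels": list(scheme.labels),
                "distances": list(scheme.distances),
                "anchor": scheme.anchor,
                "anchor_mode": scheme.anchor_mode,
                "mu_log": list(scheme.mu_log) if scheme.mu_log is not None else None,
            },
            indent=1,
        )
    )


def read_labels(path: str | Path) -> LabelScheme:
    d = json.loads(Path(path).read_text())
    return LabelScheme(
        labels=tuple(d["labels"]),
        distances=tuple(d["distances"]),
        anchor=d["anchor"],
        anchor_mode=d["anchor_mode"],
        mu_log=tuple(d["mu_log"]) if d.get("mu_log") is not None else None,
    )


# -- design matrices ---------------------------------------------------------

def write_design(path: str | Path, design: FIRDesign) -> None:
    path = Path(path)
    labels = [c.label() for c in design.columns]
    pd.DataFrame(design.matrix, columns=labels).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    sidecar = {
        "columns": [
            {"run": c.run, "kind": c.kind, "condition": c.condition, "time_bin": c.time_bin}
            for c in design.columns
        ],
        "run_blocks": {str(r): [s.start, s.stop] for r, s in design.run_blocks.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_design(path: str | Path) -> FIRDesign:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    matrix = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy()
    columns = tuple(
        ColumnInfo(run=c["run"], kind=c["kind"], condition=c["condition"], time_bin=c["time_bin"])
        for c in meta["columns"]
    )
    run_blocks = {int(r): slice(a, b) for r, (a, b) in meta["run_blocks"].items()}
    return FIRDesign(matrix=matrix, columns=columns, run_blocks=run_blocks)


# -- accuracy maps and beta stacks -------------------------------------------

def write_accuracy_map(path: str | Path, amap: AccuracyMap) -> None:
    path = Path(path)
    nib.Nifti1Image(amap.values.astype(np.float64), amap.affine).to_filename(path)
    sidecar = {
        "train_bins": list(amap.train_bins),
        "test_bins": list(amap.test_bins),
        "subject_id": amap.subject_id,
    }
    _nifti_sidecar(path).write_text(json.dumps(sidecar, indent=1))


def _nifti_sidecar(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_accuracy_map(path: str | Path) -> AccuracyMap:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(_nifti_sidecar(path).read_text())
    return AccuracyMap(
        values=np.asanyarray(img.dataobj).astype(float),
        train_bins=tuple(meta["train_bins"]),
        test_bins=tuple(meta["test_bins"]),
        subject_id=meta["subject_id"],
        affine=img.affine,
    )


def write_beta_stack(out_dir: str | Path, stack: BetaStack) -> None:
    """One 4D NIfTI per condition (volumes ordered run-major, bin-minor)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c_i, condition in enumerate(stack.conditions):
        vols = np.full((*stack.mask.shape, len(stack.runs) * len(stack.bins)), np.nan)
        v = 0
        for r_i in range(len(stack.runs)):
            for b_i in range(len(stack.bins)):
                vol = np.full(stack.mask.shape, np.nan)
                vol[stack.mask] = stack.flat[r_i, c_i, b_i]
                vols[..., v] = vol
                v += 1
        nib.Nifti1Image(vols, stack.affine).to_filename(out_dir / f"betas_cond-{condition}.nii")
    nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine).to_filename(out_dir / "mask.nii")
    index = {
        "runs": list(stack.runs),
        "conditions": list(stack.conditions),
        "bins": list(stack.bins),
        "tr_s": stack.tr_s,
    }
    (out_dir / "betas.json").write_text(json.dumps(index, indent=1))


def read_beta_stack(out_dir: str | Path) -> BetaStack:
    out_dir = Path(out_dir)
    index = json.loads((out_dir / "betas.json").read_text())
    mask_img = nib.load(str(out_dir / "mask.nii"))
    mask = np.asanyarray(mask_img.dataobj).astype(bool)
    runs, conditions, bins = index["runs"], index["conditions"], index["bins"]
    flat = np.empty((len(runs), len(conditions), len(bins), int(mask.sum())))
    for c_i, condition in enumerate(conditions):
        img = nib.load(str(out_dir / f"betas_cond-{condition}.nii"))
        data = np.asanyarray(img.dataobj)
        v = 0
        for r_i in range(len(runs)):
            for b_i in range(len(bins)):
                flat[r_i, c_i, b_i] = data[..., v][mask]
                v += 1
    return BetaStack(
        flat=flat,
        runs=tuple(runs),
        conditions=tuple(conditions),
        bins=tuple(bins),
        mask=mask,
        affine=mask_img.affine,
        tr_s=float(index["tr_s"]),
    )


# -- manifests ---------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, name: str = "manifest.json") -> Path:
    """Hash every file under ``out_dir`` into a manifest for change detection."""
    out_dir = Path(out_dir)
    entries = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != name:
            entries[str(p.relative_to(out_dir))] = file_sha256(p)
    manifest = out_dir / name
    manifest.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return manifest
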
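"""Time-resolved searchlight support-vector-regression decoding.

For every voxel, the beta patterns of the voxels within a spherical
neighbourhood (default radius 4 voxels) are used to train a linear
epsilon-SVR that predicts the trial's force label, under leave-one-run-out
cross-validation (one fold per run). Decoding accuracy is the Fisher
z-transformed Pearson correlation between predicted and true labels
("zcorr"), computed per fold over the held-out run's samples and averaged
across folds; its chance level is 0. Training a decoder on one set of
time-bins and testing on another yields the cross-regression cells used for
temporal generalization.

The SVR is libsvm's epsilon-SVR with a linear kernel (C = 1, epsilon = 0.1
by default). Searchlight maps need hundreds of thousands of tiny fits, so
fitting goes through scikit-learn's low-level libsvm binding when
available, which bypasses per-call estimator overhead; the result is
identical to ``sklearn.svm.SVR`` (asserted in the test suite), which also
serves as the fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVR

from .glm import BetaStack
from .labels import LabelScheme

try:  # fast path: low-level libsvm binding
    from sklearn.svm import _libsvm as _libsvm_fast

    _libsvm_fast.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _libsvm_fast = None

logger = logging.getLogger(__name__)

__all__ = [
    "SearchlightSpec",
    "AccuracyMap",
    "sphere_offsets",
    "zcorr",
    "decode_map",
    "decode_cells",
]

#: |r| is clipped here before the Fisher transform, bounding zcorr at ~7.25.
R_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class SearchlightSpec:
    radius_voxels: float = 4.0
    include_center: bool = True
    min_voxels: int = 2
    C: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.radius_voxels < 1:
            raise ValueError("searchlight radius must be >= 1 voxel")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


@dataclass(frozen=True)
class AccuracyMap:
    """Voxelwise zcorr for one (train-bins, test-bins) pair."""

    values: np.ndarray
    train_bins: tuple[int, ...]
    test_bins: tuple[int, ...]
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4), repr=False)


def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer voxel offsets with Euclidean norm <= radius, centre included."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_voxels))
    grid = np.stack(
        np.meshgrid(*([np.arange(-r, r + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return grid[(grid**2).sum(axis=1) <= radius_voxels**2]


def zcorr(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Fisher z-transformed Pearson correlation, the decoding accuracy.

    |r| is clipped just below 1 so perfect prediction maps to a finite
    ceiling. A constant prediction has no defined correlation and scores 0
    (with a warning); a constant target is a caller error.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or p.size < 3:
        raise ValueError("need >= 3 prediction/target pairs")
    if np.ptp(a) == 0:
        raise ValueError("target labels are constant; zcorr undefined")
    if np.ptp(p) == 0:
        warnings.warn("constant prediction; zcorr set to 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(p, a)[0, 1])
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def _fit_linear_svr(X: np.ndarray, y: np.ndarray, C: float, epsilon: float):
    """Train a linear epsilon-SVR; returns (weights, intercept)."""
    if _libsvm_fast is not None:
        _support, SV, _nSV, sv_coef, intercept, *_ = _libsvm_fast.fit(
            np.ascontiguousarray(X, dtype=np.float64),
            np.ascontiguousarray(y, dtype=np.float64),
            svm_type=3,
            kernel="linear",
            C=float(C),
            epsilon=float(epsilon),
        )
        return SV.T @ sv_coef.ravel(), float(intercept[0])
    model = SVR(kernel="linear", C=C, epsilon=epsilon).fit(X, y)
    return model.coef_.ravel(), float(model.intercept_[0])


def _sphere_membership(mask: np.ndarray, offsets: np.ndarray, centers: np.ndarray):
    """Per-centre in-mask neighbour ids (index into the mask's voxel list)."""
    vol_index = np.full(mask.shape, -1, dtype=np.int64)
    vol_index[mask] = np.arange(int(mask.sum()))
    coords = np.argwhere(centers)
    neigh = np.full((len(coords), len(offsets)), -1, dtype=np.int64)
    shape = np.asarray(mask.shape)
    for k, off in enumerate(offsets):
        pos = coords + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        neigh[ok, k] = vol_index[tuple(pos[ok].T)]
    return coords, [row[row >= 0] for row in neigh]


def _label_values(labels) -> np.ndarray:
    if isinstance(labels, LabelScheme):
        return np.asarray(labels.labels, dtype=float)
    arr = np.asarray(labels, dtype=float)
    if arr.ndim != 1:
        raise ValueError("labels must be a vector of per-condition targets")
    return arr


def decode_cells(
    betas: BetaStack,
    labels,
    cells: Sequence[tuple[Sequence[int], Sequence[int]]],
    spec: SearchlightSpec = SearchlightSpec(),
    scaling: str = "train_fold",
    centers: np.ndarray | None = None,
    subject_id: str = "",
) -> list[AccuracyMap]:
    """Searchlight decoding for several (train-bins, test-bins) cells at once.

    Cells sharing a train-bin set reuse the same trained decoders, which is
    what makes the full temporal-generalization grid affordable; per-cell
    results are identical to calling :func:`decode_map` separately.
    ``scaling='train_fold'`` z-scales each voxel with statistics estimated
    on the training folds only (leakage-safe default); ``'all'`` uses all
    samples of the beta stack, matching the scaling described for the
    original toolbox. ``centers`` optionally restricts the computed centre
    voxels (e.g., to a peak of interest).
    """
    if scaling not in ("train_fold", "all"):
        raise ValueError("scaling must be 'train_fold' or 'all'")
    lab = _label_values(labels)
    R, C, B, V = betas.flat.shape
    if R < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    if len(lab) != C:
        raise ValueError("one label per condition required")
    if np.ptp(lab) == 0:
        raise ValueError("labels are constant; decoding target undefined")
    bin_pos = {b: i for i, b in enumerate(betas.bins)}
    norm_cells = []
    for train_bins, test_bins in cells:
        t = tuple(sorted(int(b) for b in train_bins))
        s = tuple(sorted(int(b) for b in test_bins))
        missing = [b for b in t + s if b not in bin_pos]
        if missing:
            raise ValueError(f"time-bins {missing} absent from the beta stack")
        if not t or not s:
            raise ValueError("train and test bin sets must be non-empty")
        norm_cells.append((t, s))

    offsets = sphere_offsets(spec.radius_voxels)
    if not spec.include_center:
        offsets = offsets[np.any(offsets != 0, axis=1)]
    if centers is None:
        centers_mask = betas.mask
    else:
        centers_mask = np.asarray(centers, dtype=bool)
        if centers_mask.shape != betas.mask.shape or np.any(centers_mask & ~betas.mask):
            raise ValueError("centers must be a subset of the beta-stack mask")
    coords, members = _sphere_membership(betas.mask, offsets, centers_mask)
    n_centers = len(coords)
    usable = np.array([m.size >= spec.min_voxels for m in members])
    n_small = int((~usable).sum())
    if n_small:
        logger.info("%d searchlight centres below min_voxels=%d -> NaN", n_small, spec.min_voxels)

    flat = betas.flat
    if scaling == "all":
        allX = flat.reshape(R * C * B, V)
        g_mean = allX.mean(axis=0)
        g_sd = allX.std(axis=0)
        g_sd[g_sd == 0] = 1.0

    groups: dict[tuple[int, ...], list[int]] = {}
    for i, (t, _s) in enumerate(norm_cells):
        groups.setdefault(t, []).append(i)

    zsum = np.zeros((len(norm_cells), n_centers))
    n_const = 0
    for fold in range(R):
        train_runs = [r for r in range(R) if r != fold]
        for train_bins, cell_ids in groups.items():
            tb = [bin_pos[b] for b in train_bins]
            Xtr = flat[train_runs][:, :, tb].reshape(-1, V)
            ytr = np.tile(np.repeat(lab, len(tb)), len(train_runs))
            if scaling == "train_fold":
                m = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
            else:
                m, sd = g_mean, g_sd
            Xtr = (Xtr - m) / sd
            # One stacked test matrix per train group, segmented by cells
            # with equal test-sample counts, so each centre needs a single
            # prediction matmul and one vectorised correlation per segment.
            by_len: dict[int, list[int]] = {}
            for ci in cell_ids:
                by_len.setdefault(len(norm_cells[ci][1]) * C, []).append(ci)
            te_blocks = []
            segments = []
            row = 0
            for n_te, cids in by_len.items():
                A = np.empty((len(cids), n_te))
                for k, ci in enumerate(cids):
                    sb = [bin_pos[b] for b in norm_cells[ci][1]]
                    te_blocks.append(flat[fold][:, sb].reshape(-1, V))
                    A[k] = np.repeat(lab, len(sb))
                A_c = A - A.mean(axis=1, keepdims=True)
                a_ss = (A_c**2).sum(axis=1)
                segments.append(
                    (np.asarray(cids), slice(row, row + len(cids) * n_te), n_te, A_c, a_ss)
                )
                row += len(cids) * n_te
            Xte_all = (np.concatenate(te_blocks, axis=0) - m) / sd
            for j in range(n_centers):
                if not usable[j]:
                    continue
                idx = members[j]
                w, b = _fit_linear_svr(Xtr[:, idx], ytr, spec.C, spec.epsilon)
                pred_all = Xte_all[:, idx] @ w + b
                for cids, rows, n_te, A_c, a_ss in segments:
                    P = pred_all[rows].reshape(len(cids), n_te)
                    P_c = P - P.mean(axis=1, keepdims=True)
                    p_ss = (P_c**2).sum(axis=1)
                    den = np.sqrt(p_ss * a_ss)
                    num = (P_c * A_c).sum(axis=1)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
                    n_const += int((den == 0).sum())
                    zsum[cids, j] += np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    if n_const:
        logger.info("%d constant-prediction folds scored as zcorr = 0", n_const)

    values = zsum / R
    values[:, ~usable] = np.nan
    maps = []
    for ci, (t, s) in enumerate(norm_cells):
        vol = np.full(betas.mask.shape, np.nan)
        vol[tuple(coords.T)] = values[ci]
        maps.append(
            AccuracyMap(
                values=vol,
                train_bins=t,
                test_bins=s,
                subject_id=subject_id,
                affine=betas.affine,
            )
        )
    return maps


def decode_map(
    betas: BetaStack,
    labels,
    train_bins: Sequence[int],
    test_bins: Sequence[int],
    spec: SearchlightSpec = SearchlightSpec(),
    scaling: str = "train_fold",
    centers: np.ndarray | None = None,
    subject_id: str = "",
) -> AccuracyMap:
    """Searchlight accuracy map for one (train-bins, test-bins) pair.

    With ``train_bins == test_bins`` this is the main time-resolved
    analysis; otherwise it is one cross-regression cell.
    """
    return decode_cells(
        betas, labels, [(train_bins, test_bins)], spec, scaling, centers, subject_id
    )[0]
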
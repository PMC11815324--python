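"""Group-level inference on accuracy maps with voxel-level FWE control.

Subject accuracy maps (already in Fisher-z units, chance = 0) are optionally
smoothed, averaged within trial periods, and tested voxelwise against
chance with a one-sample t-test. Family-wise error across voxels is
controlled either by Bonferroni or by a sign-flipping max-statistic
permutation test: under the null the subject maps are symmetric about
chance, so randomly flipping each subject's sign yields the exact null
distribution of the maximum t over the mask, from which adjusted p-values
follow. Tests are one-sided (above-chance decoding).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .periods import DEFAULT_PERIODS, PeriodDef
from .searchlight import AccuracyMap

__all__ = [
    "GroupResult",
    "smooth_map",
    "one_sample_t",
    "fwe_correct",
    "period_inference",
    "group_inference",
]


@dataclass(frozen=True)
class GroupResult:
    t_map: np.ndarray
    p_map: np.ndarray
    threshold_mask: np.ndarray
    df: int
    method: str
    alpha: float = 0.05
    affine: np.ndarray = field(default_factory=lambda: np.eye(4), repr=False)


def smooth_map(values: np.ndarray, fwhm_mm: float, voxel_mm: float = 2.5) -> np.ndarray:
    """NaN-aware Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)).

    Values are smoothed within the finite-valued region and renormalized by
    the smoothed indicator, so mass is conserved away from edges; the NaN
    pattern is preserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_mm
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(finite.astype(float), sigma)
    out = np.full_like(values, np.nan, dtype=float)
    good = finite & (den > 1e-12)
    out[good] = num[good] / den[good]
    return out


def _stack(maps: Sequence) -> np.ndarray:
    arrs = [m.values if isinstance(m, AccuracyMap) else np.asarray(m, dtype=float) for m in maps]
    return np.stack(arrs)


def one_sample_t(maps: Sequence, chance: float = 0.0) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t against chance; returns (t_map, df).

    Voxels with fewer than 3 finite subject values are NaN. A zero
    between-subject SD yields +/-inf (warned) rather than an error.
    """
    data = _stack(maps) - chance
    n_sub = data.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    n_valid = np.isfinite(data).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(data, axis=0)
        sd = np.nanstd(data, axis=0, ddof=1)
    t = np.full(mean.shape, np.nan)
    ok = n_valid >= 3
    zero_sd = ok & (sd == 0)
    if np.any(zero_sd & (mean != 0)):
        warnings.warn("zero between-subject SD at some voxels; t set to +/-inf", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_valid[ok]))
    t[zero_sd & (mean == 0)] = 0.0
    return t, n_sub - 1


def _t_stat(data: np.ndarray) -> np.ndarray:
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / math.sqrt(data.shape[0]))


def fwe_correct(
    t_map: np.ndarray,
    subject_maps: Sequence,
    method: str = "sign_flip_maxT",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    chance: float = 0.0,
) -> GroupResult:
    """Voxel-level FWE-adjusted p-values for above-chance decoding.

    ``bonferroni`` multiplies the one-sided uncorrected p by the number of
    in-mask voxels; ``sign_flip_maxT`` compares each observed t with the
    permutation distribution of the maximum t under random sign flips of
    the subject maps (exhaustive when n_perm >= 2^n_subjects, else sampled
    with ``seed``).
    """
    if method not in ("bonferroni", "sign_flip_maxT"):
        raise ValueError(f"unknown FWE method {method!r}")
    data = _stack(subject_maps) - chance
    n_sub = data.shape[0]
    df = n_sub - 1
    mask = np.isfinite(t_map)
    n_vox = int(mask.sum())
    p_map = np.full(t_map.shape, np.nan)
    if method == "bonferroni":
        p_unc = stats.t.sf(t_map[mask], df)
        p_map[mask] = np.minimum(1.0, p_unc * n_vox)
    else:
        flat = np.nan_to_num(data[:, mask].reshape(n_sub, n_vox))
        t_obs = t_map[mask]
        n_exhaustive = 2**n_sub
        if n_perm >= n_exhaustive:
            warnings.warn(
                f"n_perm={n_perm} >= 2^{n_sub}; using all {n_exhaustive} sign patterns",
                stacklevel=2,
            )
            signs = np.array(list(product((1.0, -1.0), repeat=n_sub)))
            max_null = np.empty(len(signs))
            for i, s in enumerate(signs):
                max_null[i] = np.nanmax(_t_stat(flat * s[:, None]))
            p_adj = np.array([(max_null >= t).mean() for t in t_obs])
        else:
            rng = np.random.default_rng(seed)
            max_null = np.empty(n_perm)
            for i in range(n_perm):
                s = rng.choice((1.0, -1.0), size=n_sub)
                max_null[i] = np.nanmax(_t_stat(flat * s[:, None]))
            p_adj = np.array([(1 + (max_null >= t).sum()) / (n_perm + 1) for t in t_obs])
        p_map[mask] = p_adj
    threshold = np.zeros(t_map.shape, dtype=bool)
    threshold[mask] = p_map[mask] <= alpha
    return GroupResult(
        t_map=t_map, p_map=p_map, threshold_mask=threshold, df=df, method=method, alpha=alpha
    )


def group_inference(
    subject_maps: Sequence,
    fwhm_mm: float = 8.0,
    voxel_mm: float = 2.5,
    method: str = "sign_flip_maxT",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    chance: float = 0.0,
) -> GroupResult:
    """Smooth subject maps, then one-sample t + voxel-level FWE correction."""
    smoothed = [smooth_map(m.values if isinstance(m, AccuracyMap) else m, fwhm_mm, voxel_mm)
                for m in subject_maps]
    t_map, _df = one_sample_t(smoothed, chance=chance)
    return fwe_correct(t_map, smoothed, method, alpha, n_perm, seed, chance)


def period_inference(
    subject_bin_maps: Sequence[Mapping[int, AccuracyMap]],
    periods: Sequence[PeriodDef] = DEFAULT_PERIODS,
    fwhm_mm: float = 8.0,
    voxel_mm: float = 2.5,
    method: str = "sign_flip_maxT",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    chance: float = 0.0,
) -> dict[str, GroupResult]:
    """Period-level group tests from per-subject, per-bin accuracy maps.

    For each subject, bin maps are averaged within each period; the period
    maps then go through smoothing, the one-sample t-test and FWE
    correction. The same path applies to cross-regression cells via
    :func:`group_inference`.
    """
    results: dict[str, GroupResult] = {}
    for period in periods:
        per_subject = []
        for bin_maps in subject_bin_maps:
            missing = [b for b in period.bins if b not in bin_maps]
            if missing:
                raise ValueError(f"period {period.name}: bins {missing} missing for a subject")
            stack = np.stack([
                bin_maps[b].values if isinstance(bin_maps[b], AccuracyMap) else bin_maps[b]
                for b in period.bins
            ])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_subject.append(np.nanmean(stack, axis=0))
        results[period.name] = group_inference(
            per_subject, fwhm_mm, voxel_mm, method, alpha, n_perm, seed, chance
        )
    return results
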
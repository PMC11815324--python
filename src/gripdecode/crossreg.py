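"""Temporal generalization by cross-regression decoding.

Decoders trained on each time-bin are tested on every time-bin (12 x 12 =
144 cells under the same leave-one-run-out folds as the main analysis), and
the bin-level accuracy maps are averaged into the 4 x 4 grid of trial
periods (cue, early delay, late delay, motor execution -> 16 maps). An
above-chance off-diagonal cell means the multivoxel code generalizes
between the two periods, i.e., the representation is stable over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .glm import BetaStack
from .periods import DEFAULT_PERIODS, PeriodDef, periods_by_name
from .searchlight import AccuracyMap, SearchlightSpec, decode_cells

__all__ = ["GenMatrix", "cross_decode_all", "average_periods", "temporal_generalization"]


@dataclass(frozen=True)
class GenMatrix:
    """Bin-level (12 x 12) and period-level (4 x 4) generalization maps."""

    bin_cells: dict[tuple[int, int], AccuracyMap]
    cells: dict[tuple[str, str], AccuracyMap]


def cross_decode_all(
    betas: BetaStack,
    labels,
    spec: SearchlightSpec = SearchlightSpec(),
    scaling: str = "train_fold",
    bins: Sequence[int] | None = None,
    centers: np.ndarray | None = None,
    subject_id: str = "",
) -> dict[tuple[int, int], AccuracyMap]:
    """All ordered (train-bin, test-bin) accuracy maps.

    Cell (i, j) equals ``decode_map(train_bins={i}, test_bins={j})``; the
    diagonal therefore reproduces the main time-resolved analysis exactly.
    """
    use_bins = tuple(betas.bins) if bins is None else tuple(bins)
    cells = [((i,), (j,)) for i in use_bins for j in use_bins]
    maps = decode_cells(betas, labels, cells, spec, scaling, centers, subject_id)
    return {
        (t[0], s[0]): m for (t, s), m in zip(cells, maps)
    }


def average_periods(
    bin_cells: Mapping[tuple[int, int], AccuracyMap],
    periods: Sequence[PeriodDef] = DEFAULT_PERIODS,
) -> dict[tuple[str, str], AccuracyMap]:
    """Voxelwise (NaN-aware) mean of bin cells within each period pair."""
    by_name = periods_by_name(periods)
    out: dict[tuple[str, str], AccuracyMap] = {}
    for pname, p in by_name.items():
        for qname, q in by_name.items():
            stack = []
            for i in p.bins:
                for j in q.bins:
                    if (i, j) not in bin_cells:
                        raise ValueError(f"bin cell ({i}, {j}) missing for period ({pname}, {qname})")
                    stack.append(bin_cells[(i, j)].values)
            arr = np.stack(stack)
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(arr, axis=0)
            ref = bin_cells[(p.bins[0], q.bins[0])]
            out[(pname, qname)] = AccuracyMap(
                values=mean,
                train_bins=p.bins,
                test_bins=q.bins,
                subject_id=ref.subject_id,
                affine=ref.affine,
            )
    return out


def temporal_generalization(
    betas: BetaStack,
    labels,
    spec: SearchlightSpec = SearchlightSpec(),
    scaling: str = "train_fold",
    periods: Sequence[PeriodDef] = DEFAULT_PERIODS,
    centers: np.ndarray | None = None,
    subject_id: str = "",
) -> GenMatrix:
    """Full grid: 144 bin-level cells reduced to 16 period-level cells."""
    bin_cells = cross_decode_all(
        betas, labels, spec, scaling, centers=centers, subject_id=subject_id
    )
    return GenMatrix(bin_cells=bin_cells, cells=average_periods(bin_cells, periods))
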
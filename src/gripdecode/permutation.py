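"""Label-permutation specificity control.

If a searchlight truly carries a parametric (ordered) force code, decoding
accuracy should degrade as the SVR labels are shuffled further from the
linear order, reaching chance for a completely unordered labelling. Each of
the 24 orderings of the four levels gets a rank-order distance -- the sum of
absolute differences of adjacent ranks (3 for the linear order, up to 7) --
and the orderings are grouped into five distance classes (0 = ordered,
1..4 = increasingly unordered). Decoding is re-run with the relabelled
targets and averaged within class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np

from .glm import BetaStack
from .labels import LabelScheme
from .searchlight import AccuracyMap, SearchlightSpec, decode_cells

__all__ = ["LabelPermutation", "rank_distance", "enumerate_classes", "decode_per_class"]

IDENTITY = (1, 2, 3, 4)
REVERSAL = (4, 3, 2, 1)
#: Rank distance of the linear order, the minimum attainable.
ORDERED_DISTANCE = 3


@dataclass(frozen=True)
class LabelPermutation:
    perm: tuple[int, int, int, int]
    rank_distance: int
    distance_class: int


def rank_distance(perm: Sequence[int]) -> int:
    """Sum of absolute differences of adjacent ranks of an ordering of 1..4."""
    p = tuple(int(x) for x in perm)
    if sorted(p) != [1, 2, 3, 4]:
        raise ValueError(f"{perm!r} is not a permutation of (1, 2, 3, 4)")
    return int(sum(abs(p[k] - p[k + 1]) for k in range(3)))


def enumerate_classes() -> list[LabelPermutation]:
    """All 24 orderings with their distances and distance classes.

    Class = distance - 3, so the linear order and its reversal form class 0
    and the four non-zero classes are the "permuted" conditions.
    """
    out = []
    for perm in permutations((1, 2, 3, 4)):
        d = rank_distance(perm)
        out.append(LabelPermutation(perm=perm, rank_distance=d, distance_class=d - ORDERED_DISTANCE))
    return out


def decode_per_class(
    betas: BetaStack,
    base_labels: LabelScheme,
    spec: SearchlightSpec,
    class_id: int,
    train_bins: Sequence[int],
    test_bins: Sequence[int],
    n_draws: int | None = None,
    seed: int | None = None,
    scaling: str = "train_fold",
    centers: np.ndarray | None = None,
    exclude_reversal: bool = False,
) -> AccuracyMap:
    """Class-mean accuracy map for one distance class.

    Every permutation in the class (or ``n_draws`` sampled with ``seed``)
    relabels the conditions by composing the base labels with the
    permutation; the identical searchlight analysis is run and the maps are
    averaged. ``exclude_reversal`` drops the reversal from class 0, leaving
    exactly the main analysis.
    """
    members = [p for p in enumerate_classes() if p.distance_class == class_id]
    if exclude_reversal:
        members = [p for p in members if p.perm != REVERSAL]
    if not members:
        raise ValueError(f"distance class {class_id} is empty")
    if n_draws is not None and n_draws < len(members):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(members), size=n_draws, replace=False)
        members = [members[i] for i in sorted(idx)]

    acc = None
    ref = None
    for member in members:
        permuted = base_labels.permuted(member.perm)
        m = decode_cells(
            betas, permuted, [(train_bins, test_bins)], spec, scaling, centers
        )[0]
        acc = m.values if acc is None else acc + m.values
        ref = m
    return AccuracyMap(
        values=acc / len(members),
        train_bins=ref.train_bins,
        test_bins=ref.test_bins,
        subject_id=ref.subject_id,
        affine=ref.affine,
    )
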
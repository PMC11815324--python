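"""Fechner-law adjustment of the SVR target labels.

Perceived grip-force intensity compresses logarithmically with physical
force (Fechner's law), so equally spaced decoding labels would misstate the
perceptual geometry of the four force levels. The adjustment works on the
log-transformed applied forces: with mu_i the mean log applied force of
level i, the label spacing between adjacent levels is d_i = 1 / |mu_i -
mu_{i+1}|, and the four labels are the cumulative sums of the spacings
shifted by an anchoring rule. Decoding accuracy (a correlation) is
invariant to the anchor, which is therefore presentational.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["LabelScheme", "compute_label_distances", "build_labels", "labels_from_forces"]


@dataclass(frozen=True)
class LabelScheme:
    """The four SVR target values and the quantities they derive from."""

    labels: tuple[float, float, float, float]
    distances: tuple[float, float, float]
    anchor: float
    anchor_mode: str
    mu_log: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        d = np.diff(self.labels)
        if np.any(d <= 0):
            raise ValueError("labels must be strictly increasing")
        if not np.allclose(d, self.distances, rtol=0, atol=1e-9):
            raise ValueError("label spacings must equal the distances")

    def value(self, condition: int) -> float:
        return self.labels[condition - 1]

    def permuted(self, perm: Sequence[int]) -> np.ndarray:
        """Condition-to-label map after relabelling by ``perm`` of (1..4)."""
        return np.asarray([self.labels[p - 1] for p in perm])


def compute_label_distances(
    applied_forces_by_level: Sequence[Sequence[float]],
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Mean log applied force per level and the reciprocal-gap spacings.

    Returns ``(mu_log, distances)`` with ``distances[i] = 1 / |mu_log[i] -
    mu_log[i+1]|``: the closer two levels sit in log-force (the harder they
    are to tell apart), the farther apart their SVR labels are placed.
    """
    if len(applied_forces_by_level) != 4:
        raise ValueError("exactly four force levels required")
    mu_log = []
    for level, forces in enumerate(applied_forces_by_level, start=1):
        arr = np.asarray(forces, dtype=float)
        if arr.size == 0:
            raise ValueError(f"level {level}: no applied forces")
        if np.any(arr <= 0):
            raise ValueError(f"level {level}: forces must be strictly positive")
        mu_log.append(float(np.mean(np.log(arr))))
    gaps = np.abs(np.diff(mu_log))
    if np.any(gaps == 0):
        raise ValueError("adjacent level means coincide; label distance undefined")
    return tuple(mu_log), tuple(1.0 / gaps)


def build_labels(
    distances: Sequence[float],
    anchor_mode: str = "zero_mean",
    anchor_value: float = 0.0,
    mu_log: Sequence[float] | None = None,
) -> LabelScheme:
    """Turn three label spacings into the four SVR targets.

    ``anchor_mode='zero_mean'`` centres the label vector; ``'first_at'``
    pins the first label to ``anchor_value``.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape != (3,) or not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("distances must be 3 positive finite values")
    cum = np.concatenate([[0.0], np.cumsum(d)])
    if anchor_mode == "zero_mean":
        shift = -cum.mean()
    elif anchor_mode == "first_at":
        shift = anchor_value
    else:
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    labels = cum + shift
    return LabelScheme(
        labels=tuple(float(v) for v in labels),
        distances=tuple(float(v) for v in d),
        anchor=float(shift),
        anchor_mode=anchor_mode,
        mu_log=tuple(float(v) for v in mu_log) if mu_log is not None else None,
    )


def labels_from_forces(
    applied_forces_by_level: Sequence[Sequence[float]],
    anchor_mode: str = "zero_mean",
    anchor_value: float = 0.0,
) -> LabelScheme:
    """Full Fechner adjustment: log-means -> reciprocal gaps -> labels."""
    mu_log, distances = compute_label_distances(applied_forces_by_level)
    return build_labels(distances, anchor_mode, anchor_value, mu_log=mu_log)
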
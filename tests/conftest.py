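import numpy as np
import pytest

from gripdecode.glm import BetaStack


def build_beta_stack(
    flat: np.ndarray,
    mask_shape=(6, 6, 6),
    n_runs=4,
    n_conditions=4,
    n_bins=12,
) -> BetaStack:
    mask = np.ones(mask_shape, dtype=bool)
    return BetaStack(
        flat=flat,
        runs=tuple(range(1, n_runs + 1)),
        conditions=tuple(range(1, n_conditions + 1)),
        bins=tuple(range(1, n_bins + 1)),
        mask=mask,
        affine=np.diag([2.5, 2.5, 2.5, 1.0]),
        tr_s=1.5,
    )


def embedded_beta_stack(
    mask_shape=(8, 8, 8),
    center=(4, 4, 4),
    radius=2.0,
    active_bins=(3, 4, 5),
    labels=(-1.5, -0.58, 1.36, 4.33),
    amplitude=1.0,
    noise_sd=0.5,
    seed=0,
    n_runs=4,
    n_bins=12,
    pattern_seed=7,
    second=None,
):
    """Beta stack with a label-proportional pattern at given bins.

    ``second`` optionally adds another embedded sphere as a dict with keys
    center/active_bins/pattern_seed (pattern_seed=None shares the first
    region's weights).
    """
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(mask_shape))
    flat = rng.normal(0.0, noise_sd, size=(n_runs, 4, n_bins, n_vox))
    lab = np.asarray(labels, dtype=float)

    def embed(center, active_bins, pattern_seed, weights=None):
        grid = np.indices(mask_shape).reshape(3, -1).T
        d2 = ((grid - np.asarray(center)) ** 2).sum(axis=1)
        ids = np.where(d2 <= radius**2)[0]
        if weights is None:
            w = np.random.default_rng(pattern_seed).standard_normal(len(ids))
            weights = w / w.std()
        for b in active_bins:
            flat[:, :, b - 1, ids] += amplitude * lab[None, :, None] * weights[None, None, :]
        return weights

    w = embed(center, active_bins, pattern_seed)
    if second is not None:
        embed(
            second["center"],
            second["active_bins"],
            second.get("pattern_seed"),
            weights=w if second.get("pattern_seed") is None else None,
        )
    return build_beta_stack(flat, mask_shape, n_runs=n_runs, n_bins=n_bins)


@pytest.fixture(scope="session")
def paper_labels():
    return (-1.5, -0.58, 1.36, 4.33)
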
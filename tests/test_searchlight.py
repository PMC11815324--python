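"""Searchlight SVR decoding: geometry, the zcorr metric, cross-validation
hygiene and signal recovery."""

import numpy as np
import pytest
from sklearn.svm import SVR

from gripdecode.searchlight import (
    R_CLIP,
    SearchlightSpec,
    _fit_linear_svr,
    decode_map,
    sphere_offsets,
    zcorr,
)
from tests.conftest import build_beta_stack, embedded_beta_stack

LABELS = (-1.5, -0.58, 1.36, 4.33)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,expected", [(0, 1), (1, 7)])
    def test_small_radii(self, radius, expected):
        assert len(sphere_offsets(radius)) == expected

    def test_radius_four_against_brute_force(self):
        count = sum(
            1
            for x in range(-4, 5)
            for y in range(-4, 5)
            for z in range(-4, 5)
            if x * x + y * y + z * z <= 16
        )
        offsets = sphere_offsets(4)
        assert len(offsets) == count == 257
        assert (offsets == 0).all(axis=1).any()


class TestZcorr:
    def test_perfect_prediction_hits_clip_ceiling(self):
        assert zcorr([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(np.arctanh(R_CLIP))

    def test_antisymmetry(self):
        assert zcorr([-1, -2, -3, -4], [1, 2, 3, 4]) == pytest.approx(-np.arctanh(R_CLIP))

    def test_hand_computed_example(self):
        # Pearson r of (1,2,3,4) vs (1,2,4,3) is 0.8; atanh(0.8) = 1.0986
        assert zcorr([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(np.arctanh(0.8))
        assert zcorr([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(1.0986, abs=1e-4)

    def test_constant_actual_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zcorr([1, 2, 3], [5, 5, 5])

    def test_constant_prediction_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="constant prediction"):
            assert zcorr([2, 2, 2, 2], [1, 2, 3, 4]) == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            zcorr([1, 2], [1, 2])


class TestSVRBackend:
    def test_fast_path_matches_sklearn_svr(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.normal(size=(12, 40))
            y = rng.normal(size=12)
            w, b = _fit_linear_svr(X, y, C=1.0, epsilon=0.1)
            ref = SVR(kernel="linear", C=1.0, epsilon=0.1).fit(X, y)
            Xt = rng.normal(size=(5, 40))
            np.testing.assert_allclose(Xt @ w + b, ref.predict(Xt), atol=1e-8)


class TestDecode:
    def test_perfect_signal_recovers_at_center_not_far_away(self):
        betas = embedded_beta_stack(noise_sd=0.05, amplitude=2.0, seed=3)
        amap = decode_map(betas, LABELS, (4,), (4,), SearchlightSpec(radius_voxels=2))
        assert amap.values[4, 4, 4] > 2.0
        # voxels whose spheres cannot touch the embedded sphere decode at
        # chance on average (single-voxel zcorr is noisy; test the mean)
        grid = np.indices((8, 8, 8)).reshape(3, -1).T
        far = ((grid - 4) ** 2).sum(axis=1) > (2 + 2) ** 2
        far_vals = amap.values.reshape(-1)[far]
        assert abs(np.nanmean(far_vals)) < 0.15

    def test_null_bins_decode_near_chance(self):
        betas = embedded_beta_stack(noise_sd=0.5, seed=4)
        amap = decode_map(betas, LABELS, (10,), (10,), SearchlightSpec(radius_voxels=2))
        vals = amap.values[np.isfinite(amap.values)]
        assert abs(vals.mean()) < 0.1

    def test_affine_label_shift_leaves_map_identical(self):
        betas = embedded_beta_stack(noise_sd=0.5, seed=5, mask_shape=(6, 6, 6), center=(3, 3, 3))
        spec = SearchlightSpec(radius_voxels=2)
        base = np.asarray(LABELS)
        a = decode_map(betas, base, (4,), (4,), spec)
        b = decode_map(betas, base - base.mean(), (4,), (4,), spec)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_no_leakage_from_held_out_samples(self):
        """Perturbing data seen only as held-out test samples must not
        change any map that does not use those samples."""
        rng = np.random.default_rng(7)
        flat = rng.normal(size=(4, 4, 12, 216))
        betas_a = build_beta_stack(flat.copy())
        flat_b = flat.copy()
        flat_b[0, :, 7] += 5.0  # run 1, bin 8 only
        betas_b = build_beta_stack(flat_b)
        spec = SearchlightSpec(radius_voxels=2)
        map_a = decode_map(betas_a, LABELS, (4,), (4,), spec)
        map_b = decode_map(betas_b, LABELS, (4,), (4,), spec)
        np.testing.assert_array_equal(map_a.values, map_b.values)

    def test_accuracy_decreases_with_noise(self):
        vals = []
        for sd in (0.2, 1.0, 4.0):
            betas = embedded_beta_stack(noise_sd=sd, seed=8, mask_shape=(6, 6, 6), center=(3, 3, 3))
            amap = decode_map(betas, LABELS, (4,), (4,), SearchlightSpec(radius_voxels=2))
            vals.append(amap.values[3, 3, 3])
        assert vals[0] > vals[1] > vals[2]

    def test_centers_restriction(self):
        betas = embedded_beta_stack(noise_sd=0.5, seed=9, mask_shape=(6, 6, 6), center=(3, 3, 3))
        centers = np.zeros((6, 6, 6), dtype=bool)
        centers[3, 3, 3] = True
        amap = decode_map(betas, LABELS, (4,), (4,), SearchlightSpec(radius_voxels=2), centers=centers)
        assert np.isfinite(amap.values[3, 3, 3])
        assert np.isnan(amap.values).sum() == 6**3 - 1

    def test_scaling_modes_both_run(self):
        betas = embedded_beta_stack(noise_sd=0.5, seed=10, mask_shape=(6, 6, 6), center=(3, 3, 3))
        spec = SearchlightSpec(radius_voxels=2)
        a = decode_map(betas, LABELS, (4,), (4,), spec, scaling="train_fold")
        b = decode_map(betas, LABELS, (4,), (4,), spec, scaling="all")
        assert np.isfinite(a.values[3, 3, 3]) and np.isfinite(b.values[3, 3, 3])
        with pytest.raises(ValueError):
            decode_map(betas, LABELS, (4,), (4,), spec, scaling="none")

    def test_guards(self):
        betas = embedded_beta_stack(mask_shape=(6, 6, 6), center=(3, 3, 3))
        spec = SearchlightSpec(radius_voxels=2)
        with pytest.raises(ValueError, match="absent"):
            decode_map(betas, LABELS, (13,), (13,), spec)
        with pytest.raises(ValueError, match="constant"):
            decode_map(betas, (1.0, 1.0, 1.0, 1.0), (4,), (4,), spec)
        bad_centers = np.ones((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError, match="centers"):
            decode_map(betas, LABELS, (4,), (4,), spec, centers=bad_centers)

    def test_min_voxels_yields_nan(self):
        betas = embedded_beta_stack(mask_shape=(6, 6, 6), center=(3, 3, 3))
        spec = SearchlightSpec(radius_voxels=1, min_voxels=7)
        amap = decode_map(betas, LABELS, (4,), (4,), spec)
        # corner voxels have 4-voxel spheres -> NaN; interior 7 -> finite
        assert np.isnan(amap.values[0, 0, 0])
        assert np.isfinite(amap.values[3, 3, 3])
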
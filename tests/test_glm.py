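"""FIR and HRF-convolved first-level models."""

import numpy as np
import pytest

from gripdecode.glm import (
    build_fir_design,
    build_hrf_design,
    fit_glm,
    highpass_dct,
)
from gripdecode.labels import build_labels
from gripdecode.simulate import Trial, TrialSchedule, make_trial_schedule


def _selected_all(schedules):
    sel = {}
    for s in schedules:
        for t in s.experimental_trials():
            sel.setdefault((s.run_id, t.condition), []).append(t.trial_index)
    return sel


def _default_design(seed=1):
    schedules = make_trial_schedule(4, 48, 12, 1.5, seed=seed)
    selected = {
        cell: idx[:5] for cell, idx in _selected_all(schedules).items()
    }
    motion = {s.run_id: np.random.default_rng(s.run_id).normal(size=(s.n_scans, 6))
              for s in schedules}
    return build_fir_design(schedules, selected, 12, motion), schedules, selected, motion


class TestFIRDesign:
    def test_default_layout_has_220_columns(self):
        design, *_ = _default_design()
        assert design.n_columns == 220
        kinds = [c.kind for c in design.columns]
        assert kinds.count("fir") == 4 * 12 * 4
        assert kinds.count("motion") == 6 * 4
        assert kinds.count("constant") == 4

    def test_minimal_design_two_columns(self):
        trial = Trial(0, 1, 2, False, 9.0, 6.0, 4)
        schedule = TrialSchedule(1, (trial,), 1.5, 40)
        design = build_fir_design([schedule], {(1, 1): [0]}, n_bins=1)
        assert design.n_columns == 2
        assert [c.kind for c in design.columns] == ["fir", "constant"]

    def test_indicator_semantics_against_scan_membership(self):
        """Overlapping bin windows set the indicator, never a count."""
        trials = (
            Trial(0, 1, 2, False, 9.0, 6.0, 4),
            Trial(1, 1, 3, False, 9.0, 12.0, 8),  # 4 scans later: bins overlap
        )
        schedule = TrialSchedule(1, trials, 1.5, 48)
        design = build_fir_design([schedule], {(1, 1): [0, 1]}, n_bins=12)
        fir = design.matrix[:, [i for i, c in enumerate(design.columns) if c.kind == "fir"]]
        assert fir.max() == 1.0
        # brute-force oracle: per-scan set membership
        for col_i, info in enumerate(c for c in design.columns if c.kind == "fir"):
            scans = {t.onset_scan + info.time_bin - 1 for t in trials}
            expected = np.zeros(48)
            expected[[s for s in scans if s < 48]] = 1.0
            np.testing.assert_array_equal(fir[:, col_i], expected)

    def test_bins_past_run_end_rejected(self):
        trial = Trial(0, 1, 2, False, 9.0, 6.0, 4)
        schedule = TrialSchedule(1, (trial,), 1.5, 10)
        with pytest.raises(ValueError, match="past the run"):
            build_fir_design([schedule], {(1, 1): [0]}, n_bins=12)

    def test_noncued_condition_field(self):
        schedules = make_trial_schedule(1, 16, 0, 1.5, seed=4)
        sel = {}
        for t in schedules[0].trials:
            sel.setdefault((1, t.noncued_condition), []).append(t.trial_index)
        design = build_fir_design(
            schedules, sel, n_bins=2, condition_field="noncued_condition"
        )
        fir_cols = [c for c in design.columns if c.kind == "fir"]
        by_index = {t.trial_index: t for t in schedules[0].trials}
        for i, info in enumerate(c for c in design.columns if c.kind == "fir"):
            col = design.matrix[:, i]
            for idx in sel.get((1, info.condition), []):
                t = by_index[idx]
                assert t.noncued_condition == info.condition
                assert col[t.onset_scan + info.time_bin - 1] == 1.0


class TestHighpass:
    def test_dct_column_count_745_scans(self):
        basis = highpass_dct(745, 1.5, 128.0)
        assert basis.shape == (745, 17)

    def test_no_columns_at_run_length_cutoff(self):
        assert highpass_dct(100, 1.5, 2 * 100 * 1.5).shape[1] == 0

    def test_slow_sinusoid_mostly_removed(self):
        n, tr = 745, 1.5
        t = np.arange(n) * tr
        y = np.sin(2 * np.pi * t / 256.0)
        basis = highpass_dct(n, tr, 128.0)
        q, _ = np.linalg.qr(basis)
        resid = y - q @ (q.T @ y)
        assert resid.var() < 0.01 * y.var()

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_dct(100, 1.5, 2.0)


class TestFitGLM:
    def test_noiseless_recovery_exact(self):
        design, schedules, *_ = _default_design()
        rng = np.random.default_rng(0)
        true = rng.normal(size=(design.n_columns, 27))
        Y = design.matrix @ true
        runs = []
        start = 0
        for s in schedules:
            block = Y[start : start + s.n_scans]
            runs.append(block.T.reshape(3, 3, 3, s.n_scans))
            start += s.n_scans
        betas = fit_glm(runs, design)
        fir_idx = [i for i, c in enumerate(design.columns) if c.kind == "fir"]
        for j, ci in zip(range(len(fir_idx)), fir_idx):
            info = design.columns[ci]
            r = betas.runs.index(info.run)
            c = betas.conditions.index(info.condition)
            b = betas.bins.index(info.time_bin)
            np.testing.assert_allclose(
                betas.flat[r, c, b], true[ci], atol=1e-8
            )

    def test_runwise_estimation_is_independent(self):
        design, schedules, *_ = _default_design()
        rng = np.random.default_rng(5)
        shape = (3, 3, 3)
        runs = [rng.normal(size=(*shape, s.n_scans)) for s in schedules]
        betas = fit_glm(runs, design)
        runs2 = [r.copy() for r in runs]
        runs2[1] += 10.0 * rng.normal(size=runs2[1].shape)
        betas2 = fit_glm(runs2, design)
        np.testing.assert_array_equal(betas.flat[0], betas2.flat[0])
        assert not np.allclose(betas.flat[1], betas2.flat[1])

    def test_orthogonal_drift_leaves_task_betas_unchanged(self):
        trial = Trial(0, 1, 2, False, 9.0, 6.0, 4)
        schedule = TrialSchedule(1, (trial,), 1.5, 64)
        design = build_fir_design([schedule], {(1, 1): [0]}, n_bins=2)
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(2, 2, 2, 64))
        basis = highpass_dct(64, 1.5, 64 * 1.5)
        # make the drift basis exactly orthogonal to the whole design
        task = design.matrix
        basis = basis - task @ np.linalg.lstsq(task, basis, rcond=None)[0]
        plain = fit_glm([Y], design)
        # residualize the data against the same basis by hand: task betas match
        q, _ = np.linalg.qr(basis)
        Yr = Y.reshape(-1, 64) - (Y.reshape(-1, 64) @ q) @ q.T
        filt = fit_glm([Yr.reshape(2, 2, 2, 64)], design, drift={1: basis})
        np.testing.assert_allclose(plain.flat, filt.flat, atol=1e-10)

    def test_all_zero_fir_column_rejected(self):
        trial = Trial(0, 1, 2, False, 9.0, 6.0, 4)
        schedule = TrialSchedule(1, (trial,), 1.5, 40)
        design = build_fir_design([schedule], {(1, 1): [0], (1, 2): []}, n_bins=1)
        with pytest.raises(ValueError, match="run1_fir_c2_t1"):
            fit_glm([np.zeros((2, 2, 2, 40))], design)

    def test_null_data_betas_mean_zero(self):
        design, schedules, *_ = _default_design()
        rng = np.random.default_rng(9)
        runs = [rng.normal(size=(2, 2, 2, s.n_scans)) for s in schedules]
        betas = fit_glm(runs, design)
        # FIR betas over pure noise: mean across all cells near 0
        assert abs(betas.flat.mean()) < 3 * betas.flat.std() / np.sqrt(betas.flat.size / 8)


class TestHRFDesign:
    def test_column_layout_per_run(self):
        schedules = make_trial_schedule(1, 8, 0, 1.5, seed=2)
        labels = build_labels((1.0, 1.0, 1.0))
        motion = {1: np.zeros((schedules[0].n_scans, 6))}
        design = build_hrf_design(schedules, labels, motion)
        assert design.n_columns == 12  # 3 boxcars + 2 pmods + 6 motion + 1 const
        kinds = [c.kind for c in design.columns]
        assert kinds.count("hrf") == 3 and kinds.count("pmod") == 2

    def test_equal_labels_zero_modulators(self):
        schedules = make_trial_schedule(1, 8, 0, 1.5, seed=2)

        class Flat:
            def value(self, condition):
                return 2.0

        design = build_hrf_design(schedules, Flat())
        pmods = [i for i, c in enumerate(design.columns) if c.kind == "pmod"]
        assert np.allclose(design.matrix[:, pmods], 0.0)

    def test_parametric_execution_signal_loads_on_execution_modulator(self):
        """Signal proportional to label during execution drives the execution
        modulator and leaves the delay modulator near zero."""
        from gripdecode.simulate import EffectSpec, NoiseSpec, Region, simulate_bold

        schedules = make_trial_schedule(4, 16, 0, 1.5, seed=8)
        labels = build_labels((0.92, 1.94, 2.97), "first_at", -1.5)
        region = Region("m1", (4, 4, 4), 2.0, frozenset({"ME"}), 3, 1.0)
        noise = NoiseSpec(sigma=0.2, ar1_rho=0.0, drift_amplitude=0.0, motion_leak=0.0)
        sim = simulate_bold(
            schedules, EffectSpec((region,)), noise, labels.labels, (8, 8, 8), seed=1
        )
        design = build_hrf_design(schedules, labels)
        betas_exec, betas_delay = [], []
        for run_i, (s, img) in enumerate(zip(schedules, sim.runs)):
            cols = design.run_columns(s.run_id)
            X = design.matrix[design.run_blocks[s.run_id]][:, cols]
            data = np.asanyarray(img.dataobj)
            Y = data.reshape(-1, s.n_scans).T
            B = np.linalg.lstsq(X, Y, rcond=None)[0]
            names = [design.columns[c] for c in cols]
            i_exec = next(i for i, n in enumerate(names) if n.kind == "pmod" and n.condition == "execution")
            i_delay = next(i for i, n in enumerate(names) if n.kind == "pmod" and n.condition == "delay")
            w = np.random.default_rng(3).standard_normal(33)
            w = w / w.std()
            from gripdecode.simulate import _sphere_voxels

            ids = np.ravel_multi_index(_sphere_voxels((4, 4, 4), 2.0, (8, 8, 8), "m1").T, (8, 8, 8))
            betas_exec.append((B[i_exec, ids] * w).mean())
            betas_delay.append((B[i_delay, ids] * w).mean())
        assert np.mean(betas_exec) > 5 * abs(np.mean(betas_delay))
        assert np.mean(betas_exec) > 0
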
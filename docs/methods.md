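# Methods

## Task model and timing

A trial is cue (3 s), delay (9 s experimental; 6/4.5/3/1.5 s for catch
trials), pre-Go (0.5 s), response window (1.5 s) and feedback (1.5 s).
Onsets are locked to volume acquisition (TR = 1.5 s), so the 12 modelled
1.5-s time-bins coincide with scans; the FIR window starts at cue onset
(2 cue bins, 6 delay bins, 4 execution bins). Inter-trial intervals are
jittered uniformly over TR multiples in 3–6 s; the per-run scan count is
derived from the schedule plus a tail, landing near 800 volumes for the
default 48 + 12-trial runs. Each of the four cued levels appears 12× per
run and, when trial counts divide evenly, every unordered (cued, non-cued)
level pair appears equally often. Catch trials are scheduled for realism
but carry no embedded signal and are never modelled or analysed.

## Synthetic data generator

**Forces.** Applied force is drawn log-normally around the level target
(defaults 0.12 / 0.37 / 0.62 / 0.87 of maximum grip force) with a shared
log-SD of sqrt(log(1 + cv²)), cv = 0.10. This multiplicative (Weber)
structure makes high levels harder given the constant-width target windows
and motivates the Fechner label adjustment. Traces are near-zero baseline
jitter outside press windows; plateau values are clipped at the device
maximum of 1. Delay presses are injected with a configurable probability
(default 0.02) as sustained presses whose mean exceeds the 0.05 flag
cutoff.

**BOLD.** Per-voxel signal is amplitude × pattern-weight × trial label,
active during a region's periods. Two embedding modes exist per region:

- `convolve_hrf=True` (default): the neural boxcar is convolved with the
  canonical double-gamma HRF (kernel normalized so a sustained unit input
  settles at 1). Physiologically faithful: the decodable BOLD code lags
  the neural period by several seconds.
- `convolve_hrf=False`: the pattern is written into the signal exactly at
  the period's scans. This gives bin-exact ground truth and is what the
  recovery tests use, because it makes "which bins carry the code" an
  unambiguous property of the construction.

Noise is AR(1) Gaussian (stationary SD `sigma`, default 1; lag-1
correlation 0.3), a sinusoidal drift with voxel-wise random phase
(amplitude 1, period 200 s), and a random-walk 6-parameter motion table
leaking into the data through per-voxel coefficients (leak 0.1). Voxels
are 2.5 mm isotropic. The generator does **not** emulate spatial
autocorrelation of real BOLD noise, susceptibility or motion artifacts,
physiological noise spectra, or between-subject anatomical variability —
all subjects share one grid, which is why spatial normalization is an
identity here. Passing tests therefore demonstrate correctness of the
pipeline's statistics and bookkeeping, not performance on real scanner
data, whose SNR is far lower than the default synthetic effects.

## Estimation choices

- **High-pass**: SPM-convention discrete-cosine basis keeping components
  with period > 128 s; data and design are projected run-wise. OLS without
  prewhitening — betas are used as patterns, not inferential statistics.
- **Rank deficiency** falls back to the pseudoinverse with a warning;
  an all-zero FIR column (a condition with no events) is an error naming
  the column.
- **Co-estimation leak.** Because only the 5 selected trials per
  run × condition are modelled while all trials generate signal, and the
  drift basis absorbs slow label fluctuations, inactive-bin betas acquire
  a small negative image of the active-bin code (~10% of its amplitude in
  the bin-locked construction). This is a property of the subsampled-FIR
  method itself, visible here because synthetic SNR is high; recovery
  tests only assert positives where the construction puts signal and
  nulls where the one-sided test is safely below threshold.
- **z-scaling** of beta samples is per voxel; default statistics come from
  the training folds only (`train_fold`), which is leakage-safe. The
  `all` mode scales once across all samples of the stack, matching the
  description of the original decoding toolbox.
- **SVR**: libsvm ε-SVR, linear kernel, C = 1, ε = 0.1. Searchlight maps
  need ~10⁵–10⁶ tiny fits, so fitting goes through scikit-learn's
  low-level libsvm binding (30× less per-call overhead); the test suite
  asserts its predictions equal `sklearn.svm.SVR` to 1e-8. zcorr clips
  |r| at 1 − 1e-6 (ceiling ≈ 7.25); a constant prediction scores 0; a
  constant target is an error. Fold zcorr values are averaged across the
  four leave-one-run-out folds (a pooled-predictions variant was
  considered and rejected to keep fold independence explicit).
- **Sphere membership** is Euclidean distance ≤ r in voxel units; centres
  whose in-mask sphere falls below `min_voxels` (default 2) are NaN.
- **Period averaging** is the NaN-aware voxelwise mean of bin-level maps
  (not re-decoding pooled samples), so the period diagonal equals the
  period-averaged main analysis by construction. Bin 12 belongs to no
  default period.
- **Permutation classes.** Rank distance is computed on the permuted
  sequence itself, so the descending order lands in class 0 with the
  identity. A descending relabelling still decodes positively (it is
  monotone; with Fechner spacings imperfectly so), which is why the
  "ordered" reference in recovery tests uses the identity alone
  (`exclude_reversal`). The group-level summary over classes is a linear
  trend in class index, implemented as per-class means.
- **Group stage.** Smoothing is NaN-aware Gaussian
  (σ = FWHM/(2√(2 ln 2))/voxel, default 8 mm at 2.5 mm voxels, applied
  uniformly and configurable to 0). Inference is a one-sided one-sample
  t-test against chance 0 with voxel-level FWE by Bonferroni or
  sign-flipping max-statistic permutation (exact under symmetry; flips
  enumerated exhaustively when n_perm ≥ 2^n_subjects, warned). This
  replaces random-field-theory correction, whose smoothness-estimation
  machinery is out of scope; permutation FWE is exact under
  exchangeability rather than asymptotic.
- **Label anchoring.** The reciprocal-gap spacings fix only differences;
  the default anchor is zero-mean (decoding accuracy is shift-invariant,
  verified numerically to 1e-10), with a `first_at` mode that reproduces
  a conventional printed vector such as (−1.5, −0.58, 1.36, 4.33) from
  spacings (0.92, 1.94, 2.97). Label means are computed per participant.
- **Non-cued control.** The control design models the presented-but-not-
  cued level: candidate trials (accurate, no delay press, judged on cued
  performance) are regrouped by non-cued level before subsampling.
- **Determinism.** One top-level seed fans out to named per-stage,
  per-subject sub-seeds via SHA-256; reruns are bit-identical and every
  run directory carries a SHA-256 manifest of its files.

## Problem sizes in the test suite

Tests exercise the full method at reduced geometry so the suite stays in
the minutes range on one CPU: signal recovery uses a 16×10×10 voxel box
with two radius-2 regions and 22 simulated subjects; null calibration uses
20 repetitions of 6 subjects on 7³; the permutation-distance control uses
20 single-subject simulations on 9³ decoded at the embedded peak. The
package defaults (24³ mask, 22 subjects, full 144-cell grid) run the same
code at larger sizes.

## Known limitations

- The HRF-convolved embedding and the FIR read-out mean that "period"
  labels on bin-level results are BOLD-time, not neural-time; claims about
  neural timing require deconvolution logic that is out of scope.
- No AR(1) prewhitening, no slice-timing correction, no cluster-extent
  inference, no anatomical labelling.
- The degree↔force mapping of the original cue display is internally
  inconsistent between levels; the simulator works in force units and
  leaves any degree mapping to configuration.
- Exclusion thresholds act on proportions within run × condition cells;
  cells must be non-empty, and the subsampler raises (naming the cell)
  when fewer candidates than `n_keep` survive filtering — a real risk of
  the design that callers should handle.
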
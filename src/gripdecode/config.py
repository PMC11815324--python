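"""Pipeline configuration with paper-conventional defaults.

Every tunable of the pipeline lives here: acquisition constants (TR 1.5 s,
2.5 mm voxels), schedule layout (4 runs x 48 experimental + 12 catch
trials), behavioural thresholds (accuracy floor 25%, delay-press ceiling
75%, +/-5% force tolerance), trial subsampling (5 most precise per cell),
GLM settings (12 FIR bins, 128-s high-pass), searchlight radius (4 voxels),
period definitions, and group-level smoothing (8 mm FWHM) and alpha (0.05).
Configs round-trip through YAML and reject unknown keys.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class RegionConfig(_Model):
    name: str
    center_voxel: tuple[int, int, int]
    radius_voxels: float = 2.0
    active_periods: tuple[str, ...]
    pattern_seed: int = 0
    amplitude: float = 0.8
    shared_pattern_with: str | None = None
    convolve_hrf: bool = True


class SimConfig(_Model):
    n_runs: int = 4
    n_experimental: int = 48
    n_catch: int = 12
    tr_s: float = 1.5
    iti_range_s: tuple[float, float] = (3.0, 6.0)
    mask_shape: tuple[int, int, int] = (24, 24, 24)
    level_mu: tuple[float, float, float, float] = (0.12, 0.37, 0.62, 0.87)
    level_cv: float = 0.10
    p_delay_press: float = 0.02
    sample_rate_hz: float = 200.0
    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    drift_period_s: float = 200.0
    motion_leak: float = 0.1
    regions: tuple[RegionConfig, ...] = (
        RegionConfig(
            name="early_code",
            center_voxel=(6, 12, 12),
            active_periods=("ED",),
            pattern_seed=11,
        ),
        RegionConfig(
            name="late_code",
            center_voxel=(17, 12, 12),
            active_periods=("LD", "ME"),
            pattern_seed=12,
        ),
    )


class BehavConfig(_Model):
    n_keep: int = 5
    acc_floor: float = 0.25
    press_ceiling: float = 0.75
    tol: float = 0.05
    eval_window_s: float = 0.75
    downsample_factor: int = 3
    require_accurate: bool = True


class LabelConfig(_Model):
    anchor_mode: str = "zero_mean"
    anchor_value: float = 0.0


class GlmConfig(_Model):
    n_bins: int = 12
    cutoff_s: float = 128.0
    condition_field: str = "condition"


class DecodeConfig(_Model):
    radius_voxels: float = 4.0
    min_voxels: int = 2
    C: float = 1.0
    epsilon: float = 0.1
    scaling: str = "train_fold"


class PermutationConfig(_Model):
    enabled: bool = True
    bins: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    n_draws: int | None = None


class GroupConfig(_Model):
    fwhm_mm: float = 8.0
    alpha: float = 0.05
    method: str = "sign_flip_maxT"
    n_perm: int = 1000


class PipelineConfig(_Model):
    n_subjects: int = 22
    seed: int = 0
    sim: SimConfig = SimConfig()
    behav: BehavConfig = BehavConfig()
    labels: LabelConfig = LabelConfig()
    glm: GlmConfig = GlmConfig()
    decode: DecodeConfig = DecodeConfig()
    periods: dict[str, tuple[int, ...]] = {
        "C": (1, 2),
        "ED": (3, 4, 5),
        "LD": (6, 7, 8),
        "ME": (9, 10, 11),
    }
    permutation: PermutationConfig = PermutationConfig()
    group: GroupConfig = GroupConfig()
    crossreg_enabled: bool = True

    @field_validator("n_subjects")
    @classmethod
    def _at_least_three(cls, v: int) -> int:
        if v < 3:
            raise ValueError("group inference needs at least 3 subjects")
        return v

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))
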
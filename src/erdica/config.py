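"""Pipeline configuration: every tunable in one dataclass, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults.

    Defaults describe the reference study conditions: 8 subjects, 7
    exercises x 2 efforts x 20 repetitions at 512 Hz on a 64-channel
    synthetic montage, 2 mixture-ICA models on 16 PCA dimensions, 220
    log-spaced frequencies from 3 to 150 Hz, 200-draw bootstrap masks at
    alpha = 0.05, and 10-fold cross-validated decoding.
    """

    # study / simulation
    n_subjects: int = 8
    reps: int = 20
    n_channels: int = 64
    fs: float = 512.0
    fs_aux: float = 1000.0
    regime_shift_mm: float = 15.0
    sensor_noise_uv: float = 1.0
    line_amp_uv: float = 0.5
    drift_step_uv: float = 0.01

    # head model
    head_radius_mm: float = 85.0
    conductivity: float = 0.33
    brain_radius_fraction: float = 0.95

    # preprocessing
    highpass_hz: float = 1.0
    std_limit_uv: float = 1000.0
    kurtosis_sd: float = 3.0
    corr_threshold: float = 0.4
    corr_window_s: float = 1.0
    corr_max_fraction: float = 0.001

    # mixture ICA
    n_models: int = 2
    n_components: int = 16
    ica_max_iter: int = 250
    ica_tol: float = 1e-6
    ica_fit_samples: int = 100_000

    # source space
    rv_limit: float = 0.15
    cluster_k: int = 10
    cluster_location_weight: float = 3.0

    # spectrograms
    n_freq_bins: int = 220
    fmin_hz: float = 3.0
    fmax_hz: float = 150.0
    window_s: float = 0.5
    step_s: float = 0.025
    baseline_s: tuple = (-1.0, -0.5)
    pre_s: float = 3.5      # pre-onset span; must reach past the baseline so
    post_s: float = 1.0     # the bootstrap null pool has pause columns
    n_boot: int = 200
    alpha: float = 0.05

    # decoding
    reduction_factor: int = 10
    cv_folds: int = 10
    exclude_visual: bool = True
    paper_mode: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_s = tuple(self.baseline_s)
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_models < 1 or self.n_components < 1:
            raise ValueError("n_models and n_components must be positive")
        if not 0 < self.fmin_hz < self.fmax_hz < self.fs / 2:
            raise ValueError("need 0 < fmin < fmax < Nyquist")
        if self.baseline_s[0] >= self.baseline_s[1]:
            raise ValueError("baseline interval must be increasing")
        if self.reps < 0 or self.n_subjects < 1:
            raise ValueError("invalid study size")
        if not 0 < self.brain_radius_fraction < 1:
            raise ValueError("brain_radius_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_s"] = list(self.baseline_s)
        return d


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
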
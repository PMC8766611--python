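"""Pipeline configuration: defaults, validation, YAML round-trip, hashing.

Defaults follow the analysis settings of the thermal-stimulation study
design: 0.5-70 Hz fourth-order Butterworth band-pass applied zero-phase,
50 Hz notch, 3000 ms epochs baseline-corrected to the pre-stimulus mean,
100 uV amplitude rejection with a 50-200 Hz / 1-10 mV EMG criterion on raw
data, CSP -> 2-component PCA -> LDA with an 80/20 stratified split and
stratified ten-fold cross-validation, and 3 s sliding-window augmentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass(frozen=True)
class FilterConfig:
    low_hz: float = 0.5
    high_hz: float = 70.0
    order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True


@dataclass(frozen=True)
class EpochConfig:
    length_ms: float = 3000.0
    baseline: Tuple[float, float] = (-3.0, 0.0)  # s relative to stimulus onset


@dataclass(frozen=True)
class RejectionConfig:
    amp_threshold_uv: float = 100.0
    emg_band_hz: Tuple[float, float] = (50.0, 200.0)
    emg_amp_mv: Tuple[float, float] = (1.0, 10.0)


@dataclass(frozen=True)
class ClassificationConfig:
    n_csp_pairs: int = 2
    csp_shrinkage: float = 1e-4
    pca_components: int = 2
    split_fraction: float = 0.8
    cv_folds: int = 10
    group_aware: bool = True   # keep crops of one parent trial on one side
    csp_per_fold: bool = True  # refit CSP inside each CV fold
    seed: int = 0


@dataclass(frozen=True)
class AugmentationConfig:
    window_s: float = 3.0
    stride_s: float = 3.0


@dataclass(frozen=True)
class SpectralConfig:
    alpha_band_hz: Tuple[float, float] = (8.0, 12.0)
    welch_segment_s: float = 1.0
    welch_overlap: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = FilterConfig()
    epoch: EpochConfig = EpochConfig()
    rejection: RejectionConfig = RejectionConfig()
    classification: ClassificationConfig = ClassificationConfig()
    augmentation: AugmentationConfig = AugmentationConfig()
    spectral: SpectralConfig = SpectralConfig()

    def __post_init__(self) -> None:
        f = self.filter
        if not 0 < f.low_hz < f.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")
        if self.classification.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.classification.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.augmentation.window_s <= 0 or self.augmentation.stride_s <= 0:
            raise ValueError("augmentation window/stride must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "filter", "epoch", "rejection", "classification",
            "augmentation", "spectral",
        ):
            sub = {
                "filter": FilterConfig, "epoch": EpochConfig,
                "rejection": RejectionConfig,
                "classification": ClassificationConfig,
                "augmentation": AugmentationConfig, "spectral": SpectralConfig,
            }[f.name]
            kwargs[f.name] = _build(sub, v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML; missing keys take defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(PipelineConfig, data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
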
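"""Pipeline configuration: defaults, YAML round-trip, validation.

Defaults follow the reference acquisition protocol: 128 px patches on a
32 px stride; blackout red < 50 with a 10% exclusion bound; halation
green > 250 with a 5% bound; focus cutoff 6.25% of Nyquist; three-fold
lesion-stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import TrainConfig
from .patching import PatchingConfig
from .types import ConfigurationError


@dataclass(frozen=True)
class QualityConfig:
    blackout_value: int = 50
    blackout_frac: float = 0.10
    halation_value: int = 250
    halation_frac: float = 0.05


@dataclass(frozen=True)
class FocusConfig:
    cutoff: float = 0.0625
    threshold: float = 0.02
    channel: int = 1  # green


@dataclass(frozen=True)
class CVConfig:
    k: int = 3
    unit: str = "lesion"  # or "image" / "patch" for fidelity experiments
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    patch_size: int = 128
    stride: int = 32
    quality: QualityConfig = field(default_factory=QualityConfig)
    focus: FocusConfig = field(default_factory=FocusConfig)
    coverage_threshold: float = 0.5
    cv: CVConfig = field(default_factory=CVConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    backend: str = "spectral"  # or "oracle" / "constant:<k>"

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.stride < 1:
            raise ConfigurationError("patch_size and stride must be positive")
        if not 0.0 < self.focus.cutoff < 1.0:
            raise ConfigurationError("focus cutoff must lie in (0, 1)")
        if self.cv.unit not in ("lesion", "image", "patch"):
            raise ConfigurationError(f"unknown CV unit {self.cv.unit!r}")

    def patching(self) -> PatchingConfig:
        return PatchingConfig(
            patch_size=self.patch_size,
            stride=self.stride,
            blackout_max=self.quality.blackout_frac,
            halation_max=self.quality.halation_frac,
            focus_cutoff=self.focus.cutoff,
            focus_threshold=self.focus.threshold,
            focus_channel=self.focus.channel,
            coverage_threshold=self.coverage_threshold,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: Path | str | None) -> PipelineConfig:
    """Read a YAML config; missing file sections fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(
            patch_size=raw.get("patch_size", 128),
            stride=raw.get("stride", 32),
            quality=QualityConfig(**raw.get("quality", {})),
            focus=FocusConfig(**raw.get("focus", {})),
            coverage_threshold=raw.get("coverage_threshold", 0.5),
            cv=CVConfig(**raw.get("cv", {})),
            train=TrainConfig(**raw.get("train", {})),
            backend=raw.get("backend", "spectral"),
        )
    except TypeError as exc:
        raise ConfigurationError(f"malformed configuration: {exc}") from exc


def save_config(path: Path | str, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
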
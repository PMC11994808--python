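"""Pipeline configuration: every analysis constant in one YAML-serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Defaults mirror the published analysis constants."""

    # twin training
    n_exemplars: int = 250
    min_training_samples: int = 2500
    min_training_days: int = 3
    # MCIR fusion
    zero_quantile: float = 0.95
    block_minutes: int = 15
    min_valid_minutes: int = 3
    # response metrics
    window_h: float = 72.0
    slide_window_h: float = 6.0
    window_fraction: float = 0.5
    detect_threshold: float = 0.10
    persistence_blocks: int = 5
    # statistics
    n_boot: int = 1000
    windows_per_control: int = 100
    seed: int = 0
    # paths
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not (0 < self.window_fraction <= 1):
            raise ValueError("window_fraction must lie in (0, 1]")
        if self.window_h < self.slide_window_h:
            raise ValueError("window_h must be >= slide_window_h")
        positive = ("n_exemplars", "min_training_samples", "min_training_days",
                    "block_minutes", "min_valid_minutes", "window_h",
                    "slide_window_h", "detect_threshold", "persistence_blocks",
                    "n_boot", "windows_per_control")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.5 < self.zero_quantile < 1):
            raise ValueError("zero_quantile must lie in (0.5, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
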
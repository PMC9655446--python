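"""Pipeline configuration: one object binding all four stages together."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError, InvalidInputError
from .lookup import LookupConfig
from .stream import StreamConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Effective configuration of the detect -> crop -> encode -> lookup chain.

    Defaults follow the reference deployment: detector confidence 0.7
    (strict), 640x360 detection input, 224 px chips, every-6th-frame video
    sampling with a 10-slot buffer.
    """

    detector_backend: str = "truth"
    detector_min_conf: float = 0.7
    detect_width: int = 640
    detect_height: int = 360
    chip_side: int = 224
    encoder_backend: str = "toy"
    dimension: int = 64
    lookup: LookupConfig = field(default_factory=LookupConfig)
    stream: StreamConfig = field(default_factory=StreamConfig)
    gallery_path: str = "gallery"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.detector_min_conf <= 1.0:
            raise ConfigError("detector_min_conf outside [0, 1]")
        if min(self.detect_width, self.detect_height, self.chip_side) < 1:
            raise ConfigError("image dimensions must be >= 1")
        if self.dimension < 2:
            raise ConfigError("dimension must be >= 2")
        if isinstance(self.lookup, dict):
            self.lookup = LookupConfig(**self.lookup)
        if isinstance(self.stream, dict):
            self.stream = StreamConfig(**self.stream)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"unknown configuration field: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config: {exc}") from exc
        if not isinstance(data, dict):
            raise InvalidInputError("config root must be a mapping")
        return cls.from_dict(data)
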
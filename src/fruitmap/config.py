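"""Pipeline configuration with YAML/JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

_INTERPS = ("bilinear", "nearest")
_CLASSES = ("auto", "oblate", "spherical", "prolate")


@dataclass
class PipelineConfig:
    """Everything the map-building pipeline can be steered with.

    Angles are degrees. ``geometry_class='auto'`` classifies from the
    silhouettes; a concrete class skips classification. ``seed`` feeds
    the consensus sampler of the rotation estimator, so runs are
    reproducible end to end.
    """

    geometry_class: str = "auto"
    preroll_deg: float = 45.0
    postroll_deg: float = 45.0
    lambda_max_deg: float = 60.0
    interp: str = "bilinear"
    seed: int = 0
    tol_spherical: float = 0.03

    def __post_init__(self) -> None:
        if self.geometry_class not in _CLASSES:
            raise ValueError(f"geometry_class must be one of {_CLASSES}")
        if self.interp not in _INTERPS:
            raise ValueError(f"interp must be one of {_INTERPS}")
        if not (0 < self.lambda_max_deg <= 90):
            raise ValueError("lambda_max_deg must be in (0, 90]")
        if self.preroll_deg < 0 or self.postroll_deg < 0:
            raise ValueError("pre/post-roll must be non-negative")
        if not (0 <= self.tol_spherical < 1):
            raise ValueError("tol_spherical must be a small fraction")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
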
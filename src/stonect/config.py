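"""Run configuration: one serializable object carrying every tunable.

The JSON round-trip is strict — unknown keys are rejected so a typo in a
config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .classify import CutoffConfig, KnnConfig
from .errors import InputError, ValidationError
from .filters import LaplacianKernel
from .segment import DEFAULT_MAX_EXTENT_MM, DEFAULT_THRESHOLD_HU

__all__ = ["SegmentationConfig", "RunConfig"]


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    max_extent_mm: float = DEFAULT_MAX_EXTENT_MM

    def __post_init__(self) -> None:
        if self.threshold_hu <= 0 or self.max_extent_mm <= 0:
            raise ValidationError("segmentation parameters must be positive")


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Complete, hashable description of a pipeline run."""

    kernel: LaplacianKernel = field(default_factory=LaplacianKernel)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    confidence: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValidationError("confidence must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "kernel": dataclasses.asdict(self.kernel),
            "cutoffs": dataclasses.asdict(self.cutoffs),
            "knn": dataclasses.asdict(self.knn),
            "segmentation": dataclasses.asdict(self.segmentation),
            "confidence": self.confidence,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"kernel", "cutoffs", "knn", "segmentation", "confidence", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(
            kernel=_from_dict(LaplacianKernel, data.get("kernel", {})),
            cutoffs=_from_dict(CutoffConfig, data.get("cutoffs", {})),
            knn=_from_dict(KnnConfig, data.get("knn", {})),
            segmentation=_from_dict(SegmentationConfig, data.get("segmentation", {})),
            confidence=data.get("confidence", 0.95),
            seed=data.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read config {path!s}: {exc}") from exc
        return cls.from_dict(data)

    def hash(self) -> str:
        """Short digest of the canonical JSON form, for provenance logging."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
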
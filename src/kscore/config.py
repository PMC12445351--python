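"""Run configuration: documented defaults, YAML loading, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError
from .preprocess import SegmentationParams


@dataclass(frozen=True)
class FilterParams:
    cutoff_hz: float = 5.0
    order: int = 2


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the end-to-end pipeline, with its default.

    frame_mode "auto" estimates the anatomical frame from each recording
    (making the pipeline similarity-invariant); "fixed" trusts the stored
    axes (y superior, z anterior).
    """

    filter: FilterParams = field(default_factory=FilterParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    frame_mode: str = "auto"
    grid_size: int = 101
    alpha_target: float = 94.0
    retention: float = 0.90
    correction: str = "holm"
    gpa_tol: float = 1e-9
    gpa_max_iter: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def provenance_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        kwargs: dict = {}
        for section, sub_cls in (("filter", FilterParams), ("segmentation", SegmentationParams)):
            if section in doc:
                sub = doc.pop(section) or {}
                known = {f.name for f in fields(sub_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ParameterError(f"unknown {section} config keys: {sorted(unknown)}")
                kwargs[section] = sub_cls(**sub)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(doc)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
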
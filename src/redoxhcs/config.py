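"""Run configuration: a validated plain-text (YAML/JSON) key-value schema.

Unknown keys are rejected so that typos fail before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigurationError
from .segment import SegmentationParams

_TOP_KEYS = {
    "plate_dir",
    "layout",
    "out_dir",
    "seed",
    "mode",
    "intensity_floor",
    "fold_threshold",
    "high_ratio_gate",
    "ratio_mode",
    "segmentation",
    "verbosity",
}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}


@dataclass
class RunConfig:
    plate_dir: str
    layout: str
    out_dir: str
    seed: int = 0
    mode: str = "nuclear-ring"
    intensity_floor: float = 9.0
    fold_threshold: float = 3.0
    high_ratio_gate: float | None = None
    ratio_mode: str = "pixel_mean"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("intensity", "nuclear-ring"):
            raise ConfigurationError(
                f"mode must be 'intensity' or 'nuclear-ring', got {self.mode!r}"
            )
        if self.ratio_mode not in ("pixel_mean", "roi_mean"):
            raise ConfigurationError("ratio_mode must be 'pixel_mean' or 'roi_mean'")
        if self.fold_threshold <= 0:
            raise ConfigurationError("fold_threshold must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("plate_dir", "layout", "out_dir"):
            if key not in data:
                raise ConfigurationError(f"config missing required key {key!r}")
        seg_data = data.get("segmentation", {}) or {}
        if not isinstance(seg_data, Mapping):
            raise ConfigurationError("segmentation section must be a mapping")
        bad = set(seg_data) - _SEG_KEYS
        if bad:
            raise ConfigurationError(f"unknown segmentation keys: {sorted(bad)}")
        try:
            seg = SegmentationParams(**seg_data)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid segmentation params: {exc}") from exc
        kwargs = {k: v for k, v in data.items() if k != "segmentation"}
        try:
            return cls(segmentation=seg, **kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"invalid config: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        """Stable hash of the analysis-relevant configuration.

        Excludes ``out_dir`` and ``verbosity``: where results are written
        and how chatty the run is do not change what is computed.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("verbosity", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    from .io import load_config_file

    return RunConfig.from_dict(load_config_file(path))
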
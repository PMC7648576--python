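"""Run configuration: a single YAML-loadable object validated up front."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imagegen import SceneParams
from .segmentation import SegmentationConfig


@dataclass(frozen=True)
class RunConfig:
    """Everything a full simulate->quantify->classify->compare run needs.

    ``scene`` configures the synthetic scene (ignored when ``input_dir``
    points at an existing fixture); segmentation, pairing and threshold
    settings feed the corresponding stages.  Validation happens at
    construction, before any I/O.
    """

    seed: int = 0
    out_dir: str = "asympart_run"
    input_dir: str | None = None  # existing fixture; None -> simulate
    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    budneck_segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(threshold_method="robust",
                                                   min_area=2, max_area=40))
    inner_steps: int = 2
    outer_steps: int = 4
    pairing_max_distance: float = 20.0
    budneck_max_distance: float = 15.0
    threshold_statistic: tuple[str, float | None] = ("max", None)
    exclude_border: bool = True
    channel_roles: tuple[str, ...] = ("marker", "reporter", "budneck")

    def __post_init__(self) -> None:
        if not 0 <= self.inner_steps < self.outer_steps:
            raise ValueError("require 0 <= inner_steps < outer_steps")
        if self.pairing_max_distance <= 0 or self.budneck_max_distance <= 0:
            raise ValueError("distances must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "scene" in raw and isinstance(raw["scene"], dict):
            sc = dict(raw["scene"])
            for key in ("image_shape", "category_mixture", "stage_mixture",
                        "background_gradient"):
                if key in sc and isinstance(sc[key], list):
                    sc[key] = tuple(sc[key])
            raw["scene"] = SceneParams(**sc)
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        if "budneck_segmentation" in raw and isinstance(raw["budneck_segmentation"], dict):
            raw["budneck_segmentation"] = SegmentationConfig(**raw["budneck_segmentation"])
        if "threshold_statistic" in raw and isinstance(raw["threshold_statistic"], list):
            raw["threshold_statistic"] = tuple(raw["threshold_statistic"])
        if "channel_roles" in raw and isinstance(raw["channel_roles"], list):
            raw["channel_roles"] = tuple(raw["channel_roles"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        """Stable short hash of the analysis-relevant configuration.

        The output directory is excluded so that identical analyses written
        to different locations hash (and therefore compare) equal.
        """
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
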
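"""Pipeline configuration: one validated object tying every tunable together.

Serialises to/from JSON or YAML losslessly.  Units follow the package
conventions (um, um^2, ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ctcscan.fafish import BreakApartRules, ScanConfig, SpotDetectionParams
from ctcscan.phenotype import ClassificationThresholds
from ctcscan.segment import SegmentationParams, SelectionGates
from ctcscan.simulate import CellPopulation, ExposureModel, FilterGeometry, SnickSpec


class ConfigError(ValueError):
    """Invalid or unreadable pipeline configuration."""


@dataclass
class PipelineConfig:
    geometry: FilterGeometry = field(default_factory=FilterGeometry)
    population: CellPopulation = field(default_factory=CellPopulation)
    exposure_model: ExposureModel = field(default_factory=ExposureModel)
    scan: ScanConfig = field(default_factory=ScanConfig)
    gates: SelectionGates = field(default_factory=SelectionGates)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    fish_rules: BreakApartRules = field(default_factory=BreakApartRules)
    fish_detection: SpotDetectionParams = field(default_factory=SpotDetectionParams)
    pixel_size_um: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            geometry = d.get("geometry", {})
            snick = geometry.pop("snick", None) if isinstance(geometry, dict) else None
            kwargs = dict(
                geometry=FilterGeometry(**geometry, **({"snick": SnickSpec(**snick)} if snick else {}))
                if isinstance(geometry, dict)
                else geometry,
                population=CellPopulation(**_tupled(d.get("population", {}), ("cluster_size_range", "leukocyte_area_um2", "ctc_area_um2"))),
                exposure_model=ExposureModel(**d.get("exposure_model", {})),
                scan=ScanConfig(**_scan_dict(d.get("scan", {}))),
                gates=SelectionGates(**d.get("gates", {})),
                segmentation=SegmentationParams(**d.get("segmentation", {})),
                thresholds=ClassificationThresholds(**d.get("thresholds", {})),
                fish_rules=BreakApartRules(**d.get("fish_rules", {})),
                fish_detection=SpotDetectionParams(**d.get("fish_detection", {})),
                pixel_size_um=d.get("pixel_size_um", 0.5),
                seed=d.get("seed", 0),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            text = path.read_text()
            if path.suffix in (".yaml", ".yml"):
                d = yaml.safe_load(text) or {}
            else:
                d = json.loads(text)
        except (OSError, json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d, indent=1))


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def _scan_dict(d: dict) -> dict:
    d = dict(d)
    if "exposures_ms" in d:
        d["exposures_ms"] = {ch: tuple(v) for ch, v in d["exposures_ms"].items()}
    return d
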
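"""Pipeline configuration: YAML in, validated nested dataclasses out.

Unknown keys are rejected so typos never silently fall back to defaults, and
the resolved configuration (every default filled in) is serialized into the
results directory together with a short hash that every output artifact is
tagged with.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .decoder import ClassifierConfig
from .design import DesignConfig, EllipsoidSpec
from .searchlight import SearchlightSpec
from .synthetic import DEMO_GRID_SHAPE, SignalConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PreprocessConfig:
    delay_volumes: int = 2
    window_volumes: int = 2

    def __post_init__(self) -> None:
        if self.delay_volumes < 0 or self.window_volumes < 1:
            raise ValueError("invalid preprocess window settings")


@dataclass(frozen=True)
class SearchlightSection:
    radius_vox: int = 1
    metric: str = "chebyshev"
    min_neighborhood: int = 9
    n_select: int = 100
    inner_folds: int = 5

    def spec(self) -> SearchlightSpec:
        return SearchlightSpec(self.radius_vox, self.metric, self.min_neighborhood)


@dataclass(frozen=True)
class GroupConfig:
    #: null selection probability; None derives n_select / |ROI| per ROI.
    p0: float | None = None
    alpha: float = 0.001
    bonferroni: bool = False


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 10
    shared_clusters: bool = True
    master_seed: int = 0
    grid_shape: tuple[int, int, int] = DEMO_GRID_SHAPE

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class RoiSpecConfig:
    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def spec(self) -> EllipsoidSpec:
        return EllipsoidSpec(self.name, tuple(self.center), tuple(self.radii))


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    searchlight: SearchlightSection = field(default_factory=SearchlightSection)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    #: None means the bundled demo ROI geometry.
    rois: tuple[RoiSpecConfig, ...] | None = None
    condition: str = "both"  # cued | free | both

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "design": DesignConfig,
    "signal": SignalConfig,
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "searchlight": SearchlightSection,
    "classifier": ClassifierConfig,
    "group": GroupConfig,
}


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {path!r}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Parse a YAML file (or pre-parsed mapping) into a PipelineConfig,
    rejecting unknown keys at every level."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    if "rois" in raw and raw["rois"] is not None:
        kwargs["rois"] = tuple(
            _build(RoiSpecConfig, r, f"rois[{i}]") for i, r in enumerate(raw["rois"])
        )
    if "condition" in raw:
        if raw["condition"] not in ("cued", "free", "both"):
            raise ValueError("condition must be cued, free or both")
        kwargs["condition"] = raw["condition"]
    return PipelineConfig(**kwargs)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
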
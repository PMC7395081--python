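"""YAML configuration loading for the pipeline CLI.

The file mirrors :class:`octmark.pipeline.PipelineConfig` section by
section; unknown keys are rejected so typos fail before any compute.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .errors import ValidationError
from .globalfeat import GlobalTrainConfig
from .local import LocalTrainConfig
from .markers import ZoneSpec
from .pipeline import PipelineConfig
from .simulate import CohortGenConfig, FunctionalModel, LesionClassModel
from .volume import ScanGeometry

_TUPLE_KEYS = {
    "dims", "lateral_extent_mm", "split", "hidden", "pool_shape", "aspect",
    "fovea_center_mm", "center", "semi_axes", "l1_grid",
}


def _build(cls, data: dict, label: str):
    if not isinstance(data, dict):
        raise ValidationError(f"config section {label!r} must be a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown keys in config section {label!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**kwargs)


def _build_cohort(data: dict) -> CohortGenConfig:
    data = dict(data)
    sub: dict = {}
    if "geometry" in data:
        sub["geometry"] = _build(ScanGeometry, data.pop("geometry"), "cohort.geometry")
    for key in ("bcva_model", "llva_model"):
        if key in data:
            sub[key] = _build(FunctionalModel, data.pop(key), f"cohort.{key}")
    if "lesion_models" in data:
        sub["lesion_models"] = {
            cls: _build(LesionClassModel, spec, f"cohort.lesion_models.{cls}")
            for cls, spec in data.pop("lesion_models").items()
        }
    base = _build(CohortGenConfig, data, "cohort")
    return replace(base, **sub) if sub else base


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping at top level")
    known = {"cohort", "local", "global", "zones", "l1_grid", "folds", "seed",
             "include_external", "external"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "cohort" in raw:
        kwargs["cohort"] = _build_cohort(raw["cohort"])
    if "external" in raw:
        kwargs["external"] = _build_cohort(raw["external"])
    if "local" in raw:
        kwargs["local"] = _build(LocalTrainConfig, raw["local"], "local")
    if "global" in raw:
        kwargs["global_cfg"] = _build(GlobalTrainConfig, raw["global"], "global")
    if "zones" in raw:
        kwargs["zones"] = _build(ZoneSpec, raw["zones"], "zones")
    for key in ("folds", "seed", "include_external"):
        if key in raw:
            kwargs[key] = raw[key]
    if "l1_grid" in raw:
        kwargs["l1_grid"] = tuple(raw["l1_grid"])
    return PipelineConfig(**kwargs)
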
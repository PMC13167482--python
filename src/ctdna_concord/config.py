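"""YAML pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .filtering import FilterConfig
from .simulate import CohortSimSpec, SimConfig, VariantSpec

__all__ = ["PipelineConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration keys/values."""


@dataclass(frozen=True)
class FragmentomicsParams:
    min_mapq: int = 20
    min_anchor: int = 1
    threshold: int = 150
    max_size: int = 1000
    mono: tuple[int, int] = (50, 220)
    di: tuple[int, int] = (221, 400)


@dataclass(frozen=True)
class ReportingParams:
    places: int = 1
    conf: float = 0.95
    ci_method: str = "wilson"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ctdna_concord_out"
    stages: tuple[str, ...] = ("simulate", "filter", "concord", "fragsize")
    simulate: SimConfig = field(default_factory=SimConfig)
    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fragmentomics: FragmentomicsParams = field(default_factory=FragmentomicsParams)
    reporting: ReportingParams = field(default_factory=ReportingParams)


def _build(cls, mapping: dict[str, Any], context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path: str | Path, seed_override: Optional[int] = None) -> PipelineConfig:
    """Load and validate a pipeline YAML file.

    Sub-blocks (``simulate``, ``cohort``, ``filter``, ``fragmentomics``,
    ``reporting``) are validated against their dataclasses; any unknown key
    anywhere is rejected before any stage runs.  All stage seeds derive from
    the single top-level ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_keys
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")

    seed = seed_override if seed_override is not None else int(raw.get("seed", 0))

    sim_raw = dict(raw.get("simulate", {}))
    if "variant" in sim_raw:
        sim_raw["variant"] = _build(VariantSpec, sim_raw["variant"], "simulate.variant")
    sim_raw["seed"] = seed
    cohort_raw = dict(raw.get("cohort", {}))
    cohort_raw["seed"] = seed + 1  # distinct stream, still derived from one seed

    filt_raw = dict(raw.get("filter", {}))
    for key in ("excluded_clinvar", "germline_origin_labels",
                "retained_noncoding", "coding_classes"):
        if key in filt_raw:
            filt_raw[key] = frozenset(str(s).lower() for s in filt_raw[key])

    return PipelineConfig(
        seed=seed,
        out_dir=str(raw.get("out_dir", "ctdna_concord_out")),
        stages=tuple(raw.get("stages", ("simulate", "filter", "concord", "fragsize"))),
        simulate=_build(SimConfig, sim_raw, "simulate"),
        cohort=_build(CohortSimSpec, cohort_raw, "cohort"),
        filter=_build(FilterConfig, filt_raw, "filter"),
        fragmentomics=_build(FragmentomicsParams, raw.get("fragmentomics", {}), "fragmentomics"),
        reporting=_build(ReportingParams, raw.get("reporting", {}), "reporting"),
    )


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the fully-resolved configuration."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
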
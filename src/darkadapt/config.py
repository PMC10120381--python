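"""Run configuration: one keyed document covering every tunable default.

Sections mirror the pipeline stages -- ``protocol`` (the simulated
adaptometer), ``fit`` (simplex settings and seed parameters), ``synthetic``
(observer and cohort generation), ``stats`` and ``io`` -- plus the master
RNG seed.  Unknown keys anywhere in the document are rejected outright so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, is_dataclass
from pathlib import Path
from typing import Optional, Tuple, Type, TypeVar

import yaml

from .fitting import FitConfig
from .model import DAParams
from .synthetic import CohortConfig, StaircaseProtocol

__all__ = ["RunConfig", "SyntheticSection", "StatsSection", "IOSection",
           "load_config", "config_hash"]

T = TypeVar("T")


@dataclass(frozen=True)
class SyntheticSection:
    n_aniridia: int = 26
    n_control: int = 37
    slope: float = 10.0          # observer psychometric steepness per log unit
    lapse_rate: float = 0.02
    guess_rate: float = 0.0
    cohort: CohortConfig = CohortConfig()


@dataclass(frozen=True)
class StatsSection:
    alpha: float = 0.05
    cone_candidates: Tuple[str, ...] = (
        "central_outer_retinal_thickness", "age", "aak_grade")
    rod_candidates: Tuple[str, ...] = (
        "central_outer_retinal_thickness", "age", "aak_grade",
        "perifoveal_total_thickness")
    max_aak_grade_for_regression: int = 2   # structure-function analysis excludes opaque corneas


@dataclass(frozen=True)
class IOSection:
    out_dir: str = "results"
    trial_logs: Optional[str] = None
    cohort_file: Optional[str] = None
    plots: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    protocol: StaircaseProtocol = StaircaseProtocol()
    fit: FitConfig = FitConfig()
    synthetic: SyntheticSection = SyntheticSection()
    stats: StatsSection = StatsSection()
    io: IOSection = IOSection()


def _build(cls: Type[T], data: dict, path: str = "") -> T:
    """Construct a (possibly nested) dataclass from a dict, rejecting
    unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default
        target = default.__class__ if is_dataclass(default) else None
        if name == "seed_params" and isinstance(value, dict):
            kwargs[name] = _build(DAParams, value, f"{path}.{name}")
        elif target is not None and is_dataclass(target) and isinstance(value, dict):
            kwargs[name] = _build(target, value, f"{path}.{name}")
        elif isinstance(default, tuple) and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(source=None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path, a dict, or nothing."""
    if source is None:
        return RunConfig()
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        data = source
    else:
        raise TypeError(f"cannot build RunConfig from {type(source)}")
    return _build(RunConfig, data)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the full configuration (for provenance lines)."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
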
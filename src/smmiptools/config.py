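"""YAML run configuration.

Sections map onto the library's parameter dataclasses: ``design`` ->
:class:`~smmiptools.probe_design.DesignProfile` (plus scoring weights),
``selection`` -> :class:`~smmiptools.panel_select.SelectionConfig`,
``thermo`` -> :class:`~smmiptools.thermo.ThermoParams`, ``simulate`` ->
:class:`~smmiptools.capture_sim.SimParams`, ``classify`` ->
:class:`~smmiptools.read_classify.ClassifierConfig` and ``report`` ->
:class:`~smmiptools.meth_call.ReportConfig`.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from typing import Any

import yaml

from .capture_sim import SimParams
from .meth_call import ReportConfig
from .panel_select import DEFAULT_BACKBONE, SelectionConfig
from .probe_design import DesignProfile, ScoringWeights
from .read_classify import ClassifierConfig
from .thermo import ThermoParams


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."
    backbone_seq: str = DEFAULT_BACKBONE
    loosening: bool = True
    flank_bp: int | None = None
    profile: DesignProfile = field(default_factory=DesignProfile.default)
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    simulate: SimParams = field(default_factory=SimParams)
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_jsonable(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    return obj


_TOP_KEYS = {"seed", "log_level", "output_dir", "backbone_seq", "loosening",
             "flank_bp", "design", "selection", "thermo", "simulate",
             "classify", "report"}

_WEIGHT_KEYS = {"w_cpg", "w_snp", "w_hairpin", "w_dtm",
                "dimer_conflict_increment"}
_PROFILE_KEYS = {"target_len_window", "arm_len_window", "gc_window",
                 "max_arm_dtm_c", "max_panel_tm_spread_c",
                 "dimer_tm_threshold_c", "hairpin_tm_threshold_c",
                 "max_candidates_per_target"}


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (or defaults when ``path`` is None) and apply
    flat overrides like ``{"seed": 7}``."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level of config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    design_raw = dict(raw.get("design") or {})
    unknown = set(design_raw) - _PROFILE_KEYS - _WEIGHT_KEYS
    if unknown:
        raise ConfigError(f"unknown [design] keys: {sorted(unknown)}")
    weight_kwargs = {k: design_raw.pop(k) for k in list(design_raw)
                     if k in _WEIGHT_KEYS}
    try:
        if design_raw:
            profile_kwargs = {k: tuple(v) if isinstance(v, list) else v
                              for k, v in design_raw.items()}
            base = DesignProfile(**profile_kwargs)
            stages = tuple(replace(s, **profile_kwargs)
                           for s in DesignProfile.default().loosening_schedule)
            cfg.profile = replace(base, loosening_schedule=stages) \
                if _stages_widen(base, stages) else base
        if weight_kwargs:
            cfg.weights = ScoringWeights(**weight_kwargs)
        cfg.selection = _build(SelectionConfig, raw.get("selection"), "selection")
        cfg.thermo = _build(ThermoParams, raw.get("thermo"), "thermo")
        cfg.simulate = _build(SimParams, raw.get("simulate"), "simulate")
        cfg.classify = _build(ClassifierConfig, raw.get("classify"), "classify")
        cfg.report = _build(ReportConfig, raw.get("report"), "report")
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    for key in ("seed", "log_level", "output_dir", "backbone_seq",
                "loosening", "flank_bp"):
        if key in raw:
            setattr(cfg, key, raw[key])
    for key, value in (overrides or {}).items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown override {key!r}")
        setattr(cfg, key, value)
    if not cfg.loosening:
        cfg.profile = replace(cfg.profile, loosening_schedule=())
    cfg.selection = replace(cfg.selection, seed=cfg.seed) \
        if "seed" not in (raw.get("selection") or {}) else cfg.selection
    cfg.simulate = replace(cfg.simulate, seed=cfg.seed) \
        if "seed" not in (raw.get("simulate") or {}) else cfg.simulate
    return cfg


def _stages_widen(base: DesignProfile, stages: tuple) -> bool:
    try:
        replace(base, loosening_schedule=stages)
        return True
    except ValueError:
        return False


def _build(cls, section: dict | None, name: str):
    section = dict(section or {})
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown [{name}] keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v
              for k, v in section.items()}
    return cls(**kwargs)
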
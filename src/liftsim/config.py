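"""Run configuration: YAML-backed, schema-validated, serialized into manifests."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .preprocess import FilterSpec
from .synthetic import BoxSpec, TaskConfig

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "anthropometry": {"body_mass", "stature"},
    "box": {"mass", "width", "depth", "height", "handle_offset"},
    "task": {"shelf_height", "table_height", "cycle_rate", "n_repetitions",
             "grip_ramp_duration", "marker_noise_sd", "seed", "shelf_reach",
             "table_reach", "move_fraction", "lead_time", "marker_rate",
             "force_rate"},
    "filter": {"order", "cutoff_hz", "zero_phase"},
    "so": {"w_reserve"},
    "detector": {"prominence_fraction", "min_separation_s"},
}


@dataclass
class RunConfig:
    """Validated configuration for simulation and analysis runs.

    Every default is documented on the underlying dataclasses
    (:class:`~liftsim.synthetic.TaskConfig`, :class:`~liftsim.synthetic.BoxSpec`,
    :class:`~liftsim.preprocess.FilterSpec`); the resolved values are
    serialized verbatim into the run manifest for reproducibility.
    """

    anthropometry: dict = field(default_factory=lambda: {"body_mass": 75.16,
                                                         "stature": 1.74})
    box: BoxSpec = field(default_factory=BoxSpec)
    task: TaskConfig = field(default_factory=TaskConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    w_reserve: float = 1.0
    detector: dict = field(default_factory=lambda: {"prominence_fraction": 0.25,
                                                    "min_separation_s": 1.0})
    approach: str = "all"
    seed: Optional[int] = None

    def manifest(self) -> dict:
        d = {
            "anthropometry": dict(self.anthropometry),
            "box": {k: v for k, v in asdict(self.box).items()
                    if k != "corner_marker_offsets"},
            "task": asdict(self.task),
            "filter": asdict(self.filter),
            "so": {"w_reserve": self.w_reserve},
            "detector": dict(self.detector),
            "approach": self.approach,
            "seed": self.seed,
        }
        blob = json.dumps(d, sort_keys=True, default=str)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return d


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML config file, validating section and key names.

    Unknown sections or keys raise :class:`ConfigError` naming the offender.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed YAML in {path}: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        for k, v in overrides.items():
            raw.setdefault(k, {}).update(v) if isinstance(v, dict) else raw.update({k: v})
    known_top = set(_SECTIONS) | {"approach", "seed"}
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unknown config section or key: {key!r}")
    for section, allowed in _SECTIONS.items():
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for k in sub:
            if k not in allowed:
                raise ConfigError(f"unknown key {section}.{k}")
    cfg = RunConfig(
        anthropometry={**{"body_mass": 75.16, "stature": 1.74},
                       **raw.get("anthropometry", {})},
        box=BoxSpec(**raw.get("box", {})),
        task=TaskConfig(**raw.get("task", {})),
        filter=FilterSpec(**raw.get("filter", {})),
        w_reserve=float(raw.get("so", {}).get("w_reserve", 1.0)),
        detector={**{"prominence_fraction": 0.25, "min_separation_s": 1.0},
                  **raw.get("detector", {})},
        approach=str(raw.get("approach", "all")).lower(),
        seed=raw.get("seed"),
    )
    if cfg.approach not in ("app1", "app2", "app3", "all"):
        raise ConfigError(f"approach must be app1|app2|app3|all, got {cfg.approach!r}")
    for k, v in cfg.anthropometry.items():
        if v <= 0:
            raise ConfigError(f"anthropometry.{k} must be positive")
    return cfg
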
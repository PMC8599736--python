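"""Run configuration: strict TOML loading with parameter echo support.

Unknown keys are rejected outright (silently ignored typos in a mapping
experiment are worse than a hard error) and referenced files must exist
at load time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .caller import CallerParams
from .consensus import FilterParams
from .simulate import CollisionModel, EnzymeModel, ErrorModel, EventDistribution

__all__ = ["RunConfig", "load_config", "config_hash"]

_TOP_KEYS = {"paths", "filter", "caller", "error_model", "simulation", "cutoffs"}
_SIM_KEYS = {
    "kind", "n_events", "seed", "repeats_choices", "quality_q",
    "enzyme", "distribution", "collision", "enzymes",
}
_PATH_KEYS = {"reference", "cassette", "reads", "consensus", "outdir"}


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    filter: FilterParams = field(default_factory=FilterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    simulation: dict = field(default_factory=dict)
    cutoffs: tuple = (1, 2, 3, 5, 10)


def _strict(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(cls, section: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    _strict(section, allowed, where)
    return cls(**section)


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    raw = tomllib.loads(Path(path).read_text())
    _strict(raw, _TOP_KEYS, "config")
    paths = raw.get("paths", {})
    _strict(paths, _PATH_KEYS, "paths")
    base = Path(path).parent
    resolved = {}
    for key, value in paths.items():
        p = Path(value)
        if not p.is_absolute():
            p = base / p
        if key != "outdir" and not p.exists():
            raise FileNotFoundError(f"paths.{key} does not exist: {p}")
        resolved[key] = p
    sim = raw.get("simulation", {})
    _strict(sim, _SIM_KEYS, "simulation")
    cfg = RunConfig(
        paths=resolved,
        filter=_build(FilterParams, raw.get("filter", {}), "filter"),
        caller=_build(CallerParams, raw.get("caller", {}), "caller"),
        error_model=_build(ErrorModel, raw.get("error_model", {}), "error_model"),
        simulation=sim,
        cutoffs=tuple(raw.get("cutoffs", (1, 2, 3, 5, 10))),
    )
    return cfg


def build_event_model(sim: dict):
    """Instantiate the event model named by a simulation block."""
    kind = sim.get("kind")
    if kind == "enzyme":
        return _build(EnzymeModel, sim["enzyme"], "simulation.enzyme")
    if kind == "collision":
        return _build(CollisionModel, sim["collision"], "simulation.collision")
    if kind == "distribution":
        block = dict(sim["distribution"])
        for key in ("top_dist", "bottom_dist", "joint_pairs"):
            if key in block and block[key] is not None:
                block[key] = {
                    _parse_key(k): v for k, v in block[key].items()
                }
        return EventDistribution(**block)
    raise ValueError(f"unknown simulation kind {kind!r}")


def _parse_key(k):
    if isinstance(k, str) and "," in k:
        return tuple(int(x) for x in k.split(","))
    return int(k)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the effective parameters."""
    blob = json.dumps(
        {
            "paths": {k: str(v) for k, v in cfg.paths.items()},
            "filter": dataclasses.asdict(cfg.filter),
            "caller": dataclasses.asdict(cfg.caller),
            "error_model": dataclasses.asdict(cfg.error_model),
            "simulation": cfg.simulation,
            "cutoffs": list(cfg.cutoffs),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
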
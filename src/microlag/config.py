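"""Flat key-value configuration round-trip (YAML/JSON) and provenance records.

Config files are flat mappings whose keys mirror the parameter dataclass
fields exactly; unknown keys are an error, so a typo can never silently fall
back to a default.  Every run emits a provenance JSON (full parameter set,
seeds, package version) sufficient to reproduce it byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from . import __version__
from .params import (
    ConfigError,
    InitialCondition,
    PopulationParams,
    TransferParams,
    params_from_dict,
    params_to_dict,
)
from .stochastic import StochasticRunConfig

__all__ = ["load_config", "save_config", "provenance", "RUN_KEYS"]

RUN_KEYS = ("dt_jump", "t_end", "seed", "record_events", "dt_out")


def load_config(
    path,
) -> tuple[PopulationParams, TransferParams, InitialCondition, StochasticRunConfig]:
    """Parse a YAML (or JSON) config file into typed parameter objects."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    pop, tr, init = params_from_dict(data, allow_extra=RUN_KEYS)
    run = {k: data[k] for k in RUN_KEYS if k in data}
    if "seed" in run and run["seed"] is not None:
        run["seed"] = int(run["seed"])
    if "record_events" in run:
        run["record_events"] = bool(run["record_events"])
    for k in ("dt_jump", "t_end", "dt_out"):
        if k in run:
            run[k] = float(run[k])
    cfg = StochasticRunConfig(**run)
    return pop, tr, init, cfg


def save_config(
    path,
    pop: PopulationParams,
    tr: TransferParams,
    init: InitialCondition,
    cfg: StochasticRunConfig | None = None,
) -> None:
    data = params_to_dict(pop, tr, init)
    if cfg is not None:
        data.update(
            dt_jump=cfg.dt_jump,
            t_end=cfg.t_end,
            seed=cfg.seed,
            record_events=cfg.record_events,
            dt_out=cfg.dt_out,
        )
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def provenance(
    pop: PopulationParams,
    tr: TransferParams,
    init: InitialCondition,
    cfg: StochasticRunConfig | None = None,
    **extra,
) -> dict:
    """JSON-serializable record of everything needed to reproduce a run."""
    rec = {
        "package": "microlag",
        "version": __version__,
        "params": params_to_dict(pop, tr, init),
    }
    if cfg is not None:
        rec["run"] = {
            "dt_jump": cfg.dt_jump,
            "t_end": cfg.t_end,
            "seed": cfg.seed,
            "record_events": cfg.record_events,
            "dt_out": cfg.dt_out,
        }
    rec.update(extra)
    return rec


def write_provenance(path, rec: dict) -> None:
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))
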
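"""YAML configuration and run manifests.

A config file mirrors the :class:`~redusim.parameters.ModelParameters`
sections (``liver``, ``enzyme``, ``gene``, ``mass``, ``axis``, ``pk``) plus
optional ``scenario`` and ``output`` sections.  Unknown sections or keys are
rejected so typos cannot silently fall back to defaults.  Every CLI run
writes a manifest (parameters, seed, overrides, version, timestamps) from
which the run can be reproduced exactly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import fields
from pathlib import Path
from typing import Any

import yaml

from .parameters import ModelParameters, validate_parameters
from .pk import DoseRegimen
from .simulate import Scenario

__all__ = ["load_params", "params_from_dict", "scenario_from_dict",
           "dump_params", "write_manifest"]

_SECTIONS = ("liver", "enzyme", "gene", "mass", "axis", "pk")
_SCENARIO_KEYS = {"kind", "castration_time_hr", "dose_mg_per_kg", "interval_hr",
                  "duration_days", "washout_days"}


def params_from_dict(cfg: dict[str, Any]) -> ModelParameters:
    """Build parameters from a nested mapping; unknown keys raise KeyError."""
    params = ModelParameters()
    extra = set(cfg) - set(_SECTIONS)
    if extra:
        raise KeyError(f"unknown config section(s): {sorted(extra)}")
    for section in _SECTIONS:
        block = cfg.get(section) or {}
        target = getattr(params, section)
        known = {f.name for f in fields(target)}
        unknown = set(block) - known
        if unknown:
            raise KeyError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
        for key, value in block.items():
            setattr(target, key, float(value))
    return validate_parameters(params)


def scenario_from_dict(cfg: dict[str, Any] | None) -> Scenario:
    cfg = dict(cfg or {})
    unknown = set(cfg) - _SCENARIO_KEYS
    if unknown:
        raise KeyError(f"unknown scenario key(s): {sorted(unknown)}")
    kind = cfg.pop("kind", "intact")
    if kind == "treated":
        regimen = DoseRegimen(
            dose_mg_per_kg=float(cfg.pop("dose_mg_per_kg", 40.0)),
            interval_hr=float(cfg.pop("interval_hr", 24.0)),
            duration_days=float(cfg.pop("duration_days", 21.0)),
            washout_days=float(cfg.pop("washout_days", 0.0)),
        )
        return Scenario(kind="treated", regimen=regimen)
    return Scenario(kind=kind, castration_time_hr=float(cfg.pop("castration_time_hr", 0.0)))


def load_params(path: str | Path) -> tuple[ModelParameters, dict[str, Any]]:
    """Read a YAML config; return ``(params, full_config_dict)``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TypeError("config root must be a mapping")
    model_cfg = {k: v for k, v in cfg.items() if k in _SECTIONS}
    extra = set(cfg) - set(_SECTIONS) - {"scenario", "output"}
    if extra:
        raise KeyError(f"unknown config section(s): {sorted(extra)}")
    return params_from_dict(model_cfg), cfg


def dump_params(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: ModelParameters,
    seed: int | None = None,
    overrides: dict[str, Any] | None = None,
    extras: dict[str, Any] | None = None,
) -> Path:
    """Write ``manifest.json`` capturing everything needed to reproduce a run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "redusim",
        "version": __version__,
        "command": command,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "overrides": overrides or {},
        "parameters": params.to_dict(),
    }
    if extras:
        manifest.update(extras)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path
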
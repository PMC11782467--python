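"""Run configuration: schema-checked YAML/JSON loading with defaults.

A run config has up to five blocks: ``parameters`` (ParameterSet fields,
aliases allowed), ``initial_state`` (compartment densities), ``settings``
(IntegrationSettings fields), ``sweep`` (two axis specs) and ``output``
(directory, plot toggle).  Unknown keys anywhere are an error, as are
inconsistent alias pairs (beta vs interbirth_interval, chi vs
pair_bond_duration).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .dynamics import IntegrationSettings
from .model import COMPARTMENTS, PopulationState
from .params import ParameterSet
from .sweeps import AxisSpec

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger("pairbond")

_TOP_KEYS = {"parameters", "initial_state", "settings", "sweep", "output"}
_OUTPUT_KEYS = {"directory", "plots"}
_AXIS_KEYS = {"name", "values", "start", "stop", "num"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a simulation or sweep run."""

    params: ParameterSet = field(default_factory=ParameterSet)
    initial_state: PopulationState = field(
        default_factory=PopulationState.default_initial)
    settings: IntegrationSettings = field(
        default_factory=IntegrationSettings)
    axis1: AxisSpec | None = None
    axis2: AxisSpec | None = None
    output_dir: Path = Path("results")
    plots: bool = False


def _build_axis(block: Mapping[str, Any], which: str) -> AxisSpec:
    unknown = set(block) - _AXIS_KEYS
    if unknown:
        raise ValueError(f"unknown keys in sweep.{which}: {sorted(unknown)}")
    if "name" not in block:
        raise ValueError(f"sweep.{which} needs a 'name'")
    if "values" in block:
        if {"start", "stop", "num"} & set(block):
            raise ValueError(
                f"sweep.{which}: give either 'values' or start/stop/num")
        values = block["values"]
    else:
        missing = {"start", "stop", "num"} - set(block)
        if missing:
            raise ValueError(f"sweep.{which} missing {sorted(missing)}")
        values = np.linspace(block["start"], block["stop"],
                             int(block["num"]))
    return AxisSpec(block["name"], values)


def _from_mapping(data: Mapping[str, Any]) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    params = ParameterSet.from_dict(data.get("parameters") or {})

    init_block = data.get("initial_state") or {}
    unknown = set(init_block) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartments in initial_state: "
                         f"{sorted(unknown)}")
    if init_block:
        init = PopulationState(**init_block)
    else:
        init = PopulationState.default_initial()

    settings_block = dict(data.get("settings") or {})
    valid = {f.name for f in dc_fields(IntegrationSettings)}
    unknown = set(settings_block) - valid
    if unknown:
        raise ValueError(f"unknown keys in settings: {sorted(unknown)}")
    settings = IntegrationSettings(**settings_block)

    axis1 = axis2 = None
    sweep_block = data.get("sweep") or {}
    if sweep_block:
        unknown = set(sweep_block) - {"axis1", "axis2"}
        if unknown:
            raise ValueError(f"unknown keys in sweep: {sorted(unknown)}")
        if "axis1" not in sweep_block or "axis2" not in sweep_block:
            raise ValueError("sweep needs both axis1 and axis2")
        axis1 = _build_axis(sweep_block["axis1"], "axis1")
        axis2 = _build_axis(sweep_block["axis2"], "axis2")

    output_block = data.get("output") or {}
    unknown = set(output_block) - _OUTPUT_KEYS
    if unknown:
        raise ValueError(f"unknown keys in output: {sorted(unknown)}")

    cfg = RunConfig(
        params=params,
        initial_state=init,
        settings=settings,
        axis1=axis1,
        axis2=axis2,
        output_dir=Path(output_block.get("directory", "results")),
        plots=bool(output_block.get("plots", False)),
    )
    log.info("resolved parameters: %s", cfg.params.to_dict())
    if not data.get("parameters"):
        log.info("no parameter block given; applied reference defaults")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config root must be a mapping, got "
                         f"{type(data).__name__}")
    return _from_mapping(data)
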
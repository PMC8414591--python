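"""Unit-checked YAML/JSON configuration for model and protocol parameters.

Every physical leaf in a config file is written as ``{value: ..., unit:
"..."}`` and the loader refuses a mismatched unit string, so a file is
self-documenting and cannot silently mix unit conventions.  Dimensionless
quantities use unit "1".  Only keys present in the file override the
defaults.

Example::

    model:
      rates: {kind: {value: BSE, unit: str}}
      rod:
        k_pos: {value: 2.0, unit: pN/nm}
      cycle:
        gamma: {value: 20.0, unit: "1"}
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .params import (CycleParams, ModelParams, MusAsiParams, TTParams,
                     default_model)
from .sarcomere_core import FreeEnergyLadder, RateModel, RodModel

__all__ = ["UNIT_MAP", "load_model", "dump_model", "ConfigError"]


class ConfigError(ValueError):
    pass


#: expected unit per (section, field)
UNIT_MAP = {
    ("rod", "k_pos"): "pN/nm", ("rod", "k_neg"): "pN/nm",
    ("rod", "kBT"): "pN*nm", ("rod", "x_min"): "nm", ("rod", "x_max"): "nm",
    ("ladder", "E0"): "pN*nm", ("ladder", "E1"): "pN*nm",
    ("ladder", "E2"): "pN*nm", ("ladder", "s1"): "nm", ("ladder", "s2"): "nm",
    ("rates", "kind"): "str", ("rates", "prefactors"): "1/s",
    ("rates", "r_max"): "1/s",
    ("cycle", "k_np0"): "1/s", ("cycle", "k_pn0"): "1/s",
    ("cycle", "k_attach"): "1/s", ("cycle", "k_detach"): "1/s",
    ("cycle", "k_cycle"): "1/s", ("cycle", "k_recover"): "1/s",
    ("cycle", "gamma"): "1", ("cycle", "perm_blocked"): "1",
    ("cycle", "molecules_per_tt"): "1",
    ("tt", "k_on_ca"): "1/(uM*s)", ("tt", "k_off_ca"): "1/s",
    ("tt", "k_open"): "1/s", ("tt", "k_close"): "1/s",
    ("tt", "hold_factor"): "1",
    ("geom", "SL0"): "nm", ("geom", "SA0"): "nm^2", ("geom", "RS"): "1",
    ("geom", "N_F"): "1", ("geom", "N_M"): "1",
    ("geom", "DT"): "ms", ("geom", "dt0"): "ms",
    ("geom", "include_RS_in_stiffness"): "bool",
}

_SECTIONS = {
    "rod": RodModel, "ladder": FreeEnergyLadder, "rates": RateModel,
    "cycle": CycleParams, "tt": TTParams, "geom": MusAsiParams,
}


def _read_leaf(section: str, field: str, leaf):
    key = (section, field)
    if key not in UNIT_MAP:
        raise ConfigError(f"unknown config key {section}.{field}")
    if not (isinstance(leaf, dict) and set(leaf) >= {"value", "unit"}):
        raise ConfigError(
            f"{section}.{field} must be a {{value, unit}} mapping")
    if leaf["unit"] != UNIT_MAP[key]:
        raise ConfigError(
            f"{section}.{field}: expected unit {UNIT_MAP[key]!r}, "
            f"got {leaf['unit']!r}")
    val = leaf["value"]
    if isinstance(val, list):
        return tuple(val)
    return val


def load_model(path) -> ModelParams:
    """Build a ModelParams bundle from a YAML (or JSON) config file.

    The file carries a top-level ``model`` mapping with any subset of the
    sections rod/ladder/rates/cycle/tt/geom; missing entries keep the
    package defaults.  A top-level ``kind: DSE|BSE`` shortcut applies the
    stroke-model flavour (including the BSE attachment-gate factor) before
    explicit overrides.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kind = data.get("kind", "DSE")
    model = default_model(kind=kind)
    overrides = data.get("model", {})
    if not isinstance(overrides, dict):
        raise ConfigError("'model' must be a mapping of sections")
    parts = {name: getattr(model, name) for name in _SECTIONS}
    for section, fields in overrides.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(fields, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kw = {f: _read_leaf(section, f, leaf) for f, leaf in fields.items()}
        kw.pop("ladder", None)
        parts[section] = dataclasses.replace(parts[section], **kw)
    parts["rates"] = dataclasses.replace(parts["rates"],
                                         ladder=parts["ladder"])
    return ModelParams(**parts)


def dump_model(model: ModelParams, path) -> None:
    """Write the full parameter set as a unit-annotated YAML file."""
    out = {"kind": model.rates.kind, "model": {}}
    for section in _SECTIONS:
        obj = getattr(model, section)
        sec = {}
        for f in dataclasses.fields(obj):
            if (section, f.name) not in UNIT_MAP:
                continue
            val = getattr(obj, f.name)
            if isinstance(val, tuple):
                val = list(val)
            sec[f.name] = {"value": val, "unit": UNIT_MAP[(section, f.name)]}
        out["model"][section] = sec
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
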
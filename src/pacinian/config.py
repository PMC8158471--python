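"""Reading and writing corpuscle design configurations (YAML or JSON).

A design file mirrors :class:`~pacinian.layer_parameters.CorpuscleDesign`;
quantities may carry units (``"5.5 MPa"``, ``"2 cm"``).  A file may also
simply name a preset::

    preset: printed
    n_layers: 3
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .layer_parameters import CoreCoefficients, CorpuscleDesign, MaterialSet
from .presets import get_preset
from .units import parse_quantity

__all__ = ["ConfigError", "load_design", "save_design", "design_to_dict"]

_MATERIAL_KEYS = {
    "lamella_modulus",
    "matrix_modulus",
    "fluid_viscosity",
    "lamella_density",
    "fluid_density",
}
_DESIGN_KEYS = {
    "core_radius",
    "n_layers",
    "lamella_thickness",
    "fluid_gap",
    "length",
    "core_modulus",
    "core_density",
    "matrix_enabled",
    "core_override",
    "name",
}


class ConfigError(ValueError):
    """A design config failed validation; the message names the field."""


def _parse_maybe_list(value, field):
    if isinstance(value, (list, tuple)):
        return [parse_quantity(v, field) for v in value]
    return parse_quantity(value, field)


def load_design(path) -> CorpuscleDesign:
    """Load and validate a design config, applying defaults.

    Raises :class:`ConfigError` naming the offending field for unknown
    keys, bad units or invariant violations.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")

    if "preset" in raw:
        name = raw.pop("preset")
        design = get_preset(name, raw.pop("n_layers", None))
        if raw:
            raise ConfigError(
                f"unsupported keys alongside 'preset': {sorted(raw)}"
            )
        return design

    unknown = set(raw) - _DESIGN_KEYS - {"materials"}
    if unknown:
        raise ConfigError(f"unknown keys: {sorted(unknown)}")
    missing = {"core_radius", "n_layers", "lamella_thickness", "fluid_gap", "length"} - set(raw)
    if missing:
        raise ConfigError(f"missing required keys: {sorted(missing)}")

    mat_raw = raw.get("materials")
    if not isinstance(mat_raw, dict):
        raise ConfigError("materials: required mapping is missing")
    unknown = set(mat_raw) - _MATERIAL_KEYS
    if unknown:
        raise ConfigError(f"materials: unknown keys {sorted(unknown)}")
    try:
        materials = MaterialSet(
            **{k: parse_quantity(v, k) for k, v in mat_raw.items()}
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"materials: {exc}") from exc

    kwargs = dict(
        core_radius=parse_quantity(raw["core_radius"], "core_radius"),
        n_layers=int(raw["n_layers"]),
        lamella_thickness=_parse_maybe_list(raw["lamella_thickness"], "lamella_thickness"),
        fluid_gap=_parse_maybe_list(raw["fluid_gap"], "fluid_gap"),
        length=parse_quantity(raw["length"], "length"),
        materials=materials,
        matrix_enabled=bool(raw.get("matrix_enabled", True)),
        name=str(raw.get("name", path.stem)),
    )
    for opt in ("core_modulus", "core_density"):
        if raw.get(opt) is not None:
            kwargs[opt] = parse_quantity(raw[opt], opt)
    if raw.get("core_override") is not None:
        co = raw["core_override"]
        try:
            kwargs["core_override"] = CoreCoefficients(**{
                k: parse_quantity(v, f"core_override.{k}") for k, v in co.items()
            })
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"core_override: {exc}") from exc
    try:
        return CorpuscleDesign(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def design_to_dict(design: CorpuscleDesign) -> dict:
    """Plain-SI dictionary representation (round-trips via load_design)."""
    d = asdict(design)
    if d.get("core_override") is None:
        d.pop("core_override", None)
    for opt in ("core_modulus", "core_density"):
        if d.get(opt) is None:
            d.pop(opt, None)
    for attr in ("lamella_thickness", "fluid_gap"):
        if isinstance(d[attr], tuple):
            d[attr] = list(d[attr])
    return d


def save_design(design: CorpuscleDesign, path) -> None:
    """Write a design as YAML or JSON (by extension), strict SI values."""
    path = Path(path)
    d = design_to_dict(design)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
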
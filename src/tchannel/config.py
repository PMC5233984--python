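"""Configuration loading: one YAML/JSON document -> typed scenario objects.

Sections: ``grid`` (spacing, optionally explicit origin/shape), ``head``,
``channel``, ``montage``, ``conductivity`` (tissue name -> S/m),
``solver``, ``roi``, ``membrane``.  Unknown sections or keys are rejected
so that typos fail loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .cable import MembraneParams
from .geometry import ChannelSpec, HeadParams, MontageSpec, default_grid
from .grid import ConductivityMap, GridSpec, TissueLabel
from .morphology import MorphParams, ROISpec
from .solver import SolverConfig


class ConfigError(ValueError):
    pass


def _from_dict(cls, d: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in d.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass
class Scenario:
    """Fully resolved single-configuration setup."""

    spacing: float = 0.5
    head: HeadParams = dc_field(default_factory=HeadParams)
    channel: ChannelSpec = dc_field(default_factory=ChannelSpec)
    montage: MontageSpec = dc_field(default_factory=MontageSpec)
    conductivity: ConductivityMap = dc_field(default_factory=ConductivityMap)
    solver: SolverConfig = dc_field(default_factory=SolverConfig)
    roi: ROISpec = dc_field(default_factory=ROISpec)
    membrane: MembraneParams = dc_field(default_factory=MembraneParams)
    morphology: MorphParams = dc_field(default_factory=MorphParams)
    grid_override: GridSpec | None = None

    def grid_spec(self) -> GridSpec:
        return self.grid_override or default_grid(self.head, self.spacing)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    (k.name.lower() if isinstance(k, TissueLabel) else k): enc(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, (int, float, str)) or obj is None:
                return obj
            return str(obj)

        return {
            "spacing": self.spacing,
            "head": enc(self.head),
            "channel": enc(self.channel),
            "montage": enc(self.montage),
            "conductivity": {lab.name.lower(): sig for lab, sig in self.conductivity.values.items()},
            "solver": enc(self.solver),
            "roi": enc(self.roi),
            "membrane": enc(self.membrane),
            "morphology": enc(self.morphology),
        }


_SECTIONS = {
    "head": (HeadParams, "head"),
    "channel": (ChannelSpec, "channel"),
    "montage": (MontageSpec, "montage"),
    "solver": (SolverConfig, "solver"),
    "roi": (ROISpec, "roi"),
    "membrane": (MembraneParams, "membrane"),
    "morphology": (MorphParams, "morphology"),
}


def scenario_from_dict(doc: dict) -> Scenario:
    doc = dict(doc or {})
    known = set(_SECTIONS) | {"grid", "conductivity"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    kwargs: dict = {}
    gsec = dict(doc.pop("grid", {}) or {})
    bad = set(gsec) - {"spacing", "origin", "shape"}
    if bad:
        raise ConfigError(f"unknown keys in section 'grid': {sorted(bad)}")
    if "spacing" in gsec:
        kwargs["spacing"] = float(gsec["spacing"])
    if "origin" in gsec or "shape" in gsec:
        if not ("origin" in gsec and "shape" in gsec):
            raise ConfigError("grid origin and shape must be given together")
        kwargs["grid_override"] = GridSpec(
            origin=tuple(gsec["origin"]),
            spacing=float(gsec.get("spacing", 0.5)),
            shape=tuple(gsec["shape"]),
        )

    csec = doc.pop("conductivity", None)
    if csec is not None:
        values = {}
        for name, sig in csec.items():
            try:
                values[TissueLabel[name.upper()]] = float(sig)
            except KeyError:
                raise ConfigError(f"unknown tissue {name!r} in 'conductivity'") from None
        kwargs["conductivity"] = ConductivityMap(values)

    for key, (cls, label) in _SECTIONS.items():
        if key in doc:
            kwargs[key] = _from_dict(cls, dict(doc[key] or {}), label)
    return Scenario(**kwargs)


def load_scenario(path) -> Scenario:
    """Read a YAML (or JSON) scenario document."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return scenario_from_dict(doc or {})
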
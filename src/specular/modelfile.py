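"""Declarative model files.

A model file is YAML mirroring the in-memory hierarchy: a list of patches
(each a coverage plus six-element layer rows), parameter declarations,
optional multi-parameters, constraints, instrument settings and a
``values`` block for plain forward calculations.  Layer rows are
``[sld_re, sld_im, thickness, roughness, solvent_frac, description]`` where
any entry but the description may be an expression string.

Example::

    patches:
      - coverage: 1.0
        layers:
          - [0.0,     0.0, 0,  3, 0, air]
          - [8.02e-6, 0.0, 40, 3, 0, Fe]
          - [1.24e-5, 0.0, 60, 3, 0, Au]
          - [2.07e-6, 0.0, 0,  0, 0, Si]
    instrument: {dq_q: 0.01, background: 1.0e-9, scale: 1.0}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import InstrumentSettings
from .model import (
    Constraint,
    Layer,
    ModelDefinitionError,
    MultiParameter,
    Parameter,
    ParameterSet,
    Patch,
    SystemModel,
)

__all__ = ["ModelFile", "load_model"]


class ModelFile:
    """Everything a model file declares, as package objects."""

    def __init__(self, system, params, constraints, settings, values):
        self.system: SystemModel = system
        self.params: ParameterSet = params
        self.constraints: list[Constraint] = constraints
        self.settings: list[InstrumentSettings] = settings
        self.values: dict = values


def _layer_from_row(row) -> Layer:
    if not isinstance(row, (list, tuple)) or len(row) != 6:
        raise ModelDefinitionError(
            f"layer row must have six elements "
            f"[sld_re, sld_im, thickness, roughness, solvent_frac, description]: {row!r}"
        )
    return Layer(*row[:5], description=str(row[5]))


def load_model(path) -> ModelFile:
    """Parse a YAML model file into a :class:`ModelFile`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "patches" not in doc:
        raise ModelDefinitionError(f"{path}: model file needs a 'patches' block")
    patches = []
    for entry in doc["patches"]:
        layers = [_layer_from_row(row) for row in entry["layers"]]
        patches.append(Patch(layers=layers, coverage=float(entry.get("coverage", 1.0))))
    system = SystemModel(patches=tuple(patches))

    parameters = [
        Parameter(
            name=p["name"],
            kind=p.get("kind", "uniform"),
            bound1=float(p["bounds"][0]),
            bound2=float(p["bounds"][1]),
            description=p.get("description", ""),
        )
        for p in doc.get("parameters", [])
    ]
    multi = [
        MultiParameter(
            name=m["name"],
            per_curve=tuple((t[0], float(t[1]), float(t[2])) for t in m["per_curve"]),
        )
        for m in doc.get("multi_parameters", [])
    ]
    params = ParameterSet(parameters=parameters, multi_parameters=multi)
    constraints = [Constraint(c) for c in doc.get("constraints", [])]

    instr = doc.get("instrument", {})
    if isinstance(instr, dict):
        instr = [instr]
    settings = [
        InstrumentSettings(
            dq_q=float(s.get("dq_q", 0.0)),
            background=float(s.get("background", 0.0)),
            scale=float(s.get("scale", 1.0)),
        )
        for s in instr
    ]
    values = dict(doc.get("values", {}))
    return ModelFile(system, params, constraints, settings, values)
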
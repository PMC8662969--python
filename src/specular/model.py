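"""Hierarchical interfacial model definition.

An interfacial hypothesis is a :class:`SystemModel`: a list of laterally
macroscopic :class:`Patch` regions that contribute incoherently to the
reflectivity, each patch an ordered stack of :class:`Layer` slabs from the
fronting medium (index 0) to the backing medium (index N+1).  Every layer
entry (real/imaginary scattering length density, thickness, roughness,
solvent volume fraction) may be a plain number or a symbolic expression in
named parameters and the reserved layer-index symbol ``n``.

Parameters are declared separately (:class:`Parameter`,
:class:`MultiParameter`) with either uniform bounds or a normal prior;
inequality :class:`Constraint` expressions between parameters restrict the
admissible parameter space during refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr

__all__ = [
    "ModelDefinitionError",
    "EvaluationError",
    "Parameter",
    "MultiParameter",
    "Layer",
    "Patch",
    "Constraint",
    "SystemModel",
    "ParameterSet",
    "ResolvedPatch",
    "CompiledSystem",
    "LAYER_INDEX_SYMBOL",
    "evaluate_entry",
    "resolve_system",
    "check_constraints",
]


class ModelDefinitionError(ValueError):
    """An interfacial model or parameter declaration is inconsistent."""


class EvaluationError(ValueError):
    """A symbolic layer entry failed to evaluate to a finite number."""


#: Reserved symbol denoting a layer's ordinal within its patch
#: (0 = fronting medium, N+1 = backing medium).
LAYER_INDEX_SYMBOL = "n"

# Mathematical vocabulary permitted inside layer/constraint expressions.
# Deliberately restricted: no attribute access, no general code execution.
_ALLOWED_FUNCS = {
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "asin": sp.asin,
    "acos": sp.acos,
    "atan": sp.atan,
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "erf": sp.erf,
    "abs": sp.Abs,
    "Abs": sp.Abs,
    "min": sp.Min,
    "max": sp.Max,
    "Min": sp.Min,
    "Max": sp.Max,
    "pi": sp.pi,
    "E": sp.E,
}


def parse_entry(entry):
    """Parse a layer entry into a number or a sympy expression.

    Numbers pass through; strings and sympy expressions are parsed against
    the restricted mathematical vocabulary.
    """
    if isinstance(entry, (int, float)):
        return float(entry)
    if isinstance(entry, sp.Expr):
        return sp.sympify(entry)
    if isinstance(entry, str):
        try:
            expr = parse_expr(entry, local_dict=dict(_ALLOWED_FUNCS), evaluate=True)
        except Exception as exc:  # sympy raises a zoo of exception types
            raise ModelDefinitionError(f"cannot parse expression {entry!r}: {exc}") from exc
        if expr.free_symbols:
            return expr
        return float(expr)
    raise ModelDefinitionError(f"unsupported entry type {type(entry).__name__!r}")


@lru_cache(maxsize=4096)
def _compiled(expr_srepr: str, names: tuple[str, ...]):
    """Lambdified numeric evaluator for *expr* over (n, *names)."""
    expr = sp.sympify(expr_srepr)
    symbols = [sp.Symbol(LAYER_INDEX_SYMBOL)] + [sp.Symbol(p) for p in names]
    return sp.lambdify(symbols, expr, modules=["math"])


def evaluate_entry(entry, params: Mapping[str, float], layer_index: int = 0) -> float:
    """Evaluate one layer entry to a number.

    Parameters
    ----------
    entry
        A number, an expression string, or a sympy expression.  Free symbols
        must be declared parameter names or the layer-index symbol ``n``.
    params
        Mapping of parameter name to numeric value.
    layer_index
        Value substituted for the reserved symbol ``n``.

    Raises
    ------
    ModelDefinitionError
        If the entry references an undeclared symbol.
    EvaluationError
        If the entry evaluates to a non-finite number.
    """
    parsed = parse_entry(entry)
    if isinstance(parsed, float):
        return parsed
    free = sorted(str(s) for s in parsed.free_symbols)
    undeclared = [s for s in free if s != LAYER_INDEX_SYMBOL and s not in params]
    if undeclared:
        raise ModelDefinitionError(
            f"expression {sp.sstr(parsed)!r} references undeclared parameter(s): "
            + ", ".join(undeclared)
        )
    names = tuple(s for s in free if s != LAYER_INDEX_SYMBOL)
    fn = _compiled(sp.srepr(parsed), names)
    try:
        value = float(fn(layer_index, *(params[p] for p in names)))
    except Exception as exc:
        raise EvaluationError(
            f"expression {sp.sstr(parsed)!r} failed at layer {layer_index}: {exc}"
        ) from exc
    if not math.isfinite(value):
        raise EvaluationError(
            f"expression {sp.sstr(parsed)!r} is non-finite at layer {layer_index}"
        )
    return value


# ---------------------------------------------------------------------------
# Parameter declarations
# ---------------------------------------------------------------------------

_KINDS = ("uniform", "normal", "fixed")


@dataclass(frozen=True)
class Parameter:
    """A named global parameter with a uniform bound or normal prior.

    ``kind='uniform'``: *bound1*/*bound2* are min/max; equal values mean the
    parameter is fixed.  ``kind='normal'``: *bound1*/*bound2* are mean and
    standard deviation; zero sd means fixed.  ``kind='fixed'``: pinned at
    *bound1*.
    """

    name: str
    kind: str
    bound1: float
    bound2: float
    description: str = ""

    def __post_init__(self):
        if not self.name.isidentifier():
            raise ModelDefinitionError(f"parameter name {self.name!r} is not an identifier")
        if self.name == LAYER_INDEX_SYMBOL:
            raise ModelDefinitionError(
                f"parameter name {self.name!r} collides with the layer-index symbol"
            )
        if self.kind not in _KINDS:
            raise ModelDefinitionError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "uniform" and self.bound1 > self.bound2:
            raise ModelDefinitionError(
                f"parameter {self.name!r}: min bound {self.bound1} > max bound {self.bound2}"
            )
        if self.kind == "normal" and self.bound2 < 0:
            raise ModelDefinitionError(
                f"parameter {self.name!r}: negative standard deviation {self.bound2}"
            )

    @property
    def is_fixed(self) -> bool:
        if self.kind == "fixed":
            return True
        if self.kind == "uniform":
            return self.bound1 == self.bound2
        return self.bound2 == 0.0

    @property
    def fixed_value(self) -> float:
        if not self.is_fixed:
            raise ValueError(f"parameter {self.name!r} is free")
        return self.bound1


@dataclass(frozen=True)
class MultiParameter:
    """A parameter taking a distinct value (or prior) per co-refined curve.

    The canonical uses are the solvent sld of each contrast in a
    contrast-variation series and the ±magnetic sld of each polarization in
    non-spin-flip polarized reflectometry.
    """

    name: str
    per_curve: tuple  # of (kind, bound1, bound2) triples, one per curve

    def __post_init__(self):
        object.__setattr__(self, "per_curve", tuple(tuple(t) for t in self.per_curve))
        if not self.per_curve:
            raise ModelDefinitionError(f"multi-parameter {self.name!r} declares no curves")
        for i, (kind, b1, b2) in enumerate(self.per_curve):
            Parameter(self.name, kind, b1, b2)  # reuse validation

    @property
    def n_curves(self) -> int:
        return len(self.per_curve)

    def triple(self, curve_index: int) -> tuple:
        return self.per_curve[curve_index]


@dataclass(frozen=True)
class Layer:
    """One slab: (sld_re, sld_im, thickness, roughness, solvent_frac, description).

    sld entries are in Å⁻², thickness and roughness in Å.  The roughness of
    layer *i* refers to the interface between layers *i* and *i*+1.  Any
    entry except the description may be symbolic.
    """

    sld_re: object = 0.0
    sld_im: object = 0.0
    thickness: object = 0.0
    roughness: object = 0.0
    solvent_frac: object = 0.0
    description: str = ""


@dataclass(frozen=True)
class Patch:
    """An ordered layer stack with an associated surface coverage.

    The first and last layers are the semi-infinite fronting and backing
    media; their thickness entries are stored but ignored.
    """

    layers: tuple
    coverage: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 2:
            raise ModelDefinitionError(
                f"a patch needs at least fronting and backing media, got {len(self.layers)} layer(s)"
            )
        if not 0.0 <= self.coverage <= 1.0:
            raise ModelDefinitionError(f"coverage {self.coverage} outside [0, 1]")

    @property
    def n_interior(self) -> int:
        return len(self.layers) - 2


@dataclass(frozen=True)
class Constraint:
    """An inequality between declared parameters, e.g. ``1 - V/(A*t) > 0``."""

    expression: object

    def parsed(self) -> sp.Rel:
        expr = self.expression
        if isinstance(expr, str):
            try:
                expr = parse_expr(expr, local_dict=dict(_ALLOWED_FUNCS), evaluate=False)
            except Exception as exc:
                raise ModelDefinitionError(
                    f"cannot parse constraint {self.expression!r}: {exc}"
                ) from exc
        if not isinstance(expr, sp.Rel):
            raise ModelDefinitionError(
                f"constraint {self.expression!r} is not an inequality"
            )
        return expr


@dataclass(frozen=True)
class SystemModel:
    """The full interfacial hypothesis: patches with coverages summing to 1."""

    patches: tuple

    def __post_init__(self):
        object.__setattr__(self, "patches", tuple(self.patches))
        if not self.patches:
            raise ModelDefinitionError("a system needs at least one patch")
        total = sum(p.coverage for p in self.patches)
        if abs(total - 1.0) > 1e-9:
            raise ModelDefinitionError(f"patch coverages sum to {total}, expected 1")

    @property
    def coverages(self) -> list[float]:
        return [p.coverage for p in self.patches]


@dataclass
class ResolvedPatch:
    """Numeric per-layer arrays of one patch (solvent mixing not yet applied)."""

    sld_re: list
    sld_im: list
    thickness: list
    roughness: list
    solvent_frac: list
    coverage: float
    descriptions: list = field(default_factory=list)


def _curve_value(value, curve_index: int) -> float:
    """A parameter value may be a scalar or a per-curve sequence."""
    if isinstance(value, (list, tuple)):
        return float(value[curve_index])
    return float(value)


_FIELDS = ("sld_re", "sld_im", "thickness", "roughness", "solvent_frac")


class CompiledSystem:
    """A :class:`SystemModel` with every symbolic entry pre-lambdified.

    Parsing and lambdification happen once at construction; ``resolve`` is
    then a cheap sequence of compiled-function calls, which matters inside
    differential-evolution and MCMC loops.
    """

    def __init__(self, model: SystemModel):
        self.model = model
        self._patches = []
        for patch in model.patches:
            entries = []
            for il, layer in enumerate(patch.layers):
                row = []
                for key in _FIELDS:
                    parsed = parse_entry(getattr(layer, key))
                    if isinstance(parsed, float):
                        row.append(parsed)
                    else:
                        free = sorted(str(s) for s in parsed.free_symbols)
                        names = tuple(s for s in free if s != LAYER_INDEX_SYMBOL)
                        fn = _compiled(sp.srepr(parsed), names)
                        row.append((fn, names, sp.sstr(parsed)))
                entries.append((row, layer.description))
            self._patches.append((entries, patch.coverage))

    def resolve(self, flat: Mapping[str, float]) -> list[ResolvedPatch]:
        """Numeric patch profiles for a flat name→scalar parameter map."""
        resolved = []
        for ip, (entries, coverage) in enumerate(self._patches):
            cols = {k: [] for k in _FIELDS}
            descriptions = []
            last = len(entries) - 1
            for il, (row, description) in enumerate(entries):
                for key, item in zip(_FIELDS, row):
                    if isinstance(item, float):
                        value = item
                    else:
                        fn, names, text = item
                        try:
                            value = float(fn(il, *(flat[p] for p in names)))
                        except KeyError as exc:
                            raise ModelDefinitionError(
                                f"expression {text!r} references undeclared parameter: {exc.args[0]}"
                            ) from exc
                        except Exception as exc:
                            raise EvaluationError(
                                f"expression {text!r} failed at layer {il}: {exc}"
                            ) from exc
                        if not math.isfinite(value):
                            raise EvaluationError(
                                f"expression {text!r} is non-finite at layer {il}"
                            )
                    cols[key].append(value)
                descriptions.append(description)
                if 0 < il < last and cols["thickness"][-1] < 0:
                    raise ModelDefinitionError(
                        f"patch {ip}, layer {il}: negative thickness {cols['thickness'][-1]}"
                    )
                if cols["roughness"][-1] < 0:
                    raise ModelDefinitionError(
                        f"patch {ip}, layer {il}: negative roughness {cols['roughness'][-1]}"
                    )
            resolved.append(
                ResolvedPatch(
                    coverage=coverage,
                    descriptions=descriptions,
                    **cols,
                )
            )
        return resolved


@lru_cache(maxsize=64)
def _compiled_system(model: SystemModel) -> CompiledSystem:
    return CompiledSystem(model)


def resolve_system(
    model: SystemModel,
    values: Mapping[str, object],
    curve_index: int = 0,
) -> list[ResolvedPatch]:
    """Resolve every symbolic layer entry to a number.

    *values* maps each parameter name to a scalar, or — for a
    multi-parameter — to a sequence indexed by *curve_index*.  Solvent
    mixing is **not** applied here; the reflectivity engine does that.

    Raises :class:`ModelDefinitionError` for negative resolved thickness or
    roughness of interior layers.
    """
    flat = {name: _curve_value(v, curve_index) for name, v in values.items()}
    return _compiled_system(model).resolve(flat)


def check_constraints(
    constraints: Sequence[Constraint],
    values: Mapping[str, object],
    curve_index: int = 0,
) -> bool:
    """True iff every inequality holds for the given parameter values."""
    flat = {name: _curve_value(v, curve_index) for name, v in values.items()}
    for constraint in constraints:
        rel = constraint.parsed()
        free = sorted(str(s) for s in rel.free_symbols)
        missing = [s for s in free if s not in flat]
        if missing:
            raise ModelDefinitionError(
                f"constraint {sp.sstr(rel)!r} references undeclared parameter(s): "
                + ", ".join(missing)
            )
        subs = {sp.Symbol(s): flat[s] for s in free}
        result = rel.subs(subs)
        if result not in (sp.true, True):
            if result in (sp.false, False):
                return False
            raise ModelDefinitionError(f"constraint {sp.sstr(rel)!r} did not evaluate to a truth value")
    return True


# ---------------------------------------------------------------------------
# Parameter set: the refinement-facing view of all declarations
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Global parameters plus per-curve multi-parameters.

    Provides the mapping between the flat free-parameter vector seen by
    optimizers/samplers and the name→value dictionaries consumed by
    :func:`resolve_system`.  Each free per-curve triple of a multi-parameter
    counts as its own entry in the vector.
    """

    parameters: list = field(default_factory=list)
    multi_parameters: list = field(default_factory=list)

    def __post_init__(self):
        names = [p.name for p in self.parameters] + [m.name for m in self.multi_parameters]
        if len(set(names)) != len(names):
            raise ModelDefinitionError("duplicate parameter names in ParameterSet")

    @property
    def n_curves(self) -> int:
        if not self.multi_parameters:
            return 1
        counts = {m.n_curves for m in self.multi_parameters}
        if len(counts) != 1:
            raise ModelDefinitionError(
                f"multi-parameters declare inconsistent curve counts: {sorted(counts)}"
            )
        return counts.pop()

    def free_entries(self) -> list:
        """Ordered (label, kind, b1, b2, setter-key) records of free entries.

        Labels are ``name`` for globals and ``name[i]`` for the i-th curve
        triple of a multi-parameter.
        """
        entries = []
        for p in self.parameters:
            if not p.is_fixed:
                entries.append((p.name, p.kind, p.bound1, p.bound2, (p.name, None)))
        for m in self.multi_parameters:
            for i, (kind, b1, b2) in enumerate(m.per_curve):
                if not Parameter(m.name, kind, b1, b2).is_fixed:
                    entries.append((f"{m.name}[{i}]", kind, b1, b2, (m.name, i)))
        return entries

    @property
    def n_free(self) -> int:
        return len(self.free_entries())

    def values_from_vector(self, x) -> dict:
        """Expand a free-parameter vector into the full name→value mapping.

        Multi-parameter values come out as per-curve lists, ready for
        :func:`resolve_system`'s *curve_index* selection.
        """
        values: dict = {}
        for p in self.parameters:
            values[p.name] = p.bound1 if p.is_fixed else None
        for m in self.multi_parameters:
            values[m.name] = [
                b1 if Parameter(m.name, kind, b1, b2).is_fixed else None
                for kind, b1, b2 in m.per_curve
            ]
        for xi, (_, _, _, _, (name, idx)) in zip(x, self.free_entries()):
            if idx is None:
                values[name] = float(xi)
            else:
                values[name][idx] = float(xi)
        return values

    def search_bounds(self) -> list[tuple[float, float]]:
        """Box bounds for each free entry.

        Uniform entries use their declared min/max; normal entries are
        searched within mean ± 5 sd (the prior itself is enforced as an
        additive Gaussian penalty during fitting).
        """
        bounds = []
        for _, kind, b1, b2, _ in self.free_entries():
            if kind == "normal":
                bounds.append((b1 - 5.0 * b2, b1 + 5.0 * b2))
            else:
                bounds.append((b1, b2))
        return bounds

    def normal_penalty(self, x) -> float:
        """Σ ((x−μ)/sd)² over free normally-declared entries."""
        penalty = 0.0
        for xi, (_, kind, b1, b2, _) in zip(x, self.free_entries()):
            if kind == "normal":
                penalty += ((xi - b1) / b2) ** 2
        return penalty
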
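"""Figures of merit and differential-evolution refinement.

Single- and multi-curve co-refinement of a :class:`~specular.model.SystemModel`
against measured reflectivity.  Four figures of merit are offered, on the
linear or log₁₀ scale, with or without experimental errors::

    linear_err   Σᵢ wᵢ (1/pᵢ) Σⱼ ((R_e − R_m)/δR)²
    log_err      Σᵢ wᵢ (1/pᵢ) Σⱼ ((log₁₀R_e − log₁₀R_m) R_e ln10 / δR)²
    linear_noerr Σᵢ wᵢ (1/pᵢ) Σⱼ (R_e − R_m)²/R_e
    log_noerr    Σᵢ wᵢ (1/pᵢ) Σⱼ (log₁₀R_e − log₁₀R_m)²

where wᵢ is the fit weight of curve i and pᵢ its point count (per-point
normalization keeps long curves from dominating a co-refinement).  The
log-with-errors denominator follows Gaussian error propagation,
δ(log₁₀R)² = [δR/(R ln 10)]².

Minimization uses scipy's differential evolution.  Candidates violating an
inequality constraint, or resolving to a solvent fraction outside [0, 1],
receive a large finite penalty (never NaN); free parameters declared with a
normal prior are searched within mean ± 5 sd and add a Gaussian penalty
((x − μ)/sd)² to the objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.optimize import differential_evolution

from .data import Curve
from .engine import InstrumentSettings, abeles_reflectivity, finalize, mix_patches, patch_slabs, smear
from .model import (
    CompiledSystem,
    Constraint,
    EvaluationError,
    ModelDefinitionError,
    ParameterSet,
    SystemModel,
)

__all__ = ["FomSpec", "FitResult", "Objective", "compute_fom", "chi2_red", "fit", "PENALTY"]

logger = logging.getLogger("specular")

#: Finite objective value assigned to constraint-violating candidates.
PENALTY = 1.0e10

_MODES = ("linear_err", "log_err", "linear_noerr", "log_noerr")


@dataclass
class FomSpec:
    """Figure-of-merit selection plus per-curve fit weights."""

    mode: str = "log_err"
    weights: Sequence[float] | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown FOM mode {self.mode!r}; choose from {_MODES}")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise ValueError("fit weights must be positive")


def _curve_weights(curves: Sequence[Curve], spec: FomSpec) -> list[float]:
    if spec.weights is not None:
        if len(spec.weights) != len(curves):
            raise ValueError("one weight per curve required")
        return [float(w) for w in spec.weights]
    return [float(c.fit_weight) for c in curves]


def compute_fom(curves: Sequence[Curve], models: Sequence[np.ndarray], spec: FomSpec) -> float:
    """Evaluate the selected figure of merit.

    Model arrays must already be evaluated on each curve's Q grid, smeared
    and finalized.  In the log and 1/R-weighted modes, data points with
    non-positive R_e are dropped (with a logged count); non-positive model
    values are floored at 1e−300 so the log residual stays finite and large.
    """
    if len(curves) != len(models):
        raise ValueError("one model array per curve required")
    if spec.mode.endswith("_err") and not all(c.has_errors for c in curves):
        raise ValueError(f"FOM mode {spec.mode!r} requires a δR column on every curve")
    weights = _curve_weights(curves, spec)
    total = 0.0
    for curve, model, w in zip(curves, models, weights):
        R_e = curve.R
        R_m = np.asarray(model, dtype=float)
        if R_m.shape != R_e.shape:
            raise ValueError("model array length does not match curve")
        if spec.mode == "linear_err":
            terms = ((R_e - R_m) / curve.dR) ** 2
        else:
            keep = R_e > 0
            dropped = int((~keep).sum())
            if dropped:
                logger.warning(
                    "%s: dropped %d non-positive R points for mode %s",
                    curve.source_path or "curve",
                    dropped,
                    spec.mode,
                )
            R_e_k = R_e[keep]
            R_m_k = np.maximum(R_m[keep], 1e-300)
            if spec.mode == "log_err":
                dlog = np.log10(R_e_k) - np.log10(R_m_k)
                terms = (dlog * R_e_k * math.log(10.0) / curve.dR[keep]) ** 2
            elif spec.mode == "linear_noerr":
                terms = (R_e_k - R_m[keep]) ** 2 / R_e_k
            else:  # log_noerr
                terms = (np.log10(R_e_k) - np.log10(R_m_k)) ** 2
        total += w * float(np.sum(terms)) / curve.n_points
    return total


def chi2_red(curves: Sequence[Curve], models: Sequence[np.ndarray], n_free: int) -> float | None:
    """Reduced χ² = Σᵢⱼ ((R_e − R_m)/δR)² / (N − |α|); None without δR."""
    if not all(c.has_errors for c in curves):
        return None
    chi2 = 0.0
    n_tot = 0
    for curve, model in zip(curves, models):
        chi2 += float(np.sum(((curve.R - np.asarray(model)) / curve.dR) ** 2))
        n_tot += curve.n_points
    dof = max(n_tot - n_free, 1)
    return chi2 / dof


# ---------------------------------------------------------------------------
# Objective: vector -> penalized FOM
# ---------------------------------------------------------------------------


class _CompiledConstraint:
    def __init__(self, constraint: Constraint):
        rel = constraint.parsed()
        self.text = sp.sstr(rel)
        self.names = sorted(str(s) for s in rel.free_symbols)
        fn = sp.lambdify([sp.Symbol(s) for s in self.names], rel.lhs - rel.rhs, modules=["math"])
        op = rel.rel_op
        if op in (">", ">="):
            self._ok = (lambda v: v > 0) if op == ">" else (lambda v: v >= 0)
            self._fn = fn
        elif op in ("<", "<="):
            self._ok = (lambda v: v < 0) if op == "<" else (lambda v: v <= 0)
            self._fn = fn
        else:
            raise ModelDefinitionError(f"constraint {self.text!r} must be an inequality")

    def holds(self, flat: dict) -> bool:
        try:
            value = self._fn(*(flat[s] for s in self.names))
        except KeyError as exc:
            raise ModelDefinitionError(
                f"constraint {self.text!r} references undeclared parameter: {exc.args[0]}"
            ) from exc
        return bool(self._ok(value))


class Objective:
    """Maps a free-parameter vector to per-curve model arrays and a FOM.

    Shared by the DE minimizer, the bootstrap re-fits, the Hessian
    curvature estimate and the MCMC likelihood, so all uncertainty methods
    see exactly the objective that was minimized.
    """

    def __init__(
        self,
        model: SystemModel,
        params: ParameterSet,
        constraints: Sequence[Constraint],
        curves: Sequence[Curve],
        spec: FomSpec | None = None,
        settings: Sequence[InstrumentSettings] | InstrumentSettings | None = None,
        solvent_from_fronting: bool = False,
    ):
        self.model = model
        self.params = params
        self.curves = list(curves)
        self.compiled = CompiledSystem(model)
        self.constraints = [_CompiledConstraint(c) for c in (constraints or [])]
        self.solvent_from_fronting = solvent_from_fronting

        if params.multi_parameters and params.n_curves != len(self.curves):
            raise ModelDefinitionError(
                f"multi-parameters declare {params.n_curves} curves, got {len(self.curves)}"
            )
        spec = spec or FomSpec()
        if spec.mode.endswith("_err") and not all(c.has_errors for c in self.curves):
            fallback = spec.mode.replace("_err", "_noerr")
            logger.warning(
                "FOM mode %s requires δR on every curve; falling back to %s", spec.mode, fallback
            )
            spec = FomSpec(mode=fallback, weights=spec.weights)
        self.spec = spec

        if settings is None:
            settings = InstrumentSettings()
        if isinstance(settings, InstrumentSettings):
            settings = [settings] * len(self.curves)
        if len(settings) != len(self.curves):
            raise ValueError("one InstrumentSettings per curve required")
        self.settings = []
        for s, c in zip(settings, self.curves):
            s.validate()
            if c.dQ is not None and s.dq_fwhm is None:
                s = InstrumentSettings(
                    dq_q=s.dq_q, background=s.background, scale=s.scale, dq_fwhm=c.dQ
                )
            self.settings.append(s)

        self._entries = params.free_entries()
        if not self._entries:
            raise ModelDefinitionError("no free parameters to refine")
        self.labels = [e[0] for e in self._entries]
        self.bounds = params.search_bounds()

    @property
    def n_free(self) -> int:
        return len(self._entries)

    def flat_values(self, x, curve_index: int) -> dict:
        values = self.params.values_from_vector(x)
        return {
            name: (float(v[curve_index]) if isinstance(v, list) else float(v))
            for name, v in values.items()
        }

    def constraints_ok(self, x) -> bool:
        if not self.constraints:
            return True
        for i in range(len(self.curves)):
            flat = self.flat_values(x, i)
            if not all(c.holds(flat) for c in self.constraints):
                return False
        return True

    def model_curves(self, x) -> list[np.ndarray]:
        """Smeared, finalized model reflectivity on each curve's Q grid.

        Raises ModelDefinitionError/EvaluationError for unphysical
        candidates (the penalized ``fom`` path catches these).
        """
        out = []
        for i, (curve, settings) in enumerate(zip(self.curves, self.settings)):
            patches = self.compiled.resolve(self.flat_values(x, i))
            slabs = [patch_slabs(p, self.solvent_from_fronting) for p in patches]
            coverages = [p.coverage for p in patches]

            def unsmeared(q, slabs=slabs, coverages=coverages):
                return mix_patches(
                    [abeles_reflectivity(s, d, sig, q) for s, d, sig in slabs], coverages
                )

            out.append(finalize(smear(curve.Q, unsmeared, settings), settings))
        return out

    def fom(self, x) -> float:
        """Penalized figure of merit: the DE/bootstrap objective."""
        if not self.constraints_ok(x):
            return PENALTY
        try:
            models = self.model_curves(x)
        except (ModelDefinitionError, EvaluationError, ValueError):
            return PENALTY
        value = compute_fom(self.curves, models, self.spec)
        if not math.isfinite(value):
            return PENALTY
        return value + self.params.normal_penalty(x)

    def chi2_red(self, x) -> float | None:
        """Reduced χ² of the candidate (no prior penalty)."""
        try:
            models = self.model_curves(x)
        except (ModelDefinitionError, EvaluationError, ValueError):
            return None
        return chi2_red(self.curves, models, self.n_free)

    def chi2_full(self, x) -> float:
        """Unreduced χ² = Σᵢⱼ ((R_e − R_m)/δR)²: the Hessian-curvature
        landscape (its curvature is dof × that of the reduced χ²)."""
        dof = max(sum(c.n_points for c in self.curves) - self.n_free, 1)
        value = self.chi2_red(x)
        if value is None:
            raise ValueError("χ² requires δR on every curve")
        return value * dof


@dataclass
class FitResult:
    """Outcome of a refinement."""

    best_values: dict
    best_vector: np.ndarray
    best_values_flat: dict
    free_names: list
    bounds: dict
    fom_min: float
    chi2_red: float | None
    n_free: int
    per_curve_model: list
    resolved_per_curve: list
    curves: list
    provenance: dict = field(default_factory=dict)
    uncertainties: dict | None = None
    samples: np.ndarray | None = None
    objective: Objective | None = None


def fit(
    model: SystemModel,
    params: ParameterSet,
    constraints: Sequence[Constraint] = (),
    curves: Sequence[Curve] = (),
    spec: FomSpec | None = None,
    settings=None,
    seed: int = 0,
    popsize: int = 15,
    tol: float = 1e-8,
    maxiter: int = 2000,
    solvent_from_fronting: bool = False,
) -> FitResult:
    """Differential-evolution co-refinement of one model against M curves.

    Deterministic for a fixed ``seed``; uses the rand1bin strategy with a
    population of ``popsize`` × dimension and no gradient polishing stage.
    """
    objective = Objective(
        model, params, constraints, curves, spec, settings, solvent_from_fronting
    )
    result = differential_evolution(
        objective.fom,
        bounds=objective.bounds,
        strategy="rand1bin",
        popsize=popsize,
        tol=tol,
        maxiter=maxiter,
        seed=seed,
        polish=False,
        init="latinhypercube",
        updating="immediate",
    )
    x = np.asarray(result.x, dtype=float)
    values = params.values_from_vector(x)
    models = objective.model_curves(x)
    resolved = [
        objective.compiled.resolve(objective.flat_values(x, i)) for i in range(len(curves))
    ]
    return FitResult(
        best_values=values,
        best_vector=x,
        best_values_flat=dict(zip(objective.labels, x)),
        free_names=list(objective.labels),
        bounds=dict(zip(objective.labels, objective.bounds)),
        fom_min=float(result.fun),
        chi2_red=objective.chi2_red(x),
        n_free=objective.n_free,
        per_curve_model=models,
        resolved_per_curve=resolved,
        curves=list(curves),
        provenance={
            "seed": seed,
            "iterations": int(result.nit),
            "n_evaluations": int(result.nfev),
            "strategy": "rand1bin",
            "popsize": popsize,
            "converged": bool(result.success),
        },
        objective=objective,
    )
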
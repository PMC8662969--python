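"""Layer-stack builders for analytic volume-fraction profiles.

Continuous profiles are approximated by a succession of thin slabs whose
solvent volume fraction is sampled at the slice mid-plane (second-order
accurate).  Builders emit ordinary :class:`~specular.model.Layer` lists, so
the resulting stacks slot directly into any patch; when a parameter is given
by name the emitted entries are symbolic and the profile can be refined.

Families covered:

* close-packed spherical nanoparticle layers, monodisperse and with a
  normally distributed diameter,
* power-law polymer brushes ``ϕ(z) = ϕ(0)[1 − (z/L)^n]``,
* solvent-penetrated lipid bilayers parameterized by area per molecule,
* generic repetition of a layer unit for multilayers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Constraint, Layer, ModelDefinitionError, parse_entry

__all__ = [
    "CLOSE_PACKING_FRACTION",
    "SlicedProfile",
    "BilayerSpec",
    "nanoparticle_layers",
    "nanoparticle_layers_polydisperse",
    "brush_layers",
    "bilayer_layers",
    "bilayer_dry_sld",
    "repeat_stack",
]

#: Maximal mid-plane volume fraction of close-packed equal spheres,
#: π/(2√3) ≈ 0.91: the 2D hexagonal packing density of the mid-plane
#: cross-sections.
CLOSE_PACKING_FRACTION = math.pi / (2.0 * math.sqrt(3.0))


def _is_name(x) -> bool:
    return isinstance(x, str)


def _expr(template: str, **subs) -> str:
    """Fill a formula template with numeric literals or parameter names."""
    return template.format(**{k: (v if _is_name(v) else repr(float(v))) for k, v in subs.items()})


@dataclass
class SlicedProfile:
    """A discretized continuous profile: per-slice solvent fractions.

    ``slice_thickness`` is ``total extent / n_slices`` and, like the
    per-slice entries, may be numeric or a symbolic expression.
    """

    n_slices: int
    slice_thickness: object
    solvent_frac: list  # per-slice expressions or numbers
    extent: object = None

    def __post_init__(self):
        if self.n_slices < 1:
            raise ModelDefinitionError(f"n_slices must be ≥ 1, got {self.n_slices}")
        if len(self.solvent_frac) != self.n_slices:
            raise ModelDefinitionError("one solvent fraction per slice required")

    def to_layers(
        self,
        sld_re: object,
        sld_im: object = 0.0,
        description: str = "slice",
    ) -> list[Layer]:
        """Interior layers for the sliced profile (zero inter-slice roughness).

        The outer boundaries of the sliced region take whatever roughness
        the user assigns to the neighbouring layers.
        """
        return [
            Layer(
                sld_re=sld_re,
                sld_im=sld_im,
                thickness=self.slice_thickness,
                roughness=0.0,
                solvent_frac=phi,
                description=f"{description} {k + 1}/{self.n_slices}",
            )
            for k, phi in enumerate(self.solvent_frac)
        ]


def nanoparticle_layers(A, D, n_slices: int = 100) -> SlicedProfile:
    """Close-packed spherical nanoparticle layer of diameter D.

    The particle volume fraction at height z above the substrate is
    ``ϕ(z) = (4A/D²)(Dz − z²)`` — the hexagonally packed cross-section of
    spheres of diameter D — where ``A`` is the volume fraction in the middle
    of the layer (≈ 0.91 for close packing).  Slices sample the solvent
    fraction ``1 − ϕ`` at mid-planes ``z_k = (k − ½) D / n_slices``.

    ``A`` and ``D`` may be numbers or parameter names (symbolic output).
    """
    if n_slices < 1:
        raise ModelDefinitionError(f"n_slices must be ≥ 1, got {n_slices}")
    if not _is_name(A) and not 0.0 < A <= 1.0:
        raise ModelDefinitionError(f"mid-layer volume fraction A={A} outside (0, 1]")
    if not _is_name(D) and D <= 0:
        raise ModelDefinitionError(f"diameter D={D} must be positive")
    thickness = _expr("{D}/{n}", D=D, n=n_slices) if _is_name(D) else float(D) / n_slices
    fractions = []
    for k in range(1, n_slices + 1):
        x = (k - 0.5) / n_slices  # z/D at the slice mid-plane
        # ϕ(z) = (4A/D²)(Dz − z²) = 4A·(x − x²) with x = z/D
        if _is_name(A):
            fractions.append(_expr("1 - 4*{A}*({x} - {x}**2)", A=A, x=x))
        else:
            fractions.append(1.0 - 4.0 * float(A) * (x - x * x))
    return SlicedProfile(n_slices, thickness, fractions, extent=D)


def nanoparticle_layers_polydisperse(
    A: float, D: float, sigma_D: float, n_slices: int = 100, n_quad: int = 401
) -> SlicedProfile:
    """Nanoparticle layer with normally distributed diameter.

    The particle fraction at each height is the normal-density-weighted
    average of the monodisperse profile over diameters D′ in
    [D − 4σ_D, D + 4σ_D] (truncated at D′ > 0, weights re-normalized),
    integrated on a fixed 401-point trapezoid grid.  The layer extends to
    D + 4σ_D; entries are numeric.
    """
    if sigma_D < 0:
        raise ModelDefinitionError(f"sigma_D must be non-negative, got {sigma_D}")
    if not 0.0 < A <= 1.0:
        raise ModelDefinitionError(f"mid-layer volume fraction A={A} outside (0, 1]")
    if D <= 0:
        raise ModelDefinitionError(f"diameter D={D} must be positive")
    if sigma_D == 0.0:
        return nanoparticle_layers(A, D, n_slices)
    extent = D + 4.0 * sigma_D
    dz = extent / n_slices
    z_mid = (np.arange(1, n_slices + 1) - 0.5) * dz
    lo = max(D - 4.0 * sigma_D, 1e-9 * D)
    dprime = np.linspace(lo, D + 4.0 * sigma_D, n_quad)
    weights = np.exp(-0.5 * ((dprime - D) / sigma_D) ** 2)
    norm = np.trapezoid(weights, dprime)
    phi = np.array(
        [np.trapezoid(weights * _phi_sphere_vec(A, dprime, z), dprime) / norm for z in z_mid]
    )
    fractions = list(1.0 - phi)
    return SlicedProfile(n_slices, dz, fractions, extent=extent)


def _phi_sphere_vec(A: float, dprime: np.ndarray, z: float) -> np.ndarray:
    """ϕ_{D′}(z) for an array of diameters at one height."""
    inside = (z >= 0.0) & (z <= dprime)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (4.0 * A / dprime**2) * (dprime * z - z * z)
    return np.where(inside, vals, 0.0)


def brush_layers(phi0, L, n_exp, n_slices: int = 100) -> SlicedProfile:
    """End-grafted polymer brush with ``ϕ(z) = ϕ(0)[1 − (z/L)^n]``.

    At high grafting density mean-field theory gives n = 2 (parabolic
    profile).  Since z/L at the k-th slice mid-plane is (k − ½)/n_slices,
    the per-slice solvent fraction depends on L only through the slice
    thickness L/n_slices; all three parameters may be names (symbolic).
    """
    if n_slices < 1:
        raise ModelDefinitionError(f"n_slices must be ≥ 1, got {n_slices}")
    if not _is_name(phi0) and not 0.0 < phi0 <= 1.0:
        raise ModelDefinitionError(f"ϕ(0)={phi0} outside (0, 1]")
    if not _is_name(L) and L <= 0:
        raise ModelDefinitionError(f"brush length L={L} must be positive")
    if not _is_name(n_exp) and n_exp <= 0:
        raise ModelDefinitionError(f"exponent n={n_exp} must be positive")
    thickness = _expr("{L}/{n}", L=L, n=n_slices) if _is_name(L) else float(L) / n_slices
    fractions = []
    for k in range(1, n_slices + 1):
        x = (k - 0.5) / n_slices  # z/L at the slice mid-plane
        if _is_name(phi0) or _is_name(n_exp):
            fractions.append(
                _expr("1 - {phi0}*(1 - {x}**{nexp})", phi0=phi0, x=x, nexp=n_exp)
            )
        else:
            fractions.append(1.0 - float(phi0) * (1.0 - x ** float(n_exp)))
    return SlicedProfile(n_slices, thickness, fractions, extent=L)


# ---------------------------------------------------------------------------
# Lipid bilayers
# ---------------------------------------------------------------------------


@dataclass
class BilayerSpec:
    """Four-region lipid bilayer parameterized by area per molecule.

    Regions are ordered inner heads, inner tails, outer tails, outer heads
    ("inner" = substrate side).  Each region carries its total scattering
    length ``b`` (Å), molecular volume ``V`` (ų) and thickness ``t`` (Å);
    the area per molecule ``A_pm`` (Ų) is shared by both leaflets.  ``A_pm``
    and the thicknesses may be parameter names for refinement.
    """

    A_pm: object
    b: Sequence[float] = field(default_factory=lambda: (6.0e-4, -3.0e-4, -3.0e-4, 6.0e-4))
    V: Sequence[float] = field(default_factory=lambda: (320.0, 780.0, 780.0, 320.0))
    t: Sequence[object] = field(default_factory=lambda: (9.0, 14.0, 14.0, 9.0))
    region_names: Sequence[str] = ("inner heads", "inner tails", "outer tails", "outer heads")

    def __post_init__(self):
        if not (len(self.b) == len(self.V) == len(self.t) == 4):
            raise ModelDefinitionError("a bilayer has exactly four regions")
        for i, V in enumerate(self.V):
            if V <= 0:
                raise ModelDefinitionError(f"region {i}: molecular volume must be positive")
        for i, t in enumerate(self.t):
            if not _is_name(t) and t <= 0:
                raise ModelDefinitionError(f"region {i}: thickness must be positive")
        if not _is_name(self.A_pm):
            if self.A_pm <= 0:
                raise ModelDefinitionError("area per molecule must be positive")
            for i, (V, t) in enumerate(zip(self.V, self.t)):
                if not _is_name(t) and V > self.A_pm * t:
                    raise ModelDefinitionError(
                        f"region {i}: V={V} exceeds A_pm·t={self.A_pm * t} "
                        "(unphysical negative solvent fraction)"
                    )


def bilayer_layers(
    spec: BilayerSpec, roughness: object = 0.0
) -> tuple[list[Layer], list[Constraint]]:
    """Four solvent-penetrated lipid layers plus positivity constraints.

    Each region's layer carries the molecular sld ``b/V`` and the solvent
    volume fraction ``ϕ_solv = 1 − V/(A_pm·t)``, so the engine's mixing
    rule yields the volume-conserving wet sld
    ``(V·(b/V) + (A_pm·t − V)·ρ_solv)/(A_pm·t)``; its lipid part,
    ``(1 − ϕ_solv)·b/V = b/(A_pm·t)``, is the dry layer sld (the sld not
    accounting for water penetration, see :func:`bilayer_dry_sld`).  The
    returned constraints ``1 − V/(A_pm·t) > 0`` keep the solvent fraction
    physical during refinement (they are enforced at fit time, not here).
    """
    layers: list[Layer] = []
    constraints: list[Constraint] = []
    for name, b, V, t in zip(spec.region_names, spec.b, spec.V, spec.t):
        sld = float(b) / float(V)  # molecular sld; b, V are numeric
        if _is_name(spec.A_pm) or _is_name(t):
            phi = _expr("1 - {V}/({A}*{t})", V=V, A=spec.A_pm, t=t)
            constraints.append(Constraint(_expr("1 - {V}/({A}*{t}) > 0", V=V, A=spec.A_pm, t=t)))
        else:
            phi = 1.0 - float(V) / (float(spec.A_pm) * float(t))
        layers.append(
            Layer(
                sld_re=sld,
                sld_im=0.0,
                thickness=t,
                roughness=roughness,
                solvent_frac=phi,
                description=name,
            )
        )
    return layers, constraints


def bilayer_dry_sld(spec: BilayerSpec) -> list:
    """Per-region dry layer sld ``b/(A_pm·t)``: the layer-average sld before
    accounting for water penetration (numeric, or an expression when A_pm or
    a thickness is a parameter name)."""
    out = []
    for b, t in zip(spec.b, spec.t):
        if _is_name(spec.A_pm) or _is_name(t):
            out.append(_expr("{b}/({A}*{t})", b=b, A=spec.A_pm, t=t))
        else:
            out.append(float(b) / (float(spec.A_pm) * float(t)))
    return out


def repeat_stack(unit: Sequence[Layer], count: int) -> list[Layer]:
    """Concatenate *count* copies of a layer unit (multilayer building).

    The layer-index symbol ``n`` always denotes a layer's global position in
    the final patch, so index-dependent expressions remain consistent after
    repetition: each copy sees its own indices.
    """
    if count < 1:
        raise ModelDefinitionError(f"repeat count must be ≥ 1, got {count}")
    out: list[Layer] = []
    for _ in range(count):
        out.extend(unit)
    # re-parse entries so malformed expressions surface here, not at resolve
    for layer in out[: len(unit)]:
        for attr in ("sld_re", "sld_im", "thickness", "roughness", "solvent_frac"):
            parse_entry(getattr(layer, attr))
    return out
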
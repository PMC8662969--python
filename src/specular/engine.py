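"""Specular reflectivity of a stratified medium.

The kernel is the Abelès characteristic-matrix method with Névot–Croce
Gaussian-roughness damping of each interfacial Fresnel coefficient.  On top
of the kernel this module provides solvent mixing, incoherent averaging of
lateral patches, Gaussian resolution smearing and the final scale/background
transformation.

Conventions
-----------
* Momentum transfer ``Q`` is in Å⁻¹; ``Q = 2 k_{z,0}``.
* The z component of the wavevector in layer j is

  ``k_{z,j} = sqrt(k_{z,0}² − 4π (ρ_j − ρ_0))``

  where ``ρ = ρ_re + i ρ_im`` with **ρ_im ≥ 0 meaning absorption**.  The
  square-root branch is chosen with non-negative imaginary part, i.e. the
  evanescent/absorbed wave decays into the stack.
* The roughness stored on layer j refers to the j/j+1 interface and damps
  its Fresnel coefficient by ``exp(−2 k_{z,j} k_{z,j+1} σ_j²)``.
* δQ resolution values are full widths at half maximum (FWHM) of a Gaussian
  approximation to the instrument resolution function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import (
    ModelDefinitionError,
    ResolvedPatch,
    SystemModel,
    resolve_system,
)

__all__ = [
    "InstrumentSettings",
    "mix_solvent",
    "abeles_reflectivity",
    "mix_patches",
    "smear",
    "finalize",
    "reflectivity",
    "FWHM_TO_SIGMA",
    "SMEAR_WINDOW_SIGMA",
    "SMEAR_NODES",
]

try:  # compiled kernel: the matrix product dominates fit/MCMC runtime
    import numba as _numba
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _numba = None

#: FWHM = 2 sqrt(2 ln 2) σ for a Gaussian.
FWHM_TO_SIGMA = 2.3548200450309493
#: Half-width of the smearing quadrature window, in units of σ.
SMEAR_WINDOW_SIGMA = 2.5
#: Number of Gauss–Legendre nodes used for resolution smearing.
SMEAR_NODES = 17


@dataclass
class InstrumentSettings:
    """Per-curve instrument description.

    ``dq_q`` is a constant δQ/Q (FWHM over Q, dimensionless) applied to the
    whole range; ``dq_fwhm`` is an optional per-point δQ FWHM column (Å⁻¹)
    which, when present, takes precedence.  ``scale`` multiplies and
    ``background`` is added to the reflectivity, after smearing.
    """

    dq_q: float = 0.0
    background: float = 0.0
    scale: float = 1.0
    dq_fwhm: np.ndarray | None = None

    def validate(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.background < 0:
            raise ValueError(f"background must be non-negative, got {self.background}")
        if self.dq_q < 0:
            raise ValueError(f"dQ/Q must be non-negative, got {self.dq_q}")
        if self.dq_fwhm is not None and np.any(np.asarray(self.dq_fwhm) < 0):
            raise ValueError("per-point dQ FWHM must be non-negative")


def mix_solvent(layer_sld: complex, solvent_frac: float, solvent_sld: complex) -> complex:
    """Volume-fraction mixing: ``(1 − ϕ) ρ_layer + ϕ ρ_solvent``."""
    if not 0.0 <= solvent_frac <= 1.0:
        raise ValueError(f"solvent fraction {solvent_frac} outside [0, 1]")
    return (1.0 - solvent_frac) * layer_sld + solvent_frac * solvent_sld


def _matrix_kernel_numpy(k: np.ndarray, d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Characteristic-matrix product, vectorized over Q (reference path)."""
    nlay = k.shape[0]
    M11 = np.ones_like(k[0])
    M12 = np.zeros_like(k[0])
    M21 = np.zeros_like(k[0])
    M22 = np.ones_like(k[0])
    for j in range(nlay - 1):
        kj, kj1 = k[j], k[j + 1]
        r = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigma[j] ** 2)
        beta = -1j * kj * (d[j] if j > 0 else 0.0)
        ep, em = np.exp(beta), np.exp(-beta)
        A11, A12 = ep, r * ep
        A21, A22 = r * em, em
        M11, M12, M21, M22 = (
            M11 * A11 + M12 * A21,
            M11 * A12 + M12 * A22,
            M21 * A11 + M22 * A21,
            M21 * A12 + M22 * A22,
        )
        # rescale to avoid overflow with deeply evanescent thick stacks;
        # only the ratio M21/M11 is ever used
        norm = np.abs(M11)
        big = norm > 1e150
        if np.any(big):
            scale = np.where(big, norm, 1.0)
            M11, M12, M21, M22 = M11 / scale, M12 / scale, M21 / scale, M22 / scale
    r_tot = M21 / M11
    return np.abs(r_tot) ** 2


if _numba is not None:

    @_numba.njit(cache=True, fastmath=False)
    def _matrix_kernel_jit(k, d, sigma):  # pragma: no cover - exercised via dispatch
        nlay, nq = k.shape
        R = np.empty(nq)
        for iq in range(nq):
            M11 = 1.0 + 0.0j
            M12 = 0.0j
            M21 = 0.0j
            M22 = 1.0 + 0.0j
            for j in range(nlay - 1):
                kj = k[j, iq]
                kj1 = k[j + 1, iq]
                r = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigma[j] ** 2)
                if j > 0:
                    beta = -1j * kj * d[j]
                    ep = np.exp(beta)
                    em = np.exp(-beta)
                else:
                    ep = 1.0 + 0.0j
                    em = 1.0 + 0.0j
                A12 = r * ep
                A21 = r * em
                n11 = M11 * ep + M12 * A21
                n12 = M11 * A12 + M12 * em
                n21 = M21 * ep + M22 * A21
                n22 = M21 * A12 + M22 * em
                M11, M12, M21, M22 = n11, n12, n21, n22
                a = abs(M11)
                if a > 1e150:
                    M11 /= a
                    M12 /= a
                    M21 /= a
                    M22 /= a
            amp = M21 / M11
            R[iq] = amp.real * amp.real + amp.imag * amp.imag
        return R

    _matrix_kernel = _matrix_kernel_jit
else:  # pragma: no cover
    _matrix_kernel = _matrix_kernel_numpy


def abeles_reflectivity(
    sld: Sequence[complex],
    thickness: Sequence[float],
    roughness: Sequence[float],
    Q: np.ndarray,
) -> np.ndarray:
    """Reflectivity of one slab stack by the Abelès matrix product.

    Parameters
    ----------
    sld
        Complex scattering length densities (Å⁻²) from fronting (index 0) to
        backing; at least two entries.
    thickness
        Layer thicknesses (Å); the fronting/backing entries are ignored.
    roughness
        ``roughness[j]`` is the Gaussian roughness σ (Å) of the j/j+1
        interface; the final entry is ignored.
    Q
        Momentum transfer values (Å⁻¹), strictly positive.

    Returns
    -------
    numpy.ndarray
        ``R(Q) = |M21/M11|²`` of the accumulated characteristic matrix, each
        interface damped by the Névot–Croce factor.
    """
    sld = np.asarray(sld, dtype=complex)
    d = np.asarray(thickness, dtype=float)
    sigma = np.asarray(roughness, dtype=float)
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    if sld.size < 2:
        raise ValueError("need at least fronting and backing media")
    if np.any(Q <= 0):
        raise ValueError("Q must be strictly positive")

    kz0_sq = (Q / 2.0) ** 2  # (nQ,)
    # kz² = k0² − 4π Δρ_re + 4πi Δρ_im: principal sqrt then has Im ≥ 0
    # (decaying wave) for absorbing (Δρ_im ≥ 0) and evanescent regions alike.
    d_re = sld.real - sld.real[0]
    d_im = sld.imag - sld.imag[0]
    arg = kz0_sq[None, :] - 4.0 * np.pi * d_re[:, None] + 4.0j * np.pi * d_im[:, None]
    k = np.sqrt(arg)  # (nlay, nQ)
    return _matrix_kernel(np.ascontiguousarray(k), d, sigma)


def mix_patches(R_per_patch: Sequence[np.ndarray], coverages: Sequence[float]) -> np.ndarray:
    """Incoherent (coverage-weighted) average of per-patch reflectivities."""
    if len(R_per_patch) != len(coverages):
        raise ValueError("one coverage per patch required")
    if abs(sum(coverages) - 1.0) > 1e-9:
        raise ValueError(f"coverages sum to {sum(coverages)}, expected 1")
    lengths = {np.asarray(r).shape for r in R_per_patch}
    if len(lengths) > 1:
        raise ValueError("per-patch reflectivity arrays differ in length")
    out = np.zeros_like(np.asarray(R_per_patch[0], dtype=float))
    for c, r in zip(coverages, R_per_patch):
        out += c * np.asarray(r, dtype=float)
    return out


def _smear_nodes_weights(Q: np.ndarray, fwhm: np.ndarray):
    """Quadrature nodes (nQ, m) and normalized weights for Gaussian smearing."""
    gl_x, gl_w = np.polynomial.legendre.leggauss(SMEAR_NODES)
    sigma = np.asarray(fwhm, dtype=float) / FWHM_TO_SIGMA
    half = SMEAR_WINDOW_SIGMA * sigma  # (nQ,)
    nodes = Q[:, None] + half[:, None] * gl_x[None, :]
    pdf = np.exp(-0.5 * (half[:, None] * gl_x[None, :] / np.where(sigma > 0, sigma, 1.0)[:, None]) ** 2)
    w = gl_w[None, :] * pdf
    w = w / w.sum(axis=1, keepdims=True)
    return nodes, w


def smear(
    Q: np.ndarray,
    R: np.ndarray | Callable[[np.ndarray], np.ndarray],
    settings: InstrumentSettings,
) -> np.ndarray:
    """Gaussian resolution smearing by fixed-node quadrature.

    Each output point is the Gaussian-weighted average of the unsmeared
    model over a ±2.5σ window (σ = FWHM/2.3548), computed with 17-node
    Gauss–Legendre quadrature on a locally refined Q grid.  ``R`` may be a
    callable (evaluated exactly at the quadrature nodes — preferred) or an
    array tabulated on ``Q`` (linearly interpolated).

    A per-point ``dq_fwhm`` column takes precedence over a constant
    ``dq_q``; zero resolution returns the input unchanged.
    """
    settings.validate()
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    if settings.dq_fwhm is not None:
        fwhm = np.asarray(settings.dq_fwhm, dtype=float)
        if fwhm.shape != Q.shape:
            raise ValueError("per-point dQ column length does not match Q")
    else:
        fwhm = settings.dq_q * Q

    if callable(R):
        evaluate = R
        R_on_grid = None
    else:
        R_on_grid = np.asarray(R, dtype=float)
        if R_on_grid.shape != Q.shape:
            raise ValueError("R array length does not match Q")
        evaluate = lambda q: np.interp(q, Q, R_on_grid)

    if np.all(fwhm == 0.0):
        return evaluate(Q) if R_on_grid is None else R_on_grid.copy()

    nodes, w = _smear_nodes_weights(Q, fwhm)
    # nodes may dip non-positive at very low Q; reflectivity is even in Q
    flat = np.abs(nodes.ravel())
    flat = np.where(flat == 0.0, 1e-12, flat)
    vals = np.asarray(evaluate(flat), dtype=float).reshape(nodes.shape)
    out = (vals * w).sum(axis=1)
    zero = fwhm == 0.0
    if np.any(zero):
        exact = evaluate(Q[zero]) if R_on_grid is None else R_on_grid[zero]
        out[zero] = exact
    return out


def finalize(R: np.ndarray, settings: InstrumentSettings) -> np.ndarray:
    """Apply scale and additive incoherent background: ``scale·R + bg``."""
    settings.validate()
    return settings.scale * np.asarray(R, dtype=float) + settings.background


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def patch_slabs(
    patch: ResolvedPatch, solvent_from_fronting: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solvent-mixed complex slds plus thickness/roughness arrays for a patch.

    The solvent sld is the backing medium's resolved sld by default (the
    usual solid/liquid geometry); with ``solvent_from_fronting`` the
    fronting medium is used instead (air/liquid monolayers).  The two
    semi-infinite media themselves are not mixed.
    """
    sld = np.asarray(patch.sld_re, dtype=float) + 1j * np.asarray(patch.sld_im, dtype=float)
    phi = np.asarray(patch.solvent_frac, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        bad = int(np.argmax((phi < 0) | (phi > 1)))
        raise ModelDefinitionError(
            f"layer {bad}: resolved solvent fraction {phi[bad]} outside [0, 1]"
        )
    solvent = sld[0] if solvent_from_fronting else sld[-1]
    mixed = sld.copy()
    mixed[1:-1] = (1.0 - phi[1:-1]) * sld[1:-1] + phi[1:-1] * solvent
    return (
        mixed,
        np.asarray(patch.thickness, dtype=float),
        np.asarray(patch.roughness, dtype=float),
    )


def reflectivity(
    model: SystemModel | Sequence[ResolvedPatch],
    values: dict | None,
    Q: np.ndarray,
    settings: InstrumentSettings | None = None,
    curve_index: int = 0,
    solvent_from_fronting: bool | Sequence[bool] = False,
) -> np.ndarray:
    """Smeared, scaled reflectivity of a full multi-patch system.

    ``model`` is either a :class:`~specular.model.SystemModel` (resolved
    against ``values``/``curve_index``) or an already-resolved list of
    patches.  Pipeline order: solvent mixing → Abelès per patch →
    coverage-weighted patch average → Gaussian smearing → scale/background.
    """
    if settings is None:
        settings = InstrumentSettings()
    if isinstance(model, SystemModel):
        patches = resolve_system(model, values or {}, curve_index)
    else:
        patches = list(model)
    if isinstance(solvent_from_fronting, bool):
        from_front = [solvent_from_fronting] * len(patches)
    else:
        from_front = list(solvent_from_fronting)
    slabs = [patch_slabs(p, f) for p, f in zip(patches, from_front)]
    coverages = [p.coverage for p in patches]

    def unsmeared(q: np.ndarray) -> np.ndarray:
        per_patch = [abeles_reflectivity(s, d, sig, q) for s, d, sig in slabs]
        return mix_patches(per_patch, coverages)

    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    smeared = smear(Q, unsmeared, settings)
    return finalize(smeared, settings)
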
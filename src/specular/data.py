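"""Reflectivity data files and result reports.

Experimental curves are plain ASCII with 2–4 whitespace- or
comma-delimited columns: Q, R(Q), optionally δR(Q) and δQ (FWHM), with Q
and δQ in Å⁻¹ or nm⁻¹.  Lines starting with ``#`` are comments.  Reports
are written as a human-readable log plus machine-readable ASCII tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .engine import FWHM_TO_SIGMA, patch_slabs

__all__ = ["Curve", "CurveFormatError", "read_curve", "write_curve", "sld_profile", "write_report"]

logger = logging.getLogger("specular")


class CurveFormatError(ValueError):
    """A reflectivity data file could not be parsed."""


@dataclass
class Curve:
    """One experimental (or synthetic) reflectivity data set."""

    Q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None
    dQ: np.ndarray | None = None  # FWHM, Å⁻¹
    source_path: str = ""
    fit_weight: float = 1.0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
        if self.dQ is not None:
            self.dQ = np.asarray(self.dQ, dtype=float)
        n = self.Q.size
        for name in ("R", "dR", "dQ"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise CurveFormatError(f"column {name} has {arr.size} rows, expected {n}")
        if n == 0:
            raise CurveFormatError("empty curve")
        if np.any(self.Q <= 0):
            raise CurveFormatError("Q must be strictly positive")
        if self.dR is not None and np.any(self.dR <= 0):
            raise CurveFormatError("δR must be strictly positive where present")
        if self.fit_weight <= 0:
            raise CurveFormatError(f"fit weight must be positive, got {self.fit_weight}")

    @property
    def n_points(self) -> int:
        return int(self.Q.size)

    @property
    def has_errors(self) -> bool:
        return self.dR is not None


def read_curve(
    path,
    units: str = "inv_angstrom",
    fit_weight: float = 1.0,
    dq_is_sigma: bool = False,
) -> Curve:
    """Read a 2/3/4-column ASCII reflectivity file.

    Parameters
    ----------
    units
        ``inv_angstrom`` or ``inv_nanometre``; nm⁻¹ values of Q and δQ are
        divided by 10.
    dq_is_sigma
        If the file's δQ column holds a Gaussian σ rather than a FWHM,
        convert on read (δQ is interpreted as FWHM everywhere downstream).
    """
    if units not in ("inv_angstrom", "inv_nanometre"):
        raise ValueError(f"unknown units {units!r}")
    path = Path(path)
    rows = []
    ncols = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise CurveFormatError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
        if len(vals) < 2:
            raise CurveFormatError(f"{path}:{lineno}: fewer than 2 columns")
        if ncols is None:
            ncols = min(len(vals), 4)
        rows.append(vals[:ncols])
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    scale = 0.1 if units == "inv_nanometre" else 1.0
    Q = data[:, 0] * scale
    R = data[:, 1]
    dR = data[:, 2] if ncols >= 3 else None
    dQ = data[:, 3] * scale if ncols >= 4 else None
    if dQ is not None and dq_is_sigma:
        dQ = dQ * FWHM_TO_SIGMA
    if np.any(np.diff(Q) < 0):
        logger.warning("%s: Q not sorted ascending; sorting", path)
        order = np.argsort(Q)
        Q, R = Q[order], R[order]
        dR = dR[order] if dR is not None else None
        dQ = dQ[order] if dQ is not None else None
    return Curve(Q=Q, R=R, dR=dR, dQ=dQ, source_path=str(path), fit_weight=fit_weight)


def write_curve(curve: Curve, path) -> None:
    """Write a curve back to 2/3/4-column ASCII (full float precision)."""
    cols = [curve.Q, curve.R]
    header = "Q(1/Angstrom) R"
    if curve.dR is not None:
        cols.append(curve.dR)
        header += " dR"
    if curve.dQ is not None:
        cols.append(curve.dQ)
        header += " dQ_FWHM(1/Angstrom)"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.17g")


def sld_profile(
    resolved_patch,
    solvent_from_fronting: bool = False,
    dz: float = 0.5,
    pad: float = 30.0,
):
    """Continuous (z, sld_re, sld_im, ϕ_solv) profile of one resolved patch.

    Interfacial Gaussian roughness broadens each step with an error
    function; z = 0 is the fronting/first-interior interface and z grows
    toward the backing.  Used for report tables and plots.
    """
    mixed, thickness, roughness = patch_slabs(resolved_patch, solvent_from_fronting)
    phi = np.asarray(resolved_patch.solvent_frac, dtype=float)
    # interface positions: z=0 at the first interface
    interior = thickness[1:-1]
    z_if = np.concatenate([[0.0], np.cumsum(interior)])
    z = np.arange(-pad, z_if[-1] + pad + dz, dz)
    re = np.full_like(z, mixed[0].real)
    im = np.full_like(z, mixed[0].imag)
    ph = np.full_like(z, phi[0])
    for j in range(len(mixed) - 1):
        sig = max(roughness[j], 1e-3)
        step = 0.5 * (1.0 + erf((z - z_if[j]) / (math.sqrt(2.0) * sig)))
        re += (mixed[j + 1].real - mixed[j].real) * step
        im += (mixed[j + 1].imag - mixed[j].imag) * step
        ph += (phi[j + 1] - phi[j]) * step
    return z, re, im, ph


def write_report(result, path) -> list[Path]:
    """Write a refinement report directory.

    Produces ``fit_log.txt`` (per-curve resolved layers, best-fit parameters
    ± uncertainties, FOM and reduced χ²), ``parameters.txt`` (name, value,
    sd, bounds as key-value rows), one ``curve_<i>_fit.dat`` table of the
    fitted model per curve and one ``profile_<i>.dat`` sld/solvent profile
    table per curve.  Returns the list of written files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lines = ["Refinement report", "=" * 17, ""]
    lines.append(f"figure of merit (minimum): {result.fom_min:.8g}")
    if result.chi2_red is not None:
        lines.append(f"reduced chi^2:             {result.chi2_red:.8g}")
    lines.append(f"free parameters:           {result.n_free}")
    if result.provenance:
        for k, v in sorted(result.provenance.items()):
            lines.append(f"{k}: {v}")
    lines.append("")
    lines.append("Best-fit parameters")
    lines.append("-" * 19)
    for name in result.free_names:
        sd = (result.uncertainties or {}).get(name)
        sd_txt = f" +- {sd:.6g}" if sd is not None and math.isfinite(sd) else ""
        lines.append(f"  {name} = {result.best_values_flat[name]:.8g}{sd_txt}")
    lines.append("")
    for i, patches in enumerate(result.resolved_per_curve):
        lines.append(f"Curve {i}: resolved layers")
        lines.append("-" * 24)
        for ip, patch in enumerate(patches):
            lines.append(f"  patch {ip} (coverage {patch.coverage:g})")
            lines.append(
                "    idx  sld_re        sld_im        thickness   roughness   phi_solv  description"
            )
            for il in range(len(patch.sld_re)):
                lines.append(
                    f"    {il:3d}  {patch.sld_re[il]: .6e}  {patch.sld_im[il]: .6e}  "
                    f"{patch.thickness[il]:9.3f}   {patch.roughness[il]:9.3f}   "
                    f"{patch.solvent_frac[il]:7.4f}  {patch.descriptions[il]}"
                )
        lines.append("")
    log = path / "fit_log.txt"
    log.write_text("\n".join(lines) + "\n")
    written.append(log)

    rows = []
    for name in result.free_names:
        sd = (result.uncertainties or {}).get(name)
        lo, hi = result.bounds[name]
        rows.append(
            f"{name} value={result.best_values_flat[name]:.17g} "
            f"sd={sd if sd is not None else 'nan'} min={lo:.17g} max={hi:.17g}"
        )
    params = path / "parameters.txt"
    params.write_text("\n".join(rows) + "\n")
    written.append(params)

    for i, (curve, model) in enumerate(zip(result.curves, result.per_curve_model)):
        table = path / f"curve_{i}_fit.dat"
        np.savetxt(
            table,
            np.column_stack([curve.Q, curve.R, model]),
            header="Q(1/Angstrom) R_experimental R_model",
            fmt="%.17g",
        )
        written.append(table)
    for i, patches in enumerate(result.resolved_per_curve):
        for ip, patch in enumerate(patches):
            z, re, im, ph = sld_profile(patch)
            table = path / (
                f"profile_{i}.dat" if len(patches) == 1 else f"profile_{i}_patch{ip}.dat"
            )
            np.savetxt(
                table,
                np.column_stack([z, re, im, ph]),
                header="z(Angstrom) sld_re(1/Angstrom^2) sld_im(1/Angstrom^2) phi_solv",
                fmt="%.8g",
            )
            written.append(table)
    return written
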
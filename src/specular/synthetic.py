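"""Synthetic reflectivity data with known ground truth.

Every refinement and uncertainty feature of the package is testable
without downloading any experimental file: these generators evaluate a
model forward, attach a realistic heteroscedastic error column and add
reproducible Gaussian noise.  The default noise emulates time-of-flight
neutron counting statistics: about 1% relative error on the total-reflection
plateau, growing to ~20% where the signal approaches the incoherent
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Curve
from .engine import InstrumentSettings, reflectivity
from .model import Layer, Patch, SystemModel
from .profiles import BilayerSpec, bilayer_layers

__all__ = [
    "NoiseSpec",
    "generate_curve",
    "bilayer_system",
    "generate_contrast_series",
    "default_q_grid",
]


def default_q_grid(qmin: float = 0.008, qmax: float = 0.30, n: int = 120) -> np.ndarray:
    """Logarithmically spaced Q grid typical of a reflectometry scan."""
    return np.geomspace(qmin, qmax, n)


@dataclass
class NoiseSpec:
    """Counting-noise description for synthetic curves.

    ``relative_floor`` is the fractional δR/R on the high-R plateau;
    ``background_level`` feeds an extra additive error term
    (0.2 × background) so δR/R climbs toward ~20% where R falls to the
    background, as in time-of-flight data.  ``relative_floor = 0`` produces
    a noiseless curve.
    """

    relative_floor: float = 0.01
    background_level: float = 0.0
    counting_model: str = "gaussian_relative"
    seed: int = 0

    def __post_init__(self):
        if self.relative_floor < 0:
            raise ValueError("relative_floor must be non-negative")
        if self.counting_model not in ("gaussian_relative", "poisson_like"):
            raise ValueError(f"unknown counting model {self.counting_model!r}")

    def dR(self, R: np.ndarray) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        if self.counting_model == "poisson_like":
            # δR ∝ sqrt(R): relative error grows as 1/sqrt(R) below the plateau
            plateau = float(np.max(R)) if R.size else 1.0
            base = self.relative_floor * np.sqrt(np.maximum(R, 0.0) * plateau)
        else:
            base = self.relative_floor * np.maximum(R, 0.0)
        return base + 0.2 * self.background_level


def generate_curve(
    model: SystemModel,
    values: dict,
    Q_grid: np.ndarray,
    settings: InstrumentSettings | None = None,
    noise: NoiseSpec | None = None,
    curve_index: int = 0,
    solvent_from_fronting: bool = False,
) -> Curve:
    """Forward-model a curve and add reproducible Gaussian noise.

    Returns a 4-column-style :class:`~specular.data.Curve` (Q, R, δR and —
    when the settings carry a per-point resolution — δQ).  With a zero
    noise amplitude the returned R equals the model exactly and no δR
    column is attached.
    """
    settings = settings or InstrumentSettings()
    noise = noise or NoiseSpec()
    R_model = reflectivity(
        model, values, Q_grid, settings, curve_index, solvent_from_fronting
    )
    dQ = None
    if settings.dq_fwhm is not None:
        dQ = np.asarray(settings.dq_fwhm, dtype=float).copy()
    elif settings.dq_q > 0:
        dQ = settings.dq_q * np.asarray(Q_grid, dtype=float)
    if noise.relative_floor == 0 and noise.background_level == 0:
        return Curve(Q=np.asarray(Q_grid, float), R=R_model, dR=None, dQ=dQ)
    dR = noise.dR(R_model)
    rng = np.random.default_rng(noise.seed)
    R_noisy = R_model + rng.normal(0.0, 1.0, R_model.size) * dR
    return Curve(Q=np.asarray(Q_grid, float), R=R_noisy, dR=dR, dQ=dQ)


# ---------------------------------------------------------------------------
# Contrast-variation series
# ---------------------------------------------------------------------------

#: Scattering length densities (Å⁻²) of the stock contrasts and media.
SLD_SI = 2.07e-6
SLD_SIO2 = 3.47e-6
SLD_D2O = 6.36e-6
SLD_SMW = 2.07e-6  # silicon-matched water
SLD_H2O = -0.56e-6


def bilayer_system(
    spec: BilayerSpec,
    solvent_name: str = "rho_solv",
    fronting_sld: float = SLD_SI,
    sio2_thickness: float = 12.0,
    water_thickness: object = 3.0,
    roughness: object = 3.0,
):
    """Solid-supported bilayer model: Si/SiO₂/water/4 lipid layers/solvent.

    The backing (solvent) sld is left symbolic under *solvent_name*, so a
    multi-parameter can give it a distinct value per contrast.  Returns the
    :class:`~specular.model.SystemModel` and the solvent-positivity
    constraints emitted by the bilayer builder.
    """
    lipid_layers, constraints = bilayer_layers(spec, roughness=roughness)
    layers = [
        Layer(fronting_sld, 0.0, 0.0, roughness, 0.0, "Si fronting"),
        Layer(SLD_SIO2, 0.0, sio2_thickness, roughness, 0.15, "SiO2"),
        Layer(solvent_name, 0.0, water_thickness, roughness, 1.0, "interfacial water"),
        *lipid_layers,
        Layer(solvent_name, 0.0, 0.0, 0.0, 0.0, "solvent backing"),
    ]
    return SystemModel(patches=(Patch(layers=layers, coverage=1.0),)), constraints


def generate_contrast_series(
    bilayer: BilayerSpec,
    solvent_slds,
    shared_structure: dict | None = None,
    Q_grid: np.ndarray | None = None,
    settings: InstrumentSettings | None = None,
    noise: NoiseSpec | None = None,
    **system_kwargs,
) -> list[Curve]:
    """Curves of one bilayer structure under several solvent contrasts.

    All structural parameters are shared; only the solvent sld (and, via
    per-curve settings, optionally scale/background) differ between the
    returned curves — the canonical multi-parameter co-refinement harness.
    A single solvent sld reduces to one :func:`generate_curve`.
    """
    solvent_slds = list(solvent_slds)
    if not solvent_slds:
        raise ValueError("need at least one solvent sld")
    Q_grid = default_q_grid() if Q_grid is None else np.asarray(Q_grid, dtype=float)
    model, _ = bilayer_system(bilayer, **system_kwargs)
    values = dict(shared_structure or {})
    values["rho_solv"] = solvent_slds
    base_noise = noise or NoiseSpec()
    curves = []
    for i in range(len(solvent_slds)):
        noise_i = NoiseSpec(
            relative_floor=base_noise.relative_floor,
            background_level=base_noise.background_level,
            counting_model=base_noise.counting_model,
            seed=base_noise.seed + i,
        )
        curves.append(
            generate_curve(model, values, Q_grid, settings, noise_i, curve_index=i)
        )
    return curves
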
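"""Shared fixtures and independent oracles.

The Parratt recursion implemented here is deliberately written bottom-up
(recursive amplitude combination), independent of the package's Abelès
matrix product, so the two can cross-check each other.
"""

from __future__ import annotations

import numpy as np
import pytest

import specular as s


def parratt_reflectivity(sld, thickness, roughness, Q):
    """Independent bottom-up Parratt recursion with Névot–Croce damping.

    Uses the package's documented wavevector convention
    kz_j = sqrt(kz0² − 4π Δρ_re + 4πi Δρ_im), but none of its code.
    """
    sld = np.asarray(sld, dtype=complex)
    d = np.asarray(thickness, dtype=float)
    sig = np.asarray(roughness, dtype=float)
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    n = sld.size
    k = np.sqrt(
        (Q[None, :] / 2.0) ** 2
        - 4.0 * np.pi * (sld.real - sld.real[0])[:, None]
        + 4.0j * np.pi * (sld.imag - sld.imag[0])[:, None]
    )
    r = np.zeros_like(k[0])
    for j in range(n - 2, -1, -1):
        rj = (k[j] - k[j + 1]) / (k[j] + k[j + 1]) * np.exp(-2.0 * k[j] * k[j + 1] * sig[j] ** 2)
        if j == n - 2:
            r = rj
        else:
            phase = np.exp(2.0j * k[j + 1] * d[j + 1])
            r = (rj + r * phase) / (1.0 + rj * r * phase)
    return np.abs(r) ** 2


def dense_convolution(Q, fn, dq_q, npts=4001):
    """Brute-force fine-grid Gaussian convolution (same ±2.5σ truncation)."""
    from specular.engine import FWHM_TO_SIGMA, SMEAR_WINDOW_SIGMA

    out = []
    for qi in np.atleast_1d(Q):
        sigma = dq_q * qi / FWHM_TO_SIGMA
        x = np.linspace(qi - SMEAR_WINDOW_SIGMA * sigma, qi + SMEAR_WINDOW_SIGMA * sigma, npts)
        w = np.exp(-0.5 * ((x - qi) / sigma) ** 2)
        out.append(np.trapezoid(w * fn(np.abs(x)), x) / np.trapezoid(w, x))
    return np.array(out)


def random_stack(rng, n_interior=10):
    """A random physically plausible slab stack (complex slds, σ ≤ 10 Å)."""
    n = n_interior + 2
    sld = rng.uniform(-2e-6, 8e-6, n) + 1j * rng.uniform(0.0, 5e-7, n)
    sld[0] = complex(rng.uniform(0.0, 3e-6))
    thickness = rng.uniform(5.0, 80.0, n)
    roughness = rng.uniform(0.0, 10.0, n)
    return sld, thickness, roughness


# ---------------------------------------------------------------------------
# Standard fixtures: single-film model on silicon in D2O
# ---------------------------------------------------------------------------

SINGLE_FILM_TRUTH = {"t_film": 60.0}


@pytest.fixture
def single_film_model():
    """Si / uniform film (symbolic thickness) / D2O."""
    layers = [
        s.Layer(2.07e-6, 0.0, 0.0, 3.0, 0.0, "Si"),
        s.Layer(4.0e-6, 0.0, "t_film", 3.0, 0.2, "film"),
        s.Layer(6.36e-6, 0.0, 0.0, 0.0, 0.0, "D2O"),
    ]
    return s.SystemModel(patches=(s.Patch(layers=layers, coverage=1.0),))


@pytest.fixture
def single_film_params():
    return s.ParameterSet(parameters=[s.Parameter("t_film", "uniform", 10.0, 150.0)])


def make_single_film_curve(model, seed=0, noise=0.01, n_q=60):
    settings = s.InstrumentSettings(dq_q=0.03, background=1e-7)
    Q = s.default_q_grid(0.01, 0.25, n_q)
    spec = (
        s.NoiseSpec(relative_floor=0.0)
        if noise == 0.0
        else s.NoiseSpec(relative_floor=noise, background_level=1e-7, seed=seed)
    )
    curve = s.generate_curve(model, SINGLE_FILM_TRUTH, Q, settings, spec)
    return curve, settings


@pytest.fixture
def single_film_curve(single_film_model):
    return make_single_film_curve(single_film_model, seed=0)
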
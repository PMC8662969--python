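"""Parameter-uncertainty estimation: Hessian, bootstrap and MCMC.

Three complementary routes to free-parameter standard deviations and
covariance after a differential-evolution refinement:

1. **Hessian curvature** — σ_k = sqrt(2 χ²_red,min / H_kk) with H_kk the
   second partial derivative of the reduced χ² at the minimum, by adaptive
   central finite differences.  Fast but occasionally numerically fragile;
   non-positive curvature yields an undefined (NaN) sd with a warning.
2. **Bootstrap** — each curve is replicated K times (default K = 1000) by
   adding N(0, δR) noise point-wise, and the refinement is repeated per
   replica; reports per-parameter mean and sd plus the K × n sample matrix.
3. **Ensemble MCMC** (emcee) — Gaussian likelihood in the measured R with
   uniform/normal priors and hard constraint rejection; a 500-sample pilot
   chain estimates the integrated autocorrelation time τ, 10 τ samples are
   discarded as burn-in and the production run continues to at least 60 τ.

Bootstrap and MCMC sample matrices feed corner-plot statistics and
point-wise 1σ confidence bands on the model curves and sld profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import emcee
import numpy as np
from scipy.optimize import differential_evolution

from .refine import FitResult, Objective

__all__ = [
    "BOOTSTRAP_K",
    "MCMC_PILOT_STEPS",
    "BURN_IN_TAU_MULTIPLE",
    "PRODUCTION_TAU_MULTIPLE",
    "PosteriorSample",
    "BootstrapResult",
    "CornerStats",
    "hessian_sd",
    "bootstrap",
    "mcmc",
    "corner_stats",
    "corner_plot",
    "confidence_band",
    "default_walker_count",
]

logger = logging.getLogger("specular")

#: Default number of bootstrap replicas.
BOOTSTRAP_K = 1000
#: Length (steps per walker) of the MCMC pilot chain used to estimate τ.
MCMC_PILOT_STEPS = 500
#: Burn-in, in units of the pilot's maximal integrated autocorrelation time.
BURN_IN_TAU_MULTIPLE = 10
#: Minimal production chain length, in units of max τ.
PRODUCTION_TAU_MULTIPLE = 60
#: Hard cap on total MCMC steps before declaring non-convergence.
MCMC_STEP_CAP = 50_000


# ---------------------------------------------------------------------------
# 1. Hessian curvature
# ---------------------------------------------------------------------------


def hessian_sd(
    fom_landscape: Callable[[np.ndarray], float],
    best: np.ndarray,
    chi2_red_min: float,
    rel_step: float = 1e-3,
) -> np.ndarray:
    """Per-parameter sd from the diagonal curvature of the χ² landscape.

    ``σ_k = sqrt(2 χ²_red,min / H_kk)`` with ``H_kk = ∂²(fom_landscape)/∂α_k²``
    estimated by a central second difference whose step adapts (grows up to
    ×10⁴) until the curvature signal exceeds numerical noise.  With the
    **unreduced** χ² as the landscape this is the standard scaled-covariance
    estimate (σ_k² = 2 χ²_red,min / H_kk, matching ordinary least squares
    when χ²_red ≈ 1); pass :meth:`specular.refine.Objective.chi2_full`.
    Flat or negative-curvature directions give NaN with a warning.
    """
    best = np.asarray(best, dtype=float)
    try:
        f0 = float(fom_landscape(best))
    except Exception as exc:
        raise RuntimeError(f"objective failed at the reported minimum: {exc}") from exc
    sds = np.full(best.size, np.nan)
    for k in range(best.size):
        h = rel_step * max(abs(best[k]), 1.0)
        H_kk = None
        for _ in range(5):  # adaptive step growth
            xp, xm = best.copy(), best.copy()
            xp[k] += h
            xm[k] -= h
            try:
                fp, fm = float(fom_landscape(xp)), float(fom_landscape(xm))
            except Exception as exc:
                raise RuntimeError(
                    f"objective evaluation failed near the minimum for parameter {k}: {exc}"
                ) from exc
            second = fp - 2.0 * f0 + fm
            # require the second difference to clear float cancellation noise
            noise = 8.0 * np.finfo(float).eps * max(abs(fp), abs(fm), abs(f0), 1e-300)
            if abs(second) > noise:
                H_kk = second / h**2
                break
            h *= 10.0
        if H_kk is None or H_kk <= 0:
            logger.warning(
                "parameter %d: non-positive or unresolvable curvature; sd undefined", k
            )
            continue
        sds[k] = math.sqrt(2.0 * chi2_red_min / H_kk)
    return sds


# ---------------------------------------------------------------------------
# 2. Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    mean: np.ndarray
    sd: np.ndarray
    samples: np.ndarray  # (K, n_free)
    labels: list = field(default_factory=list)


def bootstrap(
    result: FitResult,
    K: int = BOOTSTRAP_K,
    seed: int = 0,
    full_search: bool = False,
    popsize: int = 15,
    tol: float = 1e-6,
    maxiter: int = 300,
) -> BootstrapResult:
    """Noise-replica bootstrap around a completed fit.

    Each of the K replicas perturbs every data point by N(0, δR) and
    repeats the differential-evolution refinement.  By default the re-fits
    search a reduced box (the original bounds clipped to best ± 20% of the
    bound range) to keep runtime in check; ``full_search`` restores the
    original bounds.
    """
    if K < 2:
        raise ValueError(f"bootstrap needs K ≥ 2 replicas, got {K}")
    objective = result.objective
    if objective is None:
        raise ValueError("FitResult carries no objective; re-run fit()")
    if not all(c.has_errors for c in objective.curves):
        raise ValueError("bootstrap requires a δR column on every curve")
    rng = np.random.default_rng(seed)
    best = result.best_vector
    if full_search:
        bounds = list(objective.bounds)
    else:
        bounds = []
        for b, (lo, hi) in zip(best, objective.bounds):
            half = 0.2 * (hi - lo)
            bounds.append((max(lo, b - half), min(hi, b + half)))

    originals = [c.R.copy() for c in objective.curves]
    samples = np.empty((K, best.size))
    try:
        for k in range(K):
            for curve, R0 in zip(objective.curves, originals):
                curve.R = R0 + rng.normal(0.0, 1.0, R0.size) * curve.dR
            de = differential_evolution(
                objective.fom,
                bounds=bounds,
                strategy="rand1bin",
                popsize=popsize,
                tol=tol,
                maxiter=maxiter,
                seed=int(rng.integers(2**31 - 1)),
                polish=False,
                init="latinhypercube",
                updating="immediate",
            )
            samples[k] = de.x
    finally:
        for curve, R0 in zip(objective.curves, originals):
            curve.R = R0
    return BootstrapResult(
        mean=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1),
        samples=samples,
        labels=list(objective.labels),
    )


# ---------------------------------------------------------------------------
# 3. Ensemble MCMC
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Flattened posterior chain with its chain-management bookkeeping."""

    chain: np.ndarray  # (samples, n_free), post burn-in, flattened over walkers
    log_prob: np.ndarray
    tau: np.ndarray  # integrated autocorrelation time per parameter (steps)
    burn_in: int  # steps per walker discarded (= 10 max τ_pilot)
    n_steps: int  # production steps per walker retained
    tau_pilot: np.ndarray | None = None  # τ estimated from the pilot chain
    labels: list = field(default_factory=list)

    def sd(self) -> np.ndarray:
        return self.chain.std(axis=0, ddof=1)

    def mean(self) -> np.ndarray:
        return self.chain.mean(axis=0)

    def credible_interval(self, level: float = 0.6827) -> np.ndarray:
        """Central credible interval per parameter, shape (n_free, 2)."""
        lo = 50.0 * (1.0 - level)
        return np.percentile(self.chain, [lo, 100.0 - lo], axis=0).T


def default_walker_count(n_free: int) -> int:
    """Affine-invariant ensembles want comfortably more than 2·dim walkers."""
    return max(2 * n_free + 2, 50)


def _log_probability(objective: Objective, x: np.ndarray) -> float:
    for xi, (lo, hi) in zip(x, objective.bounds):
        if not lo <= xi <= hi:
            return -np.inf
    if not objective.constraints_ok(x):
        return -np.inf
    try:
        models = objective.model_curves(x)
    except Exception:
        return -np.inf
    log_like = 0.0
    for curve, model in zip(objective.curves, models):
        resid = (curve.R - model) / curve.dR
        log_like += -0.5 * float(np.sum(resid**2 + np.log(2.0 * np.pi * curve.dR**2)))
    # normal priors; uniform priors are flat inside the bounds
    log_prior = -0.5 * objective.params.normal_penalty(x)
    return log_like + log_prior


def _max_tau(sampler: emcee.EnsembleSampler, discard: int = 0) -> tuple[np.ndarray, float]:
    tau = sampler.get_autocorr_time(discard=discard, tol=0, quiet=True)
    tau = np.where(np.isfinite(tau) & (tau > 0), tau, 1.0)
    return tau, float(np.max(tau))


def mcmc(
    result: FitResult,
    seed: int = 0,
    nwalkers: int | None = None,
    pilot_steps: int = MCMC_PILOT_STEPS,
    step_cap: int = MCMC_STEP_CAP,
) -> PosteriorSample:
    """Affine-invariant ensemble sampling of the fit posterior.

    Requires δR on every curve (Gaussian likelihood).  Walkers start in a
    tight ball around the best-fit vector.  A pilot chain of
    ``pilot_steps`` estimates τ; the first 10 max(τ) steps are discarded
    and sampling continues until the retained chain is at least
    60 max(τ) steps per walker, re-estimating τ as it goes.  Exceeding
    ``step_cap`` raises, which usually signals bounds that should be
    revised.
    """
    objective = result.objective
    if objective is None:
        raise ValueError("FitResult carries no objective; re-run fit()")
    if not all(c.has_errors for c in objective.curves):
        raise ValueError("MCMC requires a δR column on every curve")
    ndim = objective.n_free
    nwalkers = nwalkers or default_walker_count(ndim)
    rng = np.random.default_rng(seed)

    best = result.best_vector
    widths = np.array([hi - lo for lo, hi in objective.bounds])
    p0 = best[None, :] + 1e-4 * widths[None, :] * rng.standard_normal((nwalkers, ndim))
    for j, (lo, hi) in enumerate(objective.bounds):
        p0[:, j] = np.clip(p0[:, j], lo + 1e-12 * widths[j], hi - 1e-12 * widths[j])

    sampler = emcee.EnsembleSampler(nwalkers, ndim, lambda x: _log_probability(objective, x))
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, pilot_steps, progress=False)
    tau_pilot, tau_max = _max_tau(sampler)
    tau = tau_pilot
    burn_in = int(math.ceil(BURN_IN_TAU_MULTIPLE * tau_max))
    target = burn_in + int(math.ceil(PRODUCTION_TAU_MULTIPLE * tau_max))

    while True:
        done = sampler.iteration
        if done >= target:
            tau, tau_max = _max_tau(sampler, discard=min(burn_in, done // 2))
            target = burn_in + int(math.ceil(PRODUCTION_TAU_MULTIPLE * tau_max))
            if done >= target:
                break
        if done >= step_cap:
            raise RuntimeError(
                f"MCMC did not reach {PRODUCTION_TAU_MULTIPLE}·τ within {step_cap} steps "
                "(τ keeps growing); consider revising parameter bounds"
            )
        state = sampler.run_mcmc(state, min(target - done, step_cap - done), progress=False)

    chain = sampler.get_chain(discard=burn_in, flat=True)
    log_prob = sampler.get_log_prob(discard=burn_in, flat=True)
    return PosteriorSample(
        chain=chain,
        log_prob=log_prob,
        tau=tau,
        burn_in=burn_in,
        n_steps=sampler.iteration - burn_in,
        tau_pilot=tau_pilot,
        labels=list(objective.labels),
    )


# ---------------------------------------------------------------------------
# Corner statistics and confidence bands
# ---------------------------------------------------------------------------


@dataclass
class CornerStats:
    means: np.ndarray
    marginals: list  # per parameter: (counts, bin_edges)
    pairs: dict  # (i, j) -> (counts2d, xedges, yedges), i < j
    correlations: np.ndarray
    labels: list = field(default_factory=list)


def corner_stats(samples: np.ndarray, labels: Sequence[str] | None = None, bins: int = 40) -> CornerStats:
    """Marginal histograms, pairwise 2D histograms and Pearson correlations."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, ndim = samples.shape
    if n < 100:
        raise ValueError(f"need at least 100 samples for corner statistics, got {n}")
    marginals = [np.histogram(samples[:, i], bins=bins) for i in range(ndim)]
    pairs = {}
    for i in range(ndim):
        for j in range(i + 1, ndim):
            counts, xe, ye = np.histogram2d(samples[:, i], samples[:, j], bins=bins)
            pairs[(i, j)] = (counts, xe, ye)
    if ndim == 1:
        corr = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(samples, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
    return CornerStats(
        means=samples.mean(axis=0),
        marginals=marginals,
        pairs=pairs,
        correlations=corr,
        labels=list(labels) if labels is not None else [f"p{i}" for i in range(ndim)],
    )


def corner_plot(samples: np.ndarray, path, labels: Sequence[str] | None = None, bins: int = 40):
    """Render the corner plot: marginals on the diagonal (with the mean
    marked in blue), pairwise 2D histograms below it."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stats = corner_stats(samples, labels=labels, bins=bins)
    ndim = stats.means.size
    fig, axes = plt.subplots(ndim, ndim, figsize=(2.2 * ndim, 2.2 * ndim), squeeze=False)
    for i in range(ndim):
        for j in range(ndim):
            ax = axes[i][j]
            if j > i:
                ax.axis("off")
            elif i == j:
                counts, edges = stats.marginals[i]
                ax.stairs(counts, edges, fill=True, color="0.6")
                ax.axvline(stats.means[i], color="tab:blue")
                if i == ndim - 1:
                    ax.set_xlabel(stats.labels[i])
            else:
                counts, xe, ye = stats.pairs[(j, i)]
                ax.pcolormesh(xe, ye, counts.T, cmap="Greys")
                if i == ndim - 1:
                    ax.set_xlabel(stats.labels[j])
                if j == 0:
                    ax.set_ylabel(stats.labels[i])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return stats


def confidence_band(
    samples: np.ndarray,
    objective: Objective,
    best: np.ndarray | None = None,
    level: float = 0.6827,
    max_draws: int = 200,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Point-wise central credible envelopes of the model curves.

    Evaluates the model over a thinned subset of ≥ min(len, 200) posterior
    (or bootstrap) draws and takes the 15.87/84.13 percentiles per Q point;
    the envelope is widened, where necessary, to contain the best-fit
    curve.  Returns one (lower, upper) pair per curve.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a confidence band")
    idx = np.unique(np.linspace(0, n - 1, min(n, max_draws)).astype(int))
    stacks: list[list[np.ndarray]] = [[] for _ in objective.curves]
    for i in idx:
        try:
            models = objective.model_curves(samples[i])
        except Exception:
            continue
        for s, m in zip(stacks, models):
            s.append(m)
    if not stacks[0]:
        raise ValueError("no sample evaluated successfully")
    best_models = objective.model_curves(best) if best is not None else None
    lo_pct = 50.0 * (1.0 - level)
    bands = []
    for ci, s in enumerate(stacks):
        arr = np.vstack(s)
        lo = np.percentile(arr, lo_pct, axis=0)
        hi = np.percentile(arr, 100.0 - lo_pct, axis=0)
        if best_models is not None:
            lo = np.minimum(lo, best_models[ci])
            hi = np.maximum(hi, best_models[ci])
        bands.append((lo, hi))
    return bands
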
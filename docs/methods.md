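# Methods

`specular` computes and refines specular neutron and X-ray reflectivity
R(Q) of stratified interfaces. This note records the model, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Forward model

**Slab model.** An interface is a list of *patches*, each an ordered stack
of slabs from the semi-infinite fronting medium (layer 0) to the
semi-infinite backing medium (layer N+1). A slab carries a complex
scattering length density ρ = ρ_re + i·ρ_im (Å⁻²), a thickness t (Å), a
roughness σ (Å) that refers to the interface with the *next* layer, and a
solvent volume fraction ϕ_solv. Any of these entries may be a symbolic
expression (sympy) in named parameters and the reserved layer-index symbol
`n` (0 = fronting); only mathematical functions (trig, exp, log, erf, sqrt,
abs, min/max) are admitted — expressions cannot execute general code.

**Reflectivity kernel.** R(Q) is the squared modulus of the total
reflection amplitude of the characteristic-matrix (Abelès) product, with
each interfacial Fresnel coefficient damped by the Névot–Croce factor
exp(−2 k_{z,j} k_{z,j+1} σ_j²). The wavevector convention is

    k_{z,j} = sqrt( (Q/2)² − 4π Δρ_re + 4πi Δρ_im ),   Δρ = ρ_j − ρ_0,

with the principal square root, whose imaginary part is then non-negative
for evanescent and absorbing (ρ_im ≥ 0) layers alike — the decaying-wave
branch. The sign convention matters: the conjugate phase choice is
indistinguishable for real potentials but wrong for absorbing stacks; the
test suite pins it against an independently written Parratt recursion and a
boundary-condition linear solve. The matrix product is accumulated with
periodic rescaling by |M11| so deeply evanescent thick stacks cannot
overflow; only the ratio M21/M11 is used. The inner product is
numba-jit-compiled, with an equivalent pure-numpy path (cross-checked to
2e−14) used when numba is unavailable. Q = 0 is rejected as undefined.

**Solvent mixing.** The wet sld of an interior slab is
(1 − ϕ_solv)·ρ_layer + ϕ_solv·ρ_solvent. The solvent sld defaults to the
*backing* medium's resolved sld (solid/liquid cells); a per-call switch
uses the fronting medium instead (air/water monolayers). Both geometries
occur in practice and nothing in the model file ties a patch to one of
them, so this is an explicit engine option rather than an inference.

**Patches.** Laterally macroscopic regions (larger than the instrument's
coherence length) add incoherently: R_total = Σ c_p R_p with coverages
summing to 1 (tolerance 1e−9).

**Resolution smearing.** δQ is everywhere the FWHM of a Gaussian
approximation to the resolution function (a reader flag converts σ columns
on input). Each smeared point is the Gaussian-weighted average of the
unsmeared model over ±2.5σ (σ = FWHM/2.3548), computed by 17-node
Gauss–Legendre quadrature with pdf weights renormalized to unit sum, so
constants are preserved exactly. A per-point δQ column takes precedence
over a constant δQ/Q. Against a 4001-point dense convolution of the same
truncated window the quadrature is accurate to ~1e−8 on smooth fringe
patterns; directly *at* a total-reflection critical edge the kink in R
limits it to ~0.6% — refine the Q grid there if that matters. Scale and
additive background are applied after smearing (for a Q-independent
background the order is immaterial).

## Profile builders

Continuous volume-fraction profiles are sliced into thin slabs sampled at
mid-planes (second-order accurate; slices carry zero inter-slice
roughness, the region boundaries take the user's roughness):

* **Nanoparticle layer**: close-packed spheres of diameter D give
  ϕ(z) = (4A/D²)(Dz − z²); A ≈ π/(2√3) ≈ 0.91 at close packing. Since
  z/D at slice k is (k − ½)/n, the per-slice solvent fraction is
  independent of D; only the slice thickness D/n carries it — so both A
  and D can stay symbolic and refinable.
* **Polydisperse variant**: diameters D′ ~ N(D, σ_D), truncated to
  [D − 4σ_D, D + 4σ_D] ∩ (0, ∞) and re-normalized; the per-height average
  uses a fixed 401-point trapezoid (deterministic, testable against a
  Monte-Carlo average). The layer extends to D + 4σ_D; entries are
  numeric because the average has no closed symbolic form.
* **Polymer brush**: ϕ(z) = ϕ(0)[1 − (z/L)^n]; n = 2 is the mean-field
  parabolic profile at high grafting density. z/L at a mid-plane is again
  L-free, so ϕ(0), L, n all remain symbolic.
* **Lipid bilayer**: four regions (inner/outer heads and tails) sharing
  one area per molecule A_pm. Each layer entry carries the *molecular*
  sld b/V with ϕ_solv = 1 − V/(A_pm·t); composed with the mixing rule this
  yields the volume-conserving wet sld
  (b + (A_pm·t − V)·ρ_solv)/(A_pm·t), whose lipid part b/(A_pm·t) is the
  dry layer sld reported by `bilayer_dry_sld`. The builder also emits the
  positivity constraints 1 − V/(A_pm·t) > 0, enforced at fit time so a
  refinement cannot wander into negative solvent content.
* **`repeat_stack`** concatenates a layer unit for multilayers; the index
  symbol `n` always denotes the global position in the final stack.

Discretization: for the 150 Å nanoparticle geometry, 100 slices (1.5 Å)
keep R within 0.5% of a 400-slice reference for Q ≤ 0.15 Å⁻¹; the error
grows roughly as (q·Δz)² beyond that, so increase `n_slices` for
wide-range X-ray work.

## Refinement

Four figures of merit, selected by data type and taste (w_i = per-curve
fit weight, p_i = point count; per-point normalization keeps long curves
from dominating co-refinements):

| mode | term per point |
|---|---|
| `linear_err` | ((R_e − R_m)/δR)² |
| `log_err` | ((log₁₀R_e − log₁₀R_m)·R_e·ln10/δR)² |
| `linear_noerr` | (R_e − R_m)²/R_e |
| `log_noerr` | (log₁₀R_e − log₁₀R_m)² |

The `log_err` denominator is Gaussian error propagation,
δ(log₁₀R)² = [δR/(R ln10)]²; for ~1% residuals the two error-weighted
modes agree to first order. Non-positive measured R is dropped (with a
logged count) in the log and 1/R-weighted modes; non-positive *model*
values are floored at 1e−300 so log residuals stay finite and large.
Requesting an error-weighted mode without a δR column falls back to the
matching no-error mode with a warning.

Minimization is scipy differential evolution (`rand1bin`, population
15 × dimension, relative tolerance, no polishing stage), deterministic
under a fixed seed. Free parameters are declared uniform (min/max box) or
normal (mean/sd): normal parameters are searched inside mean ± 5 sd and add
a Gaussian penalty ((x − μ)/sd)² to the objective, which lets the
derivative-free search respect the prior without rejection sampling.
Multi-parameters hold one (kind, bound, bound) triple per co-refined curve
— the natural encoding of per-contrast solvent slds or the ±magnetic sld
of non-spin-flip polarized measurements — and each free triple is one
dimension of the search. Candidates violating an inequality constraint or
resolving to ϕ_solv ∉ [0, 1] receive a large finite penalty (1e10), never
NaN: definition errors crash early at `calculate` time, but a fit must
survive its own search space. Scale, background and per-curve weights are
ordinary settings and can be promoted to fitted (multi-)parameters by the
user model.

χ²_red = Σ((R_e − R_m)/δR)²/(N − |α|) is reported alongside the FOM
whenever errors exist; on δR-consistent synthetic noise it sits in
[0.5, 1.5] for N ≥ 200.

## Uncertainty estimation

* **Hessian**: σ_k = sqrt(2 χ²_red,min / H_kk). The landscape passed by
  the pipeline is the *unreduced* χ², which makes this the standard scaled-
  covariance estimate and reproduces ordinary-least-squares covariance on a
  linear model with χ²_red ≈ 1 (tested). The curvature uses central second
  differences with a step that grows (up to ×10⁴) until the difference
  clears float cancellation noise; flat or negative curvature yields NaN
  plus a warning rather than a fabricated number.
* **Bootstrap** (K = 1000 by default): every point of every curve is
  re-drawn as R + N(0, δR) and the DE refinement repeated per replica.
  Re-fits search the original bounds clipped to best ± 20% of the bound
  range to bound runtime; `full_search=True` (CLI
  `--bootstrap-full-search`) restores the full box. Reports per-parameter
  mean/sd and the K × n sample matrix.
* **MCMC** (emcee, affine-invariant ensemble): Gaussian likelihood
  −½Σ[((R_e − R_m)/δR)² + ln(2π δR²)], priors uniform-in-bounds or
  Normal(μ, sd), constraints as hard rejection. Walkers default to
  max(2·n_free + 2, 50) and start in a 1e−4-width ball around the DE best.
  A 500-step pilot estimates the integrated autocorrelation time τ
  (autocorrelation windowing, c = 5); burn-in is 10·max(τ), and sampling
  continues until the retained chain exceeds 60·max(τ) steps per walker
  under the re-estimated τ, capped at 50 000 steps (exceeding the cap
  raises, usually a sign the bounds should be revised).

On a well-conditioned single-film problem the three routes agree within a
factor ~1.1 (the acceptance suite enforces 1.5). Bootstrap and MCMC sample
matrices feed corner statistics (marginal histograms with the mean marked,
pairwise 2D histograms, Pearson correlation matrix; ≥100 samples required)
and point-wise 1σ confidence bands: central 68.27% percentiles over ≥200
thinned draws, widened where necessary to contain the best-fit curve, with
no simultaneous-band correction.

## Synthetic data

`generate_curve` evaluates a model forward (smeared, scaled) and attaches
δR = f·R + 0.2·background with f the plateau-relative floor (default 1%),
then adds N(0, δR) noise; δR/R thus rises from ~1% on the plateau to ~21%
where R falls to the background, mimicking time-of-flight counting
statistics. A `poisson_like` option scales δR ∝ √R instead. Zero noise
returns the model exactly (and no δR column). `generate_contrast_series`
shares one bilayer structure across several solvent slds — the
multi-parameter co-refinement harness.

What passing these tests shows: the estimator machinery is calibrated —
parameters used to generate data are recovered within their own estimated
uncertainties, 68% intervals cover at the nominal rate (69/100 observed),
and the three uncertainty routes agree. What it does not show: robustness
to model misspecification, non-Gaussian or correlated instrument noise,
footprint/alignment artefacts, or incoherent-background structure; real
data carry all of these.

## Problem sizes used in the shipped checks

Brush recovery: quartz / 3.9 Å water / 80-slice brush (ϕ(0)=0.10, L=480 Å,
n=2) / d-toluene, 140 points on Q ∈ [0.008, 0.10] Å⁻¹, 2% noise, DE then
14-walker MCMC. Bilayer: three contrasts × 80 points, 1% noise, A_pm and
three solvent slds free. Coverage: 100 replications of a one-parameter
film fixture at 30 points with 8 walkers. Concordance: the same film at 60
points, bootstrap K = 200. These sizes are the package's own defaults for
its self-checks; all thresholds (3 sd recovery, coverage in [60, 76],
factor-1.5 concordance, 1e−10/1e−8/1e−4 oracle agreements) are fixed
independently of them.

## Known limitations

* Spin-flip polarized reflectivity (4×4 formalism) is out of scope;
  non-spin-flip polarized data are co-refined by giving the magnetic sld
  contribution as a ±multi-parameter, which needs no engine change.
* The smearing kernel is Gaussian only; no instrument-specific resolution
  shapes.
* No gradient-based local refinement after DE, and no model-evidence
  (nested-sampling) machinery.
* Layer-entry expressions are scalar per layer; profiles that need
  thousands of slices pay a per-slice resolution cost (mitigated by
  entry pre-compilation, but still linear in slice count).
* ORSO file format and reflectivity from molecular-dynamics trajectories
  are not implemented.
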
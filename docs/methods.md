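# Methods

## The baseline model

A measured Raman/SERS spectrum is modeled as

    y(ν̃) = s(ν̃) + z(ν̃) + ε(ν̃)

with `s` the nonnegative peak signal, `z` a slowly varying background
(fluorescence, substrate scattering) and `ε` i.i.d. Gaussian channel
noise. Baseline removal estimates `z` and reports `y − z`.

The estimator is the adaptive iteratively reweighted penalized
least-squares (airPLS) family: each iterate solves the weighted
Whittaker system

    (W + λ DᵀD) z = W y,

where `D` is the order-`p` forward-difference operator, `λ > 0` weights
smoothness against fidelity, and `W = diag(w)`. Iteration `t` computes
the residual `d = y − z`, the negative-residual mass
`m = Σ_{d_i<0} |d_i|`, stops when `m < τ·Σ|y|`, and otherwise sets
`w_i = 0` where `d_i ≥ 0` and `w_i = exp(t·|d_i|/m)` where `d_i < 0`.
Initial weights are all ones, so iteration 1 is an unweighted smooth.
Over iterations the baseline relaxes onto the lower envelope of the
spectrum. Three parameters matter:

| parameter | role | default |
| --- | --- | --- |
| `λ` | smoothness weight (larger → smoother) | 100 |
| `τ` | convergence tolerance on negative-residual mass | 1e-3 |
| `p` | difference order (1 or 2) | 1 |

The `(100, 1e-3, 1)` triple is the classical default ("DP" mode); the
optimized mode ("OP") fixes `p = 2` for curvature-smooth baselines and
tunes `(λ, τ)` per spectrum.

### Numerical choices

- The banded symmetric system is solved with a banded Cholesky
  (`scipy.linalg.solveh_banded`), O(n) time and memory. A pivoted
  banded LU is the fallback when extreme weight dynamic range defeats
  the Cholesky.
- The reweighting exponent is clipped at 50. The clip preserves weight
  ordering; anything above ~`exp(50)` is already "infinitely" heavier
  than a zero-weight channel, and keeping pivot squares below ~3e43
  guarantees a factorizable system in double precision. `m` is floored
  at `eps·Σ|y|` so the update never divides by zero.
- Reaching `max_iter` (default 100) returns `converged=False` rather
  than raising, which keeps batch optimization robust.
- Reported final weights are normalized by their maximum (entries in
  [0, 1]); the stored `weight_scale` restores the raw system.
- The difference penalty ignores wavenumber spacing; grids are assumed
  (near-)uniform.

## Synthetic spectra

Each spectrum combines one of three Gaussian-peak families — broad
(`B`), convoluted (`C`, overlapping cluster), distinct (`D`, resolved)
— with one of four baseline families — exponential (`E`), wide Gaussian
(`G`), fifth-order polynomial (`P`), sigmoidal (`S`) — on a 400–2000
cm⁻¹ grid with 1024 points. The 3×4 grid gives 12 canonical shapes
(`B&E` … `D&S`); compound baselines average two families with equal
weights, and the compound peak type sums a `B` and a `C` draw.

Key generator conventions (each a named constant):

- `B` spectra are peak-dominated: peak amplitude scale 100 versus 1 for
  `C`/`D`, with background amplitude only 0.15 of the peak scale. This
  reproduces the characteristic orders-of-magnitude gap in absolute
  baseline errors between broad-peak and narrow-peak spectra.
- All backgrounds ride on a constant pedestal about twice the varying
  amplitude, as fluorescence backgrounds in measured SERS spectra do.
  Constants lie in the null space of both difference penalties, so the
  pedestal does not limit what a tuned fit can recover — but it enters
  the `Σ|y|` normalization of the stopping rule, which is exactly why
  default-parameter fits stall near the raw spectrum on smooth inputs.
- Baseline families are smooth at the broad-peak bridging scale
  (exponential decay rate 0.5–2 per range, Gaussian width 0.5–1.0 of
  the range, sigmoid steepness 3.5–6.5 per range, polynomial
  coefficients decaying as 0.45^k with the swing capped). Under a broad
  peak the fit must bridge a ~0.2-range blind window; backgrounds with
  structure finer than that window are unidentifiable there by any
  baseline algorithm.
- SNR is defined as `max(true_signal) / noise_std` (a common
  spectroscopy convention; the definition is isolated in `NoiseSpec`
  and easy to swap). The noise ladder spans 6.47–49.92 in 10
  geometric steps.

Randomness flows through `numpy.random.SeedSequence` substreams keyed
by `(master_seed, shape_index, spectrum_index)` and a per-role tag, so
datasets are bit-reproducible and any single spectrum can be
regenerated in isolation.

What the generator does *not* emulate: Lorentzian/Voigt line shapes,
cosmic-ray spikes, detector etaloning, wavenumber-dependent noise, or
instrument response. Passing tests therefore demonstrate correctness of
the optimization and prediction machinery on idealized spectra, not
performance on any particular instrument's data.

## Adaptive grid search (OP mode)

Per spectrum, the search minimizes the mean absolute error (MAE)
between the fitted and the *known true* baseline over
`(log₁₀λ, log₁₀τ) ∈ [0, 10] × [−10, −1]`, with `p = 2`. A 5×5
log-uniform grid is evaluated, the window recenters on the incumbent
best and shrinks by 0.5 per refinement. Convergence: the running-best
MAE changes by less than 5 % (relative) for 5 consecutive refinements;
hard cap 50 refinements; windows narrower than 1e-3 log-units also
stop. Ties break toward smaller `λ`, then smaller `τ`. The first
window is centered on the initial guess rather than the bounds' center,
so warm starts shape the search; across a dataset, each spectrum of a
shape group starts from the previous spectrum's optimum (first spectrum:
the classical defaults `(100, 1e-3)`).

The reported `refinements` value counts productive steps — up to the
last refinement that still improved the running best by more than the
tolerance — while `total_refinements` includes the confirming steps of
the convergence window. Convergence is to a local minimum; different
starts can land in different (similarly good) minima.

Evaluation metrics: signed percentage improvement
`PI = (MAE_DP − MAE_OP)/MAE_DP × 100` (90 ⇔ a tenfold error reduction,
99 ⇔ a hundredfold; negative ⇔ degradation), threshold fractions
`Pct(PI ≥ x)`, geometric/arithmetic parameter centers (LOC/LIC), the
ordinary-least-squares fit of `log₁₀τ*` on `log₁₀λ*` describing the
diagonal valley where optima concentrate, and chi-square-scaled 95 %
confidence ellipses of parameter clouds. PI is implemented signed
(not absolute) so that degradations — which occur for noisy inputs —
are visible and the outlier rule is well defined.

## PCA-RF parameter prediction (ML mode)

Datasets are split 8:1:1 per shape (exact floor counts, remainder to
train; deterministic under a seed). A PCA projection (smallest
component count explaining 99.5 % of training variance, capped at 50)
feeds a 100-tree random forest regressing the 2-vector
`(log₁₀λ*, log₁₀τ*)` jointly — a single model for both correlated
targets. Predictions exponentiate the forest output and clamp `τ̂`
into `(1e-12, 0.5)`. A prediction is flagged as an outlier when its
PI is negative or its MAE exceeds 10× the grid-searched optimum; the
per-shape summary reports means with and without outliers. The trainer
accepts any scikit-learn-style regressor in place of the forest, but
the forest is the shipped configuration.

## Preprocessing

Model predictions are trained on noise-free spectra and degrade with
channel noise, so measured spectra should be Savitzky-Golay smoothed
(window 15, order 2, polynomial-interpolated edges — inputs that are
globally quadratic pass through exactly) before prediction. The SNR
estimator is an implementer convention: signal amplitude = maximum of
the smoothed spectrum above a quick stiff airPLS baseline proxy; noise
= robust MAD-based standard deviation of the first differences of the
smoother residual, divided by 1.419 (the calibration constant of that
statistic for white Gaussian noise under the (15, 2) smoother).
Near-noise-free spectra saturate the estimator; values are capped at
1e6. The estimate is monotone in the constructed noise level on
synthetic data, which is all it is used for.

## Problem sizes

The full study scale is 12 shapes × 500 spectra (6000) with 10 noise
levels; the package runs that scale unchanged, but tests and the
reproduction script use reduced sizes chosen to keep runs at minutes on
one CPU while leaving per-shape statistics meaningful: 12 × 6 for the
grid-search statistics, 12 × 40 (split 32/4/4 per shape) for the
prediction study, 12 compound spectra, and the top-of-ladder SNR 49.92
for the noise/denoise comparison.

## Known limitations

- Grid-search optimality is relative to the searched box and grid
  resolution; the search is local by design.
- The predictor generalizes along the training manifold: spectra
  dissimilar from all training shapes (low cosine similarity) get
  unreliable parameters. Compound shapes built from trained families
  remain within reach; genuinely novel backgrounds do not.
- PI compares against the classical-default fit on the *same* input;
  on noisy inputs both the reference and the prediction degrade, so PI
  under noise mixes both effects.
- The generator's family parameters are package conventions; they are
  single named constants precisely so alternative published
  distributions can be dropped in.
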
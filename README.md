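# airpls-opt

Baseline correction for Raman and surface-enhanced Raman (SERS)
spectra with the airPLS (adaptive iteratively reweighted penalized
least-squares) family, plus the machinery to *choose its parameters
well*: a per-spectrum adaptive grid search against known true
baselines, and a PCA + random-forest model that predicts near-optimal
parameters directly from a raw spectrum.

## Who this is for

Spectroscopists and chemometricians who preprocess Raman/SERS spectra
and have been bitten by airPLS's parameter sensitivity: the classical
defaults (λ = 100, τ = 10⁻³, p = 1) produce piecewise-linear baselines
and large errors under broad peaks, and no single fixed parameter set
works across spectral shapes.

## The method in brief

airPLS estimates the baseline `z` of a spectrum `y` by iterating the
weighted Whittaker smoother

    (W + λ DᵀD) z = W y,   W = diag(w),

where `D` is the order-`p` difference operator. Channels above the
current baseline get weight 0, channels below get exponentially
growing weights, and iteration stops when the negative-residual mass
falls below `τ·Σ|y|`. This package adds:

- **OP mode** — fix `p = 2`, adaptively grid-search `(λ, τ)` in log
  space per spectrum to minimize the mean absolute error (MAE) against
  a known true baseline, warm-starting each spectrum at the previous
  same-shape optimum. Improvement is measured as
  `PI = (MAE_DP − MAE_OP)/MAE_DP × 100` (90 ⇔ one order of magnitude).
- **ML mode** — train a PCA projection + 100-tree random forest on
  grid-searched optima to map a spectrum directly to
  `(log₁₀λ*, log₁₀τ*)`; per-shape optima form tight clusters inside a
  rising diagonal low-error valley of the log-log parameter plane.
- A synthetic SERS generator (3 peak families × 4 baseline families =
  12 shapes, compound shapes, SNR-controlled noise) with exact
  ground-truth decomposition for all of the above.

## Worked example

```python
from airpls_opt import SyntheticShapeSpec, generate_spectrum
from airpls_opt.baseline import AirPLSParams, airpls_fit
from airpls_opt.optimize import optimize_spectrum, DP_PARAMS
from airpls_opt.metrics import mae, percentage_improvement

# a convoluted-peak / Gaussian-baseline spectrum with known truth
s = generate_spectrum(SyntheticShapeSpec.from_label("C&G", rng_seed=7))

mae_dp = mae(airpls_fit(s, DP_PARAMS).baseline, s.true_baseline)
res = optimize_spectrum(s)
print(f"MAE default  : {mae_dp:.4g}")
print(f"MAE optimized: {res.mae_star:.4g}  at lam*={res.lam_star:.3g}, tau*={res.tau_star:.3g}")
print(f"improvement  : {percentage_improvement(mae_dp, res.mae_star):.2f}%")
```

prints

```
MAE default  : 0.1452
MAE optimized: 2.275e-05  at lam*=8.66, tau*=5.05e-10
improvement  : 99.98%
```

i.e. the default fit misses the true baseline by ~0.15 intensity units
on average (it stalls close to the raw spectrum), while the
grid-searched `(λ*, τ*)` with `p = 2` cuts that error by more than
three orders of magnitude.

The command-line interface mirrors the library
(`airpls-opt generate | fit-baseline | optimize | evaluate | train |
predict | denoise | pipeline`); `airpls-opt pipeline --n-per-shape 50
--seed 0 --out run/` executes the whole study end to end and writes
per-stage CSV/JSON artifacts.

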
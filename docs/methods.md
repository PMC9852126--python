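# Methods

## Model class

All models are Gaussian additive models

y = α + Σ_k f_k(x_k) + ε,

fitted by penalized least squares: minimize ‖y − Xβ‖² + Σ_j λ_j βᵀS_jβ,
where each smooth f_k is a spline basis expansion and each S_j penalizes
the integrated squared second derivative ∫f″(x)²dx of one smooth (or one
direction of a tensor smooth). No link functions or non-Gaussian
families are provided; the median (quantile) loss below is the one
departure from squared error.

### Spline bases

* **Natural cubic** (`cubic_basis(..., natural=True)`): the cardinal
  (value-at-knot) parameterization — coefficient j is the function value
  at knot j, and the curve is the natural cubic interpolant. C2
  continuity is implicit, the second and third derivatives vanish at the
  outer knots, and evaluation beyond them extrapolates the linear tail.
  The penalty has the exact closed form S = DᵀB⁻¹D from the tridiagonal
  interpolation system; its nullspace is the 2-dimensional space of
  straight lines.
* **Cyclic cubic** (`cyclic_cubic_basis`): the same construction with the
  first and last knot identified, so k nominal knots give k−1 basis
  functions, periodic through the second derivative; inputs wrap modulo
  the period. Penalty nullspace: constants only.
* **Plain cubic** (`cubic_basis(..., natural=False)`): a clamped B-spline
  basis spanning all C2 piecewise cubics (dimension k+2); the penalty is
  computed by per-interval Gauss–Legendre quadrature, which is exact for
  these piecewise-polynomial integrands. Out-of-range evaluation clamps
  with a warning (no principled tail exists without the natural
  constraint).
* **Tensor products** (`tensor_smooth`): row-wise products of two
  marginal bases with two Kronecker-structured penalties, S_x ⊗ I and
  I ⊗ S_y, one smoothing parameter per direction. Building the tensor
  from *centered* margins excludes the marginal main effects from its
  span, so the term carries only genuine interaction structure next to
  the main-effect smooths.
* **Centering** (`apply_centering`): sum-to-zero over the fitting data,
  absorbed by a null-space reparameterization (dimension drops by one,
  penalties transformed consistently). This is what makes the intercept
  of the PP model the mean pulse pressure.
* **Adaptive penalties** (`adaptive_penalty`): the single ∫f″² penalty is
  split into m sub-penalties weighting the integrand by piecewise-linear
  tents that form a partition of unity, so REML can stiffen flat regions
  while leaving a sharp transition (inspiration→expiration) free. At
  equal weights the sub-penalties sum exactly to the ordinary penalty.
  For a cyclic basis the tent grid spans one period without wrapping;
  only the penalty weights, not the basis, are non-periodic.

Knots default to the empirical quantiles of the covariate (minimum and
maximum included), so each segment holds about the same number of
observations; uniform and explicit placement are available. Duplicate
quantile knots (heavily tied covariates) are collapsed with a warning.

### Smoothing-parameter selection

λ is chosen by restricted maximum likelihood: the profiled Gaussian REML
score is minimized in log-λ — Nelder–Mead up to four free parameters,
cyclic 1-D bounded searches above that (the section-comparison model has
18). The score uses the generalized determinant of the total penalty,
computed blockwise per term. The optimizer's adequacy is checked two
ways: against a grid-search oracle on the realized prediction error, and
against mgcv's REML on identical data (fits agree to ~1e-5). Note that a
grid oracle picks the luckiest λ for each noise realization, so the
realized-MSE ratio REML/oracle is heavy-tailed per draw even for an
exact REML; averaged over replicates it sits near 1.1.

### Uncertainty

`posterior_covariance` is (XᵀX + Σλ_jS_j)⁻¹σ̂² with σ̂² = RSS/(n − edf),
the standard Bayesian covariance of a penalized smooth given λ.
Intervals are pointwise ±1.96·SE. The PPV interval is the 2.5/97.5
percentile of PPV recomputed over draws from the coefficient posterior
(50 000 by default) — a reconstruction by posterior simulation, chosen
because the statistic (a range over a ratio) has no convenient closed
form. Being pointwise, the ±2·SE bands admit occasional small excursions
when scanned over a dense grid; measured coverage of the PPV interval
over 200 simulated records is 0.985.

### Autocorrelated residuals

Densely sampled waveforms have autocorrelated noise; ignoring it gives
confidence bands that are too narrow. `fit_ar1` whitens rows (first row
of each section scaled by √(1−ρ²), then r_t − ρr_{t−1}, recursion
restarting at section boundaries) and refits; ρ is estimated by a
two-pass scheme — fit with ρ=0, take the lag-1 autocorrelation of the
residuals within sections, whiten, refit. With ρ=0 the path is the
identity transform (bit-identical to the plain fit). In simulation the
corrected bands restore ≈95% pointwise coverage where the independence
fit gives ≈73%.

### Median (quantile) fitting

`fit_quantile` minimizes the penalized pinball loss by iteratively
reweighted least squares on a smoothed check function; the smoothing
bandwidth is 5% of a MAD-based residual scale, and REML re-selects λ on
the working weighted problem every ten iterations (so λ is effectively
chosen on the final weighted problem). Non-convergence inside the
iteration cap returns the last iterate with a warning — observed
occasionally on waveform-sized problems, where the returned fit is
nonetheless stable to well below the noise floor. The median fit makes
no distributional assumption, so a large transient artifact cannot echo
into other respiratory cycles the way it does under squared error.

## Hemodynamic models and defaults

Basis sizes (all configurable): PP respiratory smooth 10 knots, PP trend
10; CVP cardiac smooth 30 (five landmarks per cycle need resolution),
CVP respiratory 14, tensor 10×8, trend 10; section-comparison
respiratory smooth 20 knots with 5 adaptive sub-penalties. The trend
smooth is deliberately small: it should absorb drift, not respiration.
The cardiac covariate is absolute seconds since the latest P wave, not a
cycle fraction — cardiac cycle length varies (respiratory sinus
arrhythmia) and the waveform does not stretch proportionally with it.
The P-wave times are QRS times minus a constant, user-supplied PR
interval (default 0.15 s, a convention; it only shifts the cycle origin
so atrial contraction sits at the start of a cycle). PPV extremes are
located on a 512-point grid over one cycle. Section-comparison
predictions at "end-inspiration" and "end-expiration" default to
respiratory positions 0.3 and 0.95. A single AR(1) ρ is shared across
sections in the joint section model (the whitening recursion still
restarts at the boundary).

Preprocessing: beats are detected as prominent maxima of a lightly
smoothed (40 ms) arterial trace with a refractory period of
60/max_heart_rate s, the diastole as the raw minimum between peaks, and
the beat is timestamped at the diastole (configurable). Prominence
defaults to 25% of the signal's interdecile range. Beats or samples
outside the annotated inspiration window are dropped, not extrapolated —
first and last partial cycles are unidentifiable. Without annotations,
respiratory position falls back to time modulo a known or spectrally
estimated period (classical periodogram for uniform sampling,
Lomb–Scargle for irregular beat series, both restricted to a plausible
band of 6–40 breaths/min), with arbitrary phase.

## Synthetic data

The generators define the conditions every claim is tested under. The
PP generator emits beats at a fixed heart rate with PP = mean + cyclic
respiratory modulation (sinusoid for closed-form checks, skewed and
plateau shapes otherwise) + slow trend + white noise; defaults are mean
PP 8 mmHg, 0.6 mmHg sinusoidal modulation (true PPV 15%), 75 bpm
against 15 breaths/min, noise SD 0.3 mmHg, 300 beats. The CVP generator
sums a per-cycle cardiac template of Gaussian bumps and dips at the
a/c/x′/v/y landmark positions (fractions 0.08/0.18/0.35/0.62/0.80 of the
cycle), a plateau-shaped respiratory modulation with a sharp
expiratory transition (to exercise the adaptive smooth), an optional
interaction that scales the x′ dip by (1 + g·cos(2π·pos)), a trend,
stationary AR(1) noise (default ρ 0.6, marginal SD 0.3 mmHg) and
optional rectangular artifact bursts with ramped edges; defaults are
30 s at 125 Hz, 80 bpm, 14 breaths/min, mean 8 mmHg. These are
schematic waveforms, not circulatory simulations: real CVP morphology
varies beat to beat, baselines wander nonlinearly, artifacts are more
diverse, and spontaneous breathing efforts (absent here, as the models
assume deep sedation) distort the respiratory cycle. Passing tests
therefore demonstrate correct recovery of the modelled structure, not
performance on arbitrary clinical recordings.

## Numerical notes and limitations

* Penalized systems are solved by Cholesky on XᵀX + Σλ_jS_j; at extreme
  fixed λ (≳1e10 on unit-scale covariates) conditioning degrades — REML
  never selects such values, but manual λ should stay moderate.
* REML surfaces for many-λ models are mildly multimodal; the coordinate
  scheme is run from scale-matched starting values and capped, with a
  warning on non-convergence.
* The identifiability check inspects only penalty nullspaces (the
  unpenalized span); perfectly confounded *penalized* directions are
  left to the penalties to resolve.
* Samples whose cardiac position exceeds the usual cycle length (long
  diastoles) sit in the extrapolation region of the non-cyclic cardiac
  smooth and inherit its linear tail.
* Hierarchical (multi-subject) models, non-Gaussian families, thin-plate
  splines and >2-dimensional tensors are out of scope.
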
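# hemogam

Decompose hemodynamic waveforms from mechanically ventilated patients into
physiologically meaningful components with penalized-spline additive
models.

## The problem

Arterial and central venous pressure signals mix several periodic
processes: the cardiac cycle, the ventilator's respiratory cycle, their
interaction, and slow drift from vascular tone, surgery or medication.
Clinically important quantities live in the respiratory component — most
prominently **pulse pressure variation (PPV)**, a dynamic predictor of
fluid responsiveness — but bedside algorithms that extract them are
proprietary and opaque. An additive model with spline smooths makes the
decomposition transparent: each component is an inspectable curve with a
confidence band.

`hemogam` is for researchers in hemodynamic monitoring and heart–lung
interaction physiology who want such decompositions from Python, from raw
waveforms or beat tables, with every modelling step open.

## The models

Pulse pressure per beat, with `pos` the beat's position in the
respiratory cycle (time since the latest inspiration start over the cycle
length, in [0, 1)):

    PP = α + f(pos) + f(t) + ε

`f(pos)` is a cyclic cubic spline (continuous through the second
derivative across the cycle seam), `f(t)` a natural cubic spline, both
penalized by the integrated squared second derivative ∫f″² with smoothing
parameters chosen by REML. Because the smooths are centered, α is the
mean PP and

    PPV = (max f(pos) − min f(pos)) / α

which coincides with the classic (PPmax − PPmin)/PPmean formula when
beats sample the cycle densely. A 95% CI comes from posterior simulation
of the coefficients.

CVP, per sample of the 125 Hz waveform, with `c` seconds since the latest
P wave and `pos` as above:

    CVP = α + f(c) + f(pos) + f(c, pos) + f(t) + ε

`f(c)` is a non-cyclic smooth (cardiac cycles vary in length, so a
fractional cyclic coordinate would wrongly stretch the waveform),
`f(c, pos)` a tensor-product smooth — non-cyclic in the cardiac
direction, cyclic in the respiratory direction, one smoothing parameter
per direction — capturing how the cardiac pattern (e.g. the depth of the
x′ descent) changes with respiratory phase. Residuals carry an AR(1)
model, without which the confidence bands of densely sampled waveform
fits are too narrow. Two recording sections (before/after a fluid bolus)
are compared in a joint fit with a section constant β_s and per-section
smooths, the respiratory smooth carrying an adaptive (regionally
weighted) penalty. For artifact-laden signals, a median (quantile) fit
under the pinball loss replaces least squares.

All of it — the cubic/cyclic/tensor bases with exact curvature
penalties, REML, AR(1) whitening, quantile IRLS, posterior simulation —
is implemented in this package on the numpy/scipy stack; one test
cross-checks the basis spans and REML fits against R's mgcv.

## Worked example

```python
import hemogam as hg

beats, truth = hg.gen_pp_series(hg.PPGeneratorConfig(seed=7))
fit = hg.fit_pp_model(beats)
result = hg.compute_ppv(fit, n_draws=20_000, seed=1)
print(result.ppv, result.ci_low, result.ci_high)
```

Running `python examples/01_ppv_from_beats.py` prints:

```
true PPV        : 15.00 %
estimated PPV   : 15.09 % [13.80, 17.43] (95% CI)
mean PP (alpha) : 7.96 mmHg
smooth range    : 1.20 mmHg over one respiratory cycle
beats used      : 300
```

The generator built 300 beats with mean PP 8 mmHg and a 0.6 mmHg
sinusoidal respiratory modulation (true PPV = 2·0.6/8 = 15%); the model
recovers 15.09% with an interval that covers the truth. The `smooth
range` is the peak-to-trough swing of the fitted respiratory smooth in
mmHg; dividing by α turns it into PPV. The other scripts in `examples/`
walk through the CVP decomposition, the fluid-bolus section comparison,
the robust median fit and the spectral respiratory-rate fallback for
recordings without ventilator timestamps.

A thin CLI wraps the same functions for file-based use:

```bash
hemogam simulate --kind pp --seed 3 --out-dir sim
hemogam ppv --beats sim/beats.csv --events sim/inspiration_starts.csv
hemogam cvp --waveform w.csv --qrs qrs.csv --events insp.csv --model interaction
hemogam compare --waveform-pre a.csv --waveform-post b.csv ...
```

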
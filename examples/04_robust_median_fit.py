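"""Robustly fit a contaminated CVP signal with a median (quantile) model.

Medical pressure signals carry occasional large artifacts (transducer
flushes, line manipulation).  A least-squares fit spreads such an
artifact across the respiratory smooth — an 'echo' appears one
respiratory period away from the true disturbance.  Fitting the median
of the signal under the pinball loss bounds the artifact's influence.
"""

import warnings

import numpy as np

import hemogam as hg

cfg = hg.CVPGeneratorConfig(
    seed=77, duration_s=15, noise_sd=0.2, ar1_rho=0.3,
    outliers={"magnitude": 25.0, "duration_s": 0.75, "at": [6.0]})
wave, ann, truth = hg.gen_cvp_wave(cfg)
segment = hg.WaveformSegment.from_frame(wave)
samples = hg.build_cvp_table(segment, ann["qrs_times"], ann["insp_starts"])

gauss = hg.fit_cvp_additive(samples, ar1="off")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    median = hg.fit_cvp_additive(samples, ar1="off", loss="median")

t = samples["time_s"].to_numpy()
idx = np.round(t * cfg.sample_rate).astype(int)
clean = truth["signal"][idx]
away = (t < 5.0) | (t > 8.0)  # samples clear of the artifact itself

dev_g = np.abs(gauss.fitted_values - clean)[away].max()
dev_m = np.abs(median.fitted_values - clean)[away].max()
print("a +25 mmHg artifact covers 5% of a 15 s record at t = 6.0-6.75 s")
print(f"max spurious deflection, least-squares fit : {dev_g:.2f} mmHg")
print(f"max spurious deflection, median fit        : {dev_m:.2f} mmHg")
print(f"suppression ratio                          : {dev_m / dev_g:.2f}")
# The least-squares echo is the price of squaring errors: being a little
# wrong twice beats being doubly wrong once.  The median fit pays no such
# price and tracks the uncontaminated signal.
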
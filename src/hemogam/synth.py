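"""Synthetic hemodynamic data with known ground truth.

Two generators emulate the data structures the models are built for:

* ``gen_pp_series`` — a per-beat pulse-pressure series from a mechanically
  ventilated patient: mean PP plus a cyclic respiratory modulation, a slow
  trend and white beat-to-beat noise.  The true pulse pressure variation
  (PPV) implied by the modulation shape is returned with the data.
* ``gen_cvp_wave`` — a 125 Hz central venous pressure waveform built from a
  per-cycle cardiac template with the five classic landmarks (a and c waves,
  x' descent, v wave, y descent, as Gaussian bumps and dips), an additive
  cyclic respiratory modulation, an optional cardiac-by-respiratory
  interaction that modulates the depth of the x' descent with respiratory
  phase, a slow trend, AR(1) noise and optional artifact bursts.

Every random quantity flows from the single ``seed``; identical configs
produce bit-identical datasets.  Ground truth (component functions, event
times, true PPV) is returned alongside each dataset so that fits can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PPGeneratorConfig",
    "CVPGeneratorConfig",
    "gen_pp_series",
    "gen_cvp_wave",
    "gen_abp_wave",
]


# ---------------------------------------------------------------------------
# Shape helpers
# ---------------------------------------------------------------------------


def _resp_shape(spec):
    """Zero-mean periodic modulation shape on [0, 1) from a spec tuple.

    ``("sinusoid", A)``      -> A * sin(2 pi pos)
    ``("skewed", A, phase)`` -> asymmetric two-harmonic shape, peak ~A
    ``("plateau", A)``       -> smoothed square pulse: rise over inspiration
                                (first ~1/3 of the cycle), sharp fall into
                                expiration; exercises adaptive smoothing.
    Returns (callable, peak-to-trough range).
    """
    kind = spec[0]
    if kind == "sinusoid":
        A = float(spec[1])

        def f(pos):
            return A * np.sin(2.0 * np.pi * np.asarray(pos))

        return f, 2.0 * A
    if kind == "skewed":
        A = float(spec[1])
        phase = float(spec[2]) if len(spec) > 2 else 0.0

        def f(pos):
            p = np.asarray(pos) - phase
            return A * (np.sin(2 * np.pi * p) + 0.4 * np.sin(4 * np.pi * p))

        grid = f(np.linspace(0, 1, 4096, endpoint=False))
        return f, float(grid.max() - grid.min())
    if kind == "plateau":
        A = float(spec[1])
        insp_frac = float(spec[2]) if len(spec) > 2 else 0.33
        # smooth periodic pulse: square wave circularly smoothed by a
        # periodic Gaussian kernel, then mean-centered
        m = 2048
        g = np.linspace(0, 1, m, endpoint=False)
        raw = ((g >= 0.02) & (g < insp_frac)).astype(float)
        k = np.exp(-0.5 * (np.minimum(g, 1 - g) / 0.015) ** 2)
        sm = np.real(np.fft.ifft(np.fft.fft(raw) * np.fft.fft(k / k.sum())))
        sm = sm - sm.mean()
        sm = sm / (sm.max() - sm.min()) * A
        grid = sm

        def f(pos, grid=grid, m=m):
            p = np.mod(np.asarray(pos, dtype=float), 1.0) * m
            i0 = np.floor(p).astype(int) % m
            i1 = (i0 + 1) % m
            w = p - np.floor(p)
            return (1 - w) * grid[i0] + w * grid[i1]

        return f, float(grid.max() - grid.min())
    raise ValueError(f"unknown respiratory-effect shape {kind!r}")


def _trend_fn(spec, duration):
    """Zero-centered slow trend over the record: linear or sigmoid."""
    if spec is None:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    kind = spec[0]
    if kind == "linear":
        total = float(spec[1])

        def f(t):
            return total * (np.asarray(t, dtype=float) / duration - 0.5)

        return f
    if kind == "sigmoid":
        amp = float(spec[1])
        center = float(spec[2]) if len(spec) > 2 else 0.5
        width = float(spec[3]) if len(spec) > 3 else 0.08

        def f(t):
            z = (np.asarray(t, dtype=float) / duration - center) / width
            return amp * (1.0 / (1.0 + np.exp(-z)) - 0.5)

        return f
    raise ValueError(f"unknown trend spec {kind!r}")


def _resp_positions(t, insp_starts):
    """Fractional position of each time in its enclosing respiratory cycle."""
    idx = np.clip(np.searchsorted(insp_starts, t, side="right") - 1, 0,
                  len(insp_starts) - 2)
    s0 = insp_starts[idx]
    s1 = insp_starts[idx + 1]
    return (t - s0) / (s1 - s0)


# ---------------------------------------------------------------------------
# Pulse pressure series
# ---------------------------------------------------------------------------


@dataclass
class PPGeneratorConfig:
    """Conditions for the pulse-pressure beat series.

    Defaults describe a deeply sedated, pressure-control ventilated adult:
    mean PP 8 mmHg with a 0.6 mmHg sinusoidal respiratory modulation
    (true PPV = 2*0.6/8 = 15%), heart rate 75 bpm against 15 breaths/min,
    no slow trend, and 0.3 mmHg beat-to-beat noise.
    """

    n_beats: int = 300
    mean_pp: float = 8.0
    resp_rate: float = 15.0  # breaths/min
    heart_rate: float = 75.0  # bpm
    resp_effect: tuple = ("sinusoid", 0.6)
    trend: tuple | None = None
    noise_sd: float = 0.3
    diastolic: float = 60.0
    seed: int = 0


def gen_pp_series(config: PPGeneratorConfig):
    """Generate a beat table plus ground truth.

    Returns ``(beats, truth)`` where ``beats`` is a DataFrame with columns
    time_s, systolic_mmHg, diastolic_mmHg, pulse_pressure, resp_position,
    and ``truth`` records the true PPV (percent), mean PP, the modulation
    and trend callables and the inspiration-start times.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    beat_period = 60.0 / cfg.heart_rate
    t = np.arange(cfg.n_beats) * beat_period
    duration = t[-1] + beat_period
    resp_period = 60.0 / cfg.resp_rate
    insp = np.arange(0.0, duration + 2 * resp_period, resp_period)
    pos = _resp_positions(t, insp)
    effect, eff_range = _resp_shape(cfg.resp_effect)
    trend = _trend_fn(cfg.trend, duration)
    pp = (cfg.mean_pp + effect(pos) + trend(t)
          + rng.normal(0.0, cfg.noise_sd, cfg.n_beats))
    beats = pd.DataFrame(
        {
            "time_s": t,
            "systolic_mmHg": cfg.diastolic + pp,
            "diastolic_mmHg": np.full(cfg.n_beats, cfg.diastolic),
            "pulse_pressure": pp,
            "resp_position": pos,
        }
    )
    truth = {
        "ppv_true": 100.0 * eff_range / cfg.mean_pp,
        "alpha": cfg.mean_pp,
        "resp_effect": effect,
        "resp_effect_range": eff_range,
        "trend": trend,
        "insp_starts": insp,
        "resp_rate_hz": cfg.resp_rate / 60.0,
        "beat_period_s": beat_period,
    }
    return beats, truth


# ---------------------------------------------------------------------------
# CVP waveform
# ---------------------------------------------------------------------------

# (center, width, amplitude) as fractions of the cardiac cycle; amplitudes
# in mmHg: positive bumps for the a, c and v waves, dips for x' and y
_DEFAULT_TEMPLATE = (
    (0.08, 0.05, 2.0),   # a: atrial contraction
    (0.18, 0.05, 1.2),   # c: tricuspid closing
    (0.35, 0.08, -3.0),  # x': ventricular contraction
    (0.62, 0.09, 2.2),   # v: atrial filling
    (0.80, 0.06, -2.0),  # y: tricuspid opening
)


@dataclass
class CVPGeneratorConfig:
    """Conditions for the CVP waveform generator.

    Defaults: 30 s at 125 Hz, heart rate 80 bpm, 14 breaths/min, mean CVP
    8 mmHg, plateau-shaped respiratory modulation of 2 mmHg, no
    interaction, AR(1) residual noise with rho 0.6 and marginal SD
    0.3 mmHg.  ``interaction_gain`` scales the x'-descent depth by
    ``(1 + gain * cos(2 pi resp_position))``, the heart-lung interaction
    the tensor smooth is meant to recover.
    """

    duration_s: float = 30.0
    sample_rate: float = 125.0
    heart_rate: float = 80.0
    rsa_gain: float = 0.0  # respiratory sinus arrhythmia (period modulation)
    resp_rate: float = 14.0
    mean_cvp: float = 8.0
    cardiac_template: tuple = _DEFAULT_TEMPLATE
    resp_effect: tuple = ("plateau", 2.0)
    interaction_gain: float = 0.0
    trend: tuple | None = None
    ar1_rho: float = 0.6
    noise_sd: float = 0.3
    outliers: dict | None = None  # {rate_per_min, magnitude, duration_s, at}
    pr_interval: float = 0.15
    seed: int = 0


def _template_fns(template, cycle_s):
    """Cardiac template in seconds; returns (full, xprime-only) callables."""
    parts = [(c * cycle_s, w * cycle_s, a) for c, w, a in template]
    xp = min(parts, key=lambda p: p[2])  # the deepest dip is the x' descent

    def full(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c, w, a in parts:
            out += a * np.exp(-0.5 * ((x - c) / w) ** 2)
        return out

    def xprime(x):
        x = np.asarray(x, dtype=float)
        c, w, a = xp
        return a * np.exp(-0.5 * ((x - c) / w) ** 2)

    return full, xprime


def _ar1_noise(rng, n, rho, sd):
    """Stationary AR(1) with marginal standard deviation ``sd``."""
    e = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    e[0] = rng.normal(0.0, sd)
    eta = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + eta[i - 1]
    return e


def gen_cvp_wave(config: CVPGeneratorConfig):
    """Generate a CVP waveform, its annotations and ground truth.

    Returns ``(wave, annotations, truth)``:

    * ``wave`` — DataFrame with columns time_s, cvp_mmHg;
    * ``annotations`` — dict with ``qrs_times`` and ``insp_starts`` arrays
      (QRS = P-wave time + PR interval, mirroring how the positions are
      later reconstructed);
    * ``truth`` — the component callables (cardiac template, respiratory
      modulation, interaction field, trend), P-wave times, the AR(1)
      parameters and the per-sample noiseless signal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    resp_period = 60.0 / cfg.resp_rate
    insp = np.arange(0.0, cfg.duration_s + 2 * resp_period, resp_period)
    resp_pos = _resp_positions(t, insp)

    # P-wave onsets; cycle length optionally modulated by respiratory phase
    base_cycle = 60.0 / cfg.heart_rate
    p_times = [0.0]
    while p_times[-1] < cfg.duration_s + base_cycle:
        phase = _resp_positions(np.array([p_times[-1]]), insp)[0]
        cyc = base_cycle * (1.0 + cfg.rsa_gain * np.sin(2 * np.pi * phase))
        p_times.append(p_times[-1] + cyc)
    p_times = np.asarray(p_times)
    qrs_times = p_times + cfg.pr_interval

    idx = np.clip(np.searchsorted(p_times, t, side="right") - 1, 0,
                  len(p_times) - 1)
    card_pos = t - p_times[idx]

    template, xprime = _template_fns(cfg.cardiac_template, base_cycle)
    resp_fn, _rng_eff = _resp_shape(cfg.resp_effect)

    def interaction(x, pos):
        return cfg.interaction_gain * xprime(x) * np.cos(
            2.0 * np.pi * np.asarray(pos))

    trend = _trend_fn(cfg.trend, cfg.duration_s)
    signal = (cfg.mean_cvp + template(card_pos) + resp_fn(resp_pos)
              + interaction(card_pos, resp_pos) + trend(t))
    noise = _ar1_noise(rng, n, cfg.ar1_rho, cfg.noise_sd) if cfg.noise_sd > 0 \
        else np.zeros(n)

    artifact = np.zeros(n)
    if cfg.outliers:
        spec = dict(cfg.outliers)
        dur = float(spec.get("duration_s", 1.0))
        mag = float(spec.get("magnitude", 25.0))
        if "at" in spec and spec["at"] is not None:
            starts = np.atleast_1d(np.asarray(spec["at"], dtype=float))
        else:
            rate = float(spec.get("rate_per_min", 1.0))
            n_bursts = rng.poisson(rate * cfg.duration_s / 60.0)
            starts = rng.uniform(0.0, max(cfg.duration_s - dur, 0.0), n_bursts)
        for s in starts:
            sel = (t >= s) & (t < s + dur)
            # raised-cosine ramp over ~40 ms at each edge
            edge = np.clip((t[sel] - s) / 0.04, 0, 1) * np.clip(
                (s + dur - t[sel]) / 0.04, 0, 1)
            artifact[sel] += mag * np.minimum(edge, 1.0)

    cvp = signal + noise + artifact
    wave = pd.DataFrame({"time_s": t, "cvp_mmHg": cvp})
    annotations = {"qrs_times": qrs_times, "insp_starts": insp}
    truth = {
        "mean_cvp": cfg.mean_cvp,
        "cardiac_template": template,
        "xprime": xprime,
        "resp_effect": resp_fn,
        "interaction": interaction,
        "trend": trend,
        "p_times": p_times,
        "cycle_s": base_cycle,
        "signal": signal,
        "noise": noise,
        "artifact": artifact,
        "cardiac_position": card_pos,
        "resp_position": resp_pos,
        "ar1_rho": cfg.ar1_rho,
        "resp_rate_hz": cfg.resp_rate / 60.0,
    }
    return wave, annotations, truth


# ---------------------------------------------------------------------------
# Arterial pressure waveform (for beat detection)
# ---------------------------------------------------------------------------


def gen_abp_wave(config: PPGeneratorConfig, sample_rate: float = 125.0,
                 systole_s: float = 0.30, noise_sd: float = 0.0):
    """Arterial-pressure-like waveform whose beats carry the PP series.

    Each beat is a smooth sin^2 systolic bump of height equal to that
    beat's pulse pressure on a flat diastolic baseline, so a peak detector
    should recover the generator's beat count and pulse pressures.
    Returns ``(wave, truth)`` with truth as in :func:`gen_pp_series` plus
    the beat onset times.
    """
    beats, truth = gen_pp_series(config)
    rng = np.random.default_rng(config.seed + 1)
    period = 60.0 / config.heart_rate
    duration = config.n_beats * period
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.full(n, config.diastolic)
    onsets = beats["time_s"].to_numpy()
    pps = beats["pulse_pressure"].to_numpy()
    width = min(systole_s, 0.8 * period)
    for t0, pp in zip(onsets, pps):
        sel = (t >= t0) & (t < t0 + width)
        v[sel] += pp * np.sin(np.pi * (t[sel] - t0) / width) ** 2
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    wave = pd.DataFrame({"time_s": t, "abp_mmHg": v})
    truth = dict(truth)
    truth["beat_onsets"] = onsets
    truth["pulse_pressures"] = pps
    return wave, truth
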
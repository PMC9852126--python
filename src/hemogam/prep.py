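"""Turn raw pressure waveforms and event annotations into model-ready tables.

The model-layer containers are plain pandas DataFrames:

* beat series — columns ``time_s``, ``systolic_mmHg``, ``diastolic_mmHg``,
  ``pulse_pressure``, ``resp_position`` (beat timing at the diastole);
* CVP sample table — columns ``time_s``, ``cvp``, ``cardiac_position``
  (seconds since the latest P wave), ``resp_position`` (fraction of the
  enclosing respiratory cycle, in [0, 1)) and ``section``.

All timestamps are seconds from a common origin.  Cycle positions are
invariant to shifting every timestamp by a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import HemogamWarning, NoConfidentEstimateError

__all__ = [
    "WaveformSegment",
    "detect_beats",
    "resp_position",
    "cardiac_position",
    "estimate_resp_rate",
    "build_beat_series",
    "build_cvp_table",
    "read_waveform",
    "read_events",
    "read_beats",
    "write_waveform",
    "write_events",
    "write_beats",
]


@dataclass
class WaveformSegment:
    """A uniformly sampled pressure waveform."""

    time: np.ndarray  # seconds
    value: np.ndarray  # mmHg
    sample_rate: float  # Hz
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or
                        np.abs(dt - 1.0 / self.sample_rate).max() > 1e-6):
            raise ValueError(
                "waveform time axis must be uniform at the stated sample rate"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = ""):
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        v = frame.iloc[:, 1].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("waveform needs at least 2 samples")
        fs = 1.0 / np.median(np.diff(t))
        return cls(time=t, value=v, sample_rate=float(fs), label=label)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------


def detect_beats(wave: WaveformSegment, min_heart_rate: float = 30.0,
                 max_heart_rate: float = 180.0,
                 prominence: float | None = None) -> pd.DataFrame:
    """Detect (systolic, diastolic) pairs in an arterial-pressure waveform.

    Systolic peaks are located on a lightly smoothed copy of the signal
    (40 ms moving average, to keep sample noise from spawning spurious
    maxima), separated by at least the refractory period
    ``60/max_heart_rate`` seconds and exceeding a minimum prominence
    (default: 25% of the segment's interdecile range, a robust proxy for
    the pulse amplitude that is insensitive to how much of each cycle the
    waveform spends near the diastolic baseline).  Systolic and
    diastolic values are then read off the raw signal: the systole as the
    raw maximum near the smoothed peak, the diastole as the raw minimum
    between consecutive peaks.  The beat is timestamped at the diastole.
    Returns an empty table (with a warning) when nothing pulse-like is
    found.
    """
    v = wave.value
    if len(v) == 0 or np.ptp(v) == 0:
        warnings.warn("no beats found (flat or empty signal)",
                      HemogamWarning, stacklevel=2)
        return _empty_beats()
    if prominence is None:
        p90, p10 = np.percentile(v, [90, 10])
        prominence = 0.25 * (p90 - p10)
        if prominence <= 0:
            prominence = 0.25 * np.ptp(v)
    win = max(int(round(0.04 * wave.sample_rate)), 1)
    kernel = np.ones(win) / win
    vs = np.convolve(v, kernel, mode="same") if win > 1 else v
    distance = max(int(round(wave.sample_rate * 60.0 / max_heart_rate)), 1)
    peaks, _props = sps.find_peaks(vs, distance=distance, prominence=prominence)
    if len(peaks) == 0:
        warnings.warn("no beats found", HemogamWarning, stacklevel=2)
        return _empty_beats()
    rows = []
    prev = 0
    for pk in peaks:
        a, b = max(pk - win, 0), min(pk + win + 1, len(v))
        sys_idx = a + int(np.argmax(v[a:b]))
        seg = v[prev:pk]
        if len(seg) == 0:
            prev = pk
            continue
        dia_idx = prev + int(np.argmin(seg))
        sys_p, dia_p = v[sys_idx], v[dia_idx]
        if sys_p - dia_p > 0:
            rows.append((wave.time[dia_idx], sys_p, dia_p, sys_p - dia_p))
        prev = pk
    if not rows:
        warnings.warn("no beats found", HemogamWarning, stacklevel=2)
        return _empty_beats()
    return pd.DataFrame(
        rows, columns=["time_s", "systolic_mmHg", "diastolic_mmHg",
                       "pulse_pressure"]
    )


def _empty_beats():
    return pd.DataFrame(
        columns=["time_s", "systolic_mmHg", "diastolic_mmHg", "pulse_pressure"]
    )


# ---------------------------------------------------------------------------
# Cycle positions
# ---------------------------------------------------------------------------


def resp_position(times, insp_starts=None, period: float | None = None
                  ) -> np.ndarray:
    """Position of each time in its respiratory cycle, as a fraction [0, 1).

    With inspiration-start annotations: time since the latest inspiration
    start divided by that cycle's length.  Times before the first or at/after
    the last annotated inspiration are returned as NaN with a warning (first
    and last partial cycles are unidentifiable).  Without annotations but
    with a known respiratory ``period``, falls back to ``(t mod T)/T``
    (arbitrary phase).
    """
    t = np.asarray(times, dtype=float)
    if insp_starts is None:
        if period is None:
            raise ValueError("need insp_starts or a known period")
        return np.mod(t, period) / period
    s = np.asarray(insp_starts, dtype=float)
    if len(s) < 2 or not np.all(np.diff(s) > 0):
        raise ValueError("insp_starts must be strictly increasing, length >= 2")
    pos = np.full(len(t), np.nan)
    inside = (t >= s[0]) & (t < s[-1])
    idx = np.clip(np.searchsorted(s, t[inside], side="right") - 1, 0,
                  len(s) - 2)
    pos[inside] = (t[inside] - s[idx]) / (s[idx + 1] - s[idx])
    n_drop = int((~inside).sum())
    if n_drop:
        warnings.warn(
            f"{n_drop} timestamps outside the annotated inspiration window "
            "were dropped (NaN position)",
            HemogamWarning, stacklevel=2,
        )
    return pos


def cardiac_position(times, qrs_times, pr_interval: float = 0.15
                     ) -> np.ndarray:
    """Seconds since the latest P wave (QRS time minus a constant PR).

    The PR interval simply shifts the cycle origin so atrial contraction
    lands at the start of a cycle rather than the end of the previous one;
    its exact value is a user-supplied convention (default 0.15 s).
    Samples before the first P wave get NaN with a warning.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(qrs_times, dtype=float)
    if len(q) == 0:
        raise ValueError("qrs_times is empty")
    if pr_interval < 0:
        raise ValueError("pr_interval must be >= 0")
    p = np.sort(q) - pr_interval
    pos = np.full(len(t), np.nan)
    inside = t >= p[0]
    idx = np.clip(np.searchsorted(p, t[inside], side="right") - 1, 0,
                  len(p) - 1)
    pos[inside] = t[inside] - p[idx]
    n_drop = int((~inside).sum())
    if n_drop:
        warnings.warn(
            f"{n_drop} samples before the first P wave were dropped",
            HemogamWarning, stacklevel=2,
        )
    return pos


# ---------------------------------------------------------------------------
# Respiratory rate estimation
# ---------------------------------------------------------------------------


def estimate_resp_rate(times, values=None, band=(0.1, 0.67),
                       threshold: float = 8.0) -> float:
    """Respiratory rate (Hz) from the dominant spectral peak in ``band``.

    Accepts a :class:`WaveformSegment` (classical periodogram, uniform
    sampling) or irregular (times, values) pairs such as a beat-time /
    pulse-pressure series (least-squares Lomb-Scargle spectrum).  Raises
    :class:`NoConfidentEstimateError` when the in-band peak does not exceed
    the band's median power by ``threshold``.
    """
    if isinstance(times, WaveformSegment):
        wave = times
        f, pxx = sps.periodogram(wave.value - wave.value.mean(),
                                 fs=wave.sample_rate)
    else:
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        span = t[-1] - t[0]
        df = 1.0 / span
        f = np.arange(max(band[0], df), band[1] + df, df / 4.0)
        pxx = sps.lombscargle(t, v - v.mean(), 2.0 * np.pi * f,
                              normalize=True)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise NoConfidentEstimateError("no frequencies inside the band")
    fb, pb = f[sel], pxx[sel]
    med = np.median(pb)
    pk = int(np.argmax(pb))
    if med <= 0 or pb[pk] < threshold * med:
        raise NoConfidentEstimateError(
            "no spectral peak confidently above background in the "
            f"respiratory band {band}"
        )
    return float(fb[pk])


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def build_beat_series(beats: pd.DataFrame, insp_starts=None,
                      period: float | None = None) -> pd.DataFrame:
    """Attach respiratory positions to a beat table; drop unresolvable beats."""
    out = beats.copy()
    out["resp_position"] = resp_position(out["time_s"].to_numpy(),
                                         insp_starts, period=period)
    return out.dropna(subset=["resp_position"]).reset_index(drop=True)


def build_cvp_table(wave: WaveformSegment, qrs_times, insp_starts=None,
                    pr_interval: float = 0.15, section: str = "all",
                    resp_period: float | None = None) -> pd.DataFrame:
    """Per-sample CVP table with cardiac and respiratory cycle positions."""
    t = wave.time
    card = cardiac_position(t, qrs_times, pr_interval)
    resp = resp_position(t, insp_starts, period=resp_period)
    tab = pd.DataFrame(
        {"time_s": t, "cvp": wave.value, "cardiac_position": card,
         "resp_position": resp, "section": section}
    )
    return tab.dropna(subset=["cardiac_position", "resp_position"]
                      ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def read_waveform(path, label: str = "") -> WaveformSegment:
    """Two-column delimited text (time_s, value_mmHg) with a header row."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (time, value)")
    return WaveformSegment.from_frame(frame.iloc[:, :2], label=label)


def read_events(path) -> np.ndarray:
    """Single-column timestamps in seconds; header optional."""
    with open(path) as fh:
        first = fh.readline().strip().split(",")[0]
    try:
        float(first)
        header = None
    except ValueError:
        header = 0
    frame = pd.read_csv(path, header=header)
    return frame.iloc[:, 0].to_numpy(dtype=float)


def read_beats(path) -> pd.DataFrame:
    """Beat table: columns time_s, systolic_mmHg, diastolic_mmHg."""
    frame = pd.read_csv(path, sep=None, engine="python")
    need = {"time_s", "systolic_mmHg", "diastolic_mmHg"}
    if not need.issubset(frame.columns):
        raise ValueError(f"{path}: beat table needs columns {sorted(need)}")
    frame = frame.copy()
    frame["pulse_pressure"] = frame["systolic_mmHg"] - frame["diastolic_mmHg"]
    if (frame["pulse_pressure"] <= 0).any():
        bad = int((frame["pulse_pressure"] <= 0).sum())
        warnings.warn(f"dropped {bad} beats with non-positive pulse pressure",
                      HemogamWarning, stacklevel=2)
        frame = frame[frame["pulse_pressure"] > 0]
    return frame.reset_index(drop=True)


def write_waveform(path, wave_frame: pd.DataFrame):
    wave_frame.to_csv(path, index=False)


def write_events(path, times):
    pd.DataFrame({"time_s": np.asarray(times, dtype=float)}).to_csv(
        path, index=False)


def write_beats(path, beats: pd.DataFrame):
    cols = [c for c in ("time_s", "systolic_mmHg", "diastolic_mmHg")
            if c in beats.columns]
    beats[cols].to_csv(path, index=False)
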
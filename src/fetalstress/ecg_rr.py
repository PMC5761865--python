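"""ECG and RR-interval handling.

This module turns a raw single-channel ECG into a cleaned, evenly
resampled RR-interval series (tachogram), the substrate of all
heart-rate-variability computation downstream:

    ECGRecord --detect_r_peaks--> BeatAnnotations --rr_from_peaks-->
    RRSeries --clean_rr--> RRSeries --resample_rr--> Tachogram

Conventions: times are in seconds, intervals in milliseconds.  Each RR
interval is stamped at its *closing* beat (right edge), so windows taken
on this timeline are right-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ECGRecord",
    "BeatAnnotations",
    "RRSeries",
    "Tachogram",
    "FLAG_OK",
    "FLAG_INTERPOLATED",
    "FLAG_REJECTED",
    "detect_r_peaks",
    "rr_from_peaks",
    "clean_rr",
    "resample_rr",
    "rejected_spans",
]

# per-interval quality flags
FLAG_OK = "ok"
FLAG_INTERPOLATED = "interpolated"
FLAG_REJECTED = "rejected"


@dataclass
class ECGRecord:
    """A single-channel ECG: voltage samples at a fixed sampling rate."""

    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sample_rate


@dataclass
class BeatAnnotations:
    """Strictly increasing R-peak times, in seconds."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class RRSeries:
    """RR intervals (ms) stamped at the closing beat time (s).

    ``flags`` marks each interval as measured (``ok``), repaired by
    interpolation (``interpolated``) or inside an unusable span
    (``rejected``).
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.intervals), FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if len(self.beat_times) != len(self.intervals):
            raise ValueError("beat_times and intervals must have equal length")
        if len(self.flags) != len(self.intervals):
            raise ValueError("flags and intervals must have equal length")
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "rr_ms": self.intervals,
                "flag": self.flags.astype(str),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RRSeries":
        flags = (
            df["flag"].to_numpy(dtype=object)
            if "flag" in df.columns
            else None
        )
        return cls(
            beat_times=df["beat_time_s"].to_numpy(dtype=float),
            intervals=df["rr_ms"].to_numpy(dtype=float),
            flags=flags,
        )


@dataclass
class Tachogram:
    """Evenly resampled RR series: values in ms on a grid of spacing 1/rate."""

    rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + (len(self.values) - 1) / self.rate


def detect_r_peaks(
    ecg: ECGRecord, min_rate: float = 60.0, max_rate: float = 280.0
) -> BeatAnnotations:
    """Detect R peaks with a Pan-Tompkins-style scheme.

    Band-pass -> derivative -> squaring -> moving-window integration ->
    adaptive two-level thresholding with a refractory period derived from
    ``max_rate``.  Defaults bound plausible fetal heart rates
    (60-280 bpm).

    Raises ``ValueError("insufficient signal")`` for records shorter than
    2 s and ``ValueError("no QRS detected")`` for flat signals or when no
    candidate peak survives thresholding.
    """
    if not (0 < min_rate < max_rate):
        raise ValueError("require 0 < min_rate < max_rate")
    if ecg.duration < 2.0:
        raise ValueError("insufficient signal")
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise ValueError("no QRS detected")
    fs = ecg.sample_rate

    # band-pass around QRS energy; fetal QRS complexes are narrow, keep
    # the passband a little wider than the adult 5-15 Hz textbook choice
    nyq = fs / 2.0
    hi = min(25.0, 0.9 * nyq)
    sos = signal.butter(2, [5.0 / nyq, hi / nyq], btype="band", output="sos")
    bp = signal.sosfiltfilt(sos, x)

    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(1, int(round(0.10 * fs)))  # 100 ms integration window
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(fs * 60.0 / max_rate))
    cand, _ = signal.find_peaks(mwi, distance=max(1, refractory))
    if len(cand) == 0:
        raise ValueError("no QRS detected")

    # adaptive signal/noise level tracking (Pan-Tompkins thresholds)
    init = mwi[: int(min(len(mwi), 2 * fs))]
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    kept = []
    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[i] > thr:
            spki = 0.125 * mwi[i] + 0.875 * spki
            kept.append(i)
        else:
            npki = 0.125 * mwi[i] + 0.875 * npki
    if not kept:
        raise ValueError("no QRS detected")

    # refine: locate the R wave as the extremum of the band-passed signal
    # within +/-100 ms of each integrated-energy peak
    half = int(round(0.10 * fs))
    peaks = []
    for i in kept:
        lo_i = max(0, i - half)
        hi_i = min(len(bp), i + half + 1)
        peaks.append(lo_i + int(np.argmax(np.abs(bp[lo_i:hi_i]))))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    dedup = [peaks[0]]
    for p in peaks[1:]:
        if p - dedup[-1] >= refractory:
            dedup.append(p)
        elif np.abs(bp[p]) > np.abs(bp[dedup[-1]]):
            dedup[-1] = p
    times = ecg.start_time + np.asarray(dedup) / fs
    return BeatAnnotations(peak_times=times)


def rr_from_peaks(beats: BeatAnnotations) -> RRSeries:
    """Build the RR series from R-peak times.

    Interval i spans peaks i..i+1 and is stamped at the closing peak.
    """
    t = beats.peak_times
    if len(t) < 2:
        raise ValueError("need at least 2 peaks to form an RR series")
    intervals = np.diff(t) * 1000.0
    return RRSeries(beat_times=t[1:], intervals=intervals)


def clean_rr(
    rr: RRSeries,
    rel_threshold: float = 0.30,
    median_window: int = 11,
    reject_span_s: float = 64.0,
    reject_fraction: float = 0.20,
) -> RRSeries:
    """Repair artifact intervals and mark unusable spans.

    Any ``ok`` interval deviating from the running median (``median_window``
    beats, centered) by more than ``rel_threshold`` is replaced by linear
    interpolation of its good neighbours and flagged ``interpolated``.
    Incoming ``interpolated``/``rejected`` flags are preserved, which makes
    the operation idempotent.  Any ``reject_span_s`` span in which more than
    ``reject_fraction`` of intervals carry a non-``ok`` flag is marked
    ``rejected``; windows overlapping such spans are invalid downstream.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    if not (0 < rel_threshold < 1):
        raise ValueError("rel_threshold must be in (0, 1)")
    values = rr.intervals.copy()
    flags = rr.flags.copy()

    considered = flags == FLAG_OK
    med = (
        pd.Series(values)
        .rolling(median_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    bad = considered & (np.abs(values - med) > rel_threshold * med)
    good = ~bad & (flags != FLAG_REJECTED)
    if bad.any():
        if good.sum() >= 2:
            values[bad] = np.interp(
                rr.beat_times[bad], rr.beat_times[good], values[good]
            )
        else:  # almost everything is bad; fall back to the running median
            values[bad] = med[bad]
        flags = flags.copy()
        flags[bad] = FLAG_INTERPOLATED

    # sliding-span rejection: any 64 s span with >20 % non-ok intervals
    flagged = flags != FLAG_OK
    n = len(values)
    reject = np.zeros(n, dtype=bool)
    j = 0
    for i in range(n):
        while rr.beat_times[i] - rr.beat_times[j] > reject_span_s:
            j += 1
        count = i - j + 1
        if count >= 3 and flagged[j : i + 1].sum() > reject_fraction * count:
            reject[j : i + 1] = True
    flags[reject] = FLAG_REJECTED

    return RRSeries(beat_times=rr.beat_times.copy(), intervals=values, flags=flags)


def rejected_spans(rr: RRSeries) -> list[tuple[float, float]]:
    """Contiguous (t_start, t_end] spans of rejected intervals, in seconds."""
    spans: list[tuple[float, float]] = []
    rej = rr.flags == FLAG_REJECTED
    i = 0
    n = len(rr)
    while i < n:
        if rej[i]:
            j = i
            while j + 1 < n and rej[j + 1]:
                j += 1
            start = rr.beat_times[i] - rr.intervals[i] / 1000.0
            spans.append((start, rr.beat_times[j]))
            i = j + 1
        else:
            i += 1
    return spans


def resample_rr(rr: RRSeries, rate: float = 8.0) -> Tachogram:
    """Linearly interpolate the RR series onto an even grid.

    Uses ``ok`` and ``interpolated`` intervals; the grid spans
    [first, last] beat time with spacing ``1/rate`` and no extrapolation
    beyond either end.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    usable = rr.flags != FLAG_REJECTED
    t = rr.beat_times[usable]
    v = rr.intervals[usable]
    if len(t) < 2:
        raise ValueError("need at least 2 usable intervals to resample")
    span = t[-1] - t[0]
    if span < 1.0 / rate:
        raise ValueError("RR span shorter than one resampling step")
    n = int(np.floor(span * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    values = np.interp(grid, t, v)
    return Tachogram(rate=rate, values=values, start_time=t[0])
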
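"""Fetal Stress Index (FSI) computation.

The FSI quantifies the magnitude of high-frequency (> 0.15 Hz,
parasympathetically mediated) oscillations of the fetal RR series.  For
each 64 s window of the evenly resampled tachogram:

1. normalize: ``(x - mean) / mean`` (dimensionless fractional fluctuation);
2. high-pass above 0.15 Hz with a discrete-wavelet (db4) filter —
   reconstruct the detail bands and discard the approximation;
3. draw upper/lower envelopes through strict local maxima/minima;
4. split the inter-envelope area into four equal 16 s subareas A1..A4 and
   take ``AUCmin = min(A1..A4)``;
5. map affinely: ``FSI_inst = 100 * (a * AUCmin + b) / 12.8``, clamped to
   [0, 100].

The reported FSI at time t is the mean of valid FSI_inst over the trailing
3 minutes.  Windows advance by 1 s; the first 64 + 180 s are warm-up.

Constants ``a`` and ``b`` tune the coherence between the visual aspect of
the RR trace and the numeric scale; they are configuration, not re-derived
here (defaults are the published values of the adult index in the same
algorithm family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .ecg_rr import RRSeries, Tachogram, clean_rr, rejected_spans, resample_rr

__all__ = [
    "FSIConfig",
    "FilteredWindow",
    "EnvelopePair",
    "SubareaSet",
    "FSISeries",
    "WindowSummary",
    "InvalidWindow",
    "normalize_window",
    "highpass_hf",
    "envelopes",
    "subarea_areas",
    "fsi_inst",
    "fsi_series",
    "summarize_window",
    "fsi_from_rr",
]


class InvalidWindow(Exception):
    """A window cannot yield a meaningful index value."""


@dataclass(frozen=True)
class FSIConfig:
    """Every tunable of the FSI chain.

    window_s : moving-window length (s)
    cutoff_hz : high-pass cutoff between LF and HF bands (Hz)
    n_subareas : number of equal time segments of the envelope area
    a, b : affine scaling constants of the index
    denom : affine scaling denominator
    step_s : hop between successive windows (s)
    avg_s : trailing-average length for the reported FSI (s)
    resample_hz : tachogram resampling rate (Hz)
    clamp : output bounds of the index
    wavelet : mother wavelet of the numerical filter
    flat_tol : peak-to-peak level (n.u.) below which a filtered window is
        treated as zero oscillation (AUCmin = 0) rather than degenerate
    """

    window_s: float = 64.0
    cutoff_hz: float = 0.15
    n_subareas: int = 4
    a: float = 5.1
    b: float = 1.2
    denom: float = 12.8
    step_s: float = 1.0
    avg_s: float = 180.0
    resample_hz: float = 8.0
    clamp: tuple[float, float] = (0.0, 100.0)
    wavelet: str = "db4"
    flat_tol: float = 1e-7
    min_valid_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.n_subareas < 1:
            raise ValueError("n_subareas must be >= 1")
        if self.cutoff_hz >= self.resample_hz / 2:
            raise ValueError("cutoff_hz must be below the Nyquist rate")
        if self.avg_s < self.step_s:
            raise ValueError("avg_s must be >= step_s")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.resample_hz))

    @property
    def dwt_level(self) -> int:
        # deepest level whose approximation band [0, fs/2^(L+1)] lies
        # entirely below the cutoff
        return int(np.floor(np.log2(self.resample_hz / self.cutoff_hz))) - 1


@dataclass
class FilteredWindow:
    """High-pass-filtered, normalized RR fluctuations of one window."""

    t0: float
    values: np.ndarray
    rate: float

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate


@dataclass
class EnvelopePair:
    """Piecewise-linear envelopes through local maxima and minima.

    Outside the first/last extremum the envelopes extend flat.  Where
    sparse extrema would let the interpolants cross, the lower envelope is
    capped at the upper one so that upper >= lower holds everywhere.
    """

    max_times: np.ndarray
    max_values: np.ndarray
    min_times: np.ndarray
    min_values: np.ndarray

    def upper(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.max_times, self.max_values)

    def lower(self, t: np.ndarray) -> np.ndarray:
        lo = np.interp(t, self.min_times, self.min_values)
        return np.minimum(lo, self.upper(t))


@dataclass
class SubareaSet:
    areas: np.ndarray  # A1..A4 in n.u.*s

    @property
    def auc_min(self) -> float:
        return float(np.min(self.areas))


@dataclass
class FSISeries:
    """Instantaneous and trailing-averaged index values.

    ``times``/``fsi_inst``/``auc_min``/``valid`` are aligned per window
    (stamped at the window end).  ``avg_times``/``avg_values`` hold the
    reported FSI, defined from ``warmup_end`` onward; NaN marks times
    where fewer than the required fraction of instantaneous samples were
    valid.
    """

    times: np.ndarray
    fsi_inst: np.ndarray
    auc_min: np.ndarray
    valid: np.ndarray
    avg_times: np.ndarray
    avg_values: np.ndarray
    warmup_end: float
    config: FSIConfig = field(default_factory=FSIConfig)

    @property
    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        ok = ~np.isnan(self.avg_values)
        return self.avg_times[ok], self.avg_values[ok]


@dataclass
class WindowSummary:
    """min/max/mean of the reported FSI over (t_start, t_end]."""

    t_start: float
    t_end: float
    fsi_min: float
    fsi_max: float
    fsi_mean: float
    n: int


def normalize_window(tach: Tachogram, t0: float, cfg: FSIConfig) -> np.ndarray:
    """Extract [t0, t0 + window_s) and normalize to zero-mean fractional units."""
    i0 = int(round((t0 - tach.start_time) * tach.rate))
    n = cfg.window_samples
    if i0 < 0 or i0 + n > len(tach.values):
        raise InvalidWindow("window not fully covered by tachogram")
    w = tach.values[i0 : i0 + n]
    m = w.mean()
    out = w / m - 1.0
    return out - out.mean()  # remove the tiny float residual: mean exactly 0


def _dwt_highpass(values: np.ndarray, cfg: FSIConfig) -> np.ndarray:
    """Subtract the below-cutoff wavelet approximation along the last axis."""
    n = values.shape[-1]
    level = cfg.dwt_level
    if n < 2**level:
        raise InvalidWindow("window shorter than filter support")
    x = values - values.mean(axis=-1, keepdims=True)
    coeffs = pywt.wavedec(x, cfg.wavelet, mode="symmetric", level=level, axis=-1)
    for i in range(1, len(coeffs)):
        coeffs[i] = np.zeros_like(coeffs[i])
    low = pywt.waverec(coeffs, cfg.wavelet, mode="symmetric", axis=-1)
    out = x - low[..., :n]
    # residual DC sits below the cutoff by definition: remove it too
    return out - out.mean(axis=-1, keepdims=True)


def highpass_hf(
    window: np.ndarray, cfg: FSIConfig, t0: float = 0.0
) -> FilteredWindow:
    """High-pass the normalized window above ``cfg.cutoff_hz``."""
    values = _dwt_highpass(np.asarray(window, dtype=float), cfg)
    return FilteredWindow(t0=t0, values=values, rate=cfg.resample_hz)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    interior = np.arange(1, len(x) - 1)
    maxima = interior[(x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])]
    minima = interior[(x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])]
    return maxima, minima


def envelopes(fw: FilteredWindow) -> EnvelopePair:
    """Upper/lower envelopes through strict local maxima/minima."""
    x = fw.values
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise InvalidWindow("fewer than 2 local maxima or minima")
    t = fw.times
    return EnvelopePair(
        max_times=t[maxima],
        max_values=x[maxima],
        min_times=t[minima],
        min_values=x[minima],
    )


def subarea_areas(
    env: EnvelopePair, cfg: FSIConfig, t0: float = 0.0
) -> SubareaSet:
    """Trapezoidal areas of upper-lower over n_subareas equal time segments."""
    seg = cfg.window_s / cfg.n_subareas
    per_seg = max(2, int(round(seg * cfg.resample_hz)))
    areas = np.empty(cfg.n_subareas)
    for k in range(cfg.n_subareas):
        tt = np.linspace(t0 + k * seg, t0 + (k + 1) * seg, per_seg + 1)
        gap = env.upper(tt) - env.lower(tt)
        areas[k] = np.trapezoid(gap, tt)
    return SubareaSet(areas=areas)


def fsi_inst(auc_min: float, cfg: FSIConfig) -> float:
    """Affine map of AUCmin to the index scale, clamped."""
    if auc_min < 0:
        raise ValueError("auc_min must be non-negative")
    raw = 100.0 * (cfg.a * auc_min + cfg.b) / cfg.denom
    return float(np.clip(raw, *cfg.clamp))


class _AreaGrid:
    """Precomputed evaluation grid and trapezoid weights for one config.

    Evaluates both envelopes on a fixed grid of ``per_seg`` points per
    subarea segment (matching :func:`subarea_areas`) and integrates each
    segment with shared endpoints.
    """

    def __init__(self, cfg: FSIConfig):
        seg = cfg.window_s / cfg.n_subareas
        self.per_seg = max(2, int(round(seg * cfg.resample_hz)))
        n_pts = cfg.n_subareas * self.per_seg + 1
        self.t = np.linspace(0.0, cfg.window_s, n_pts)
        w = np.ones(self.per_seg + 1)
        w[0] = w[-1] = 0.5
        self.weights = w * (seg / self.per_seg)
        self.n_subareas = cfg.n_subareas

    def auc_min(self, row: np.ndarray, sample_times: np.ndarray) -> float:
        maxima, minima = _local_extrema(row)
        if len(maxima) < 2 or len(minima) < 2:
            return float("nan")
        upper = np.interp(self.t, sample_times[maxima], row[maxima])
        lower = np.interp(self.t, sample_times[minima], row[minima])
        gap = upper - np.minimum(lower, upper)
        best = np.inf
        for k in range(self.n_subareas):
            seg = gap[k * self.per_seg : (k + 1) * self.per_seg + 1]
            best = min(best, float(seg @ self.weights))
        return best


def _window_auc_min(
    filtered_row: np.ndarray, cfg: FSIConfig, grid: "_AreaGrid | None" = None
) -> float:
    """AUCmin of one filtered window; NaN when the window is degenerate.

    An (almost) flat filtered window — peak-to-peak below ``flat_tol`` —
    means zero measurable oscillation and maps to AUCmin = 0 so a
    perfectly steady heart rate yields the index floor 100*b/denom.  A
    non-flat window lacking two maxima and two minima is degenerate and
    is marked invalid rather than scored as spuriously low.
    """
    if np.ptp(filtered_row) < cfg.flat_tol:
        return 0.0
    if grid is not None:
        times = np.arange(len(filtered_row)) / cfg.resample_hz
        return grid.auc_min(filtered_row, times)
    try:
        env = envelopes(
            FilteredWindow(t0=0.0, values=filtered_row, rate=cfg.resample_hz)
        )
        return subarea_areas(env, cfg, t0=0.0).auc_min
    except InvalidWindow:
        return float("nan")


def fsi_series(
    tach: Tachogram,
    cfg: FSIConfig | None = None,
    invalid_spans: list[tuple[float, float]] | None = None,
) -> FSISeries:
    """Run the full FSI chain over a tachogram.

    Windows of ``window_s`` advance by ``step_s``; each instantaneous
    value is stamped at its window end.  The averaged (reported) FSI at
    time t is the mean of valid instantaneous values in (t - avg_s, t],
    emitted only when at least ``min_valid_fraction`` of the expected
    samples in that span are valid and t is past warm-up.

    ``invalid_spans`` are (t_start, t_end] intervals — typically rejected
    RR spans — that invalidate every overlapping window.
    """
    cfg = cfg or FSIConfig()
    wn = cfg.window_samples
    step_n = int(round(cfg.step_s * cfg.resample_hz))
    if step_n < 1:
        raise ValueError("step_s too small for the resampling rate")
    if len(tach.values) < wn:
        raise ValueError("signal too short")

    # all windows as a strided (n_win, wn) view
    sw = np.lib.stride_tricks.sliding_window_view(tach.values, wn)[::step_n]
    n_win = sw.shape[0]
    t0s = tach.start_time + np.arange(n_win) * (step_n / tach.rate)
    t_ends = t0s + cfg.window_s

    means = sw.mean(axis=1)
    norm = sw / means[:, None] - 1.0
    norm = norm - norm.mean(axis=1, keepdims=True)
    filtered = _dwt_highpass(norm, cfg)

    grid = _AreaGrid(cfg)
    sample_times = np.arange(wn) / cfg.resample_hz
    auc = np.empty(n_win)
    for i in range(n_win):
        row = filtered[i]
        if np.ptp(row) < cfg.flat_tol:
            auc[i] = 0.0
        else:
            auc[i] = grid.auc_min(row, sample_times)

    valid = ~np.isnan(auc)
    if invalid_spans:
        for lo, hi in invalid_spans:
            valid &= ~((t0s < hi) & (t_ends > lo))

    fsi = np.full(n_win, np.nan)
    ok = valid & ~np.isnan(auc)
    raw = 100.0 * (cfg.a * auc[ok] + cfg.b) / cfg.denom
    fsi[ok] = np.clip(raw, *cfg.clamp)

    # trailing average over (t - avg_s, t] on the regular inst grid
    k = int(round(cfg.avg_s / cfg.step_s))
    vals = np.where(ok, fsi, 0.0)
    cnt = ok.astype(float)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0.0], np.cumsum(cnt)))
    idx = np.arange(n_win)
    lo_idx = np.maximum(idx - k + 1, 0)
    window_sum = csum[idx + 1] - csum[lo_idx]
    window_cnt = ccnt[idx + 1] - ccnt[lo_idx]
    expected = idx + 1 - lo_idx
    avg = np.full(n_win, np.nan)
    enough = window_cnt >= cfg.min_valid_fraction * expected
    nonzero = window_cnt > 0
    use = enough & nonzero
    avg[use] = window_sum[use] / window_cnt[use]

    warmup_end = t_ends[0] + cfg.avg_s
    avg[t_ends < warmup_end - 1e-9] = np.nan

    return FSISeries(
        times=t_ends,
        fsi_inst=fsi,
        auc_min=auc,
        valid=valid,
        avg_times=t_ends,
        avg_values=avg,
        warmup_end=warmup_end,
        config=cfg,
    )


def summarize_window(
    series: FSISeries, t_start: float, t_end: float
) -> WindowSummary:
    """min/max/mean of the reported FSI over the interval (t_start, t_end]."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    t, v = series.averaged
    sel = (t > t_start) & (t <= t_end + 1e-9)
    if not np.any(sel):
        raise ValueError("empty summary window")
    vv = v[sel]
    return WindowSummary(
        t_start=t_start,
        t_end=t_end,
        fsi_min=float(np.min(vv)),
        fsi_max=float(np.max(vv)),
        fsi_mean=float(np.mean(vv)),
        n=int(sel.sum()),
    )


def fsi_from_rr(
    rr: RRSeries, cfg: FSIConfig | None = None, clean: bool = True
) -> FSISeries:
    """Convenience pipeline: clean -> resample -> FSI series."""
    cfg = cfg or FSIConfig()
    if clean:
        rr = clean_rr(rr)
    tach = resample_rr(rr, rate=cfg.resample_hz)
    return fsi_series(tach, cfg, invalid_spans=rejected_spans(rr))
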
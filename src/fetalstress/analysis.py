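"""Statistical pipeline: pre-sampling FSI summaries, pH grouping,
nonparametric tests and rank correlations.

For each blood-gas sampling event the reported FSI over the 10 minutes
before the sample is summarized as FSI_min / FSI_max / FSI_mean.  Events
are grouped by the clinical acidosis threshold pH <= 7.20 and compared
with the Wilcoxon rank-sum (Mann-Whitney) test; time evolution across
sampling points uses the Friedman test; associations between FSI
summaries and the gas panel use Spearman rank correlations.  Exact null
distributions are used at the small sample sizes typical of instrumented
cohorts (combined n <= 25 for the rank-sum test, n <= 9 for Spearman),
asymptotic approximations with tie correction beyond.  No
multiple-testing correction is applied; this is noted in the output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fsi_core import FSIConfig, FSISeries, WindowSummary, fsi_from_rr, summarize_window
from .synth import ExperimentRecord, SampleEvent

__all__ = [
    "EventSummary",
    "TestResult",
    "CorrelationResult",
    "StudyResult",
    "GROUP_ABOVE",
    "GROUP_AT_OR_BELOW",
    "PH_THRESHOLD",
    "pre_sample_summaries",
    "occlusion_summaries",
    "compare_groups",
    "wilcoxon_rank_sum",
    "friedman_over_time",
    "spearman",
    "correlate",
    "run_study",
]

PH_THRESHOLD = 7.20
GROUP_ABOVE = "above"
GROUP_AT_OR_BELOW = "at_or_below"

EXACT_RANKSUM_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 9


@dataclass
class EventSummary:
    """One event paired with its pre-sampling FSI window summary."""

    event: SampleEvent
    window: WindowSummary
    group: str

    def value(self, variable: str) -> float:
        if variable in ("fsi_min", "fsi_max", "fsi_mean"):
            return getattr(self.window, variable)
        return getattr(self.event, variable)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    detail: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class CorrelationResult:
    variable: str
    rho: float
    p_value: float
    n: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0 or np.isnan(self.rho)):
            raise ValueError("|rho| must be <= 1")


def pre_sample_summaries(
    series: FSISeries,
    events: list[SampleEvent],
    window_s: float = 600.0,
) -> tuple[list[EventSummary], list[SampleEvent]]:
    """Summarize the reported FSI over (t - window_s, t] for each event.

    Events whose pre-sampling window is not fully past warm-up (or holds
    no averaged sample) are skipped and returned separately.  Grouping by
    the pH 7.20 threshold is applied: ph <= 7.20 -> ``at_or_below``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    summaries: list[EventSummary] = []
    skipped: list[SampleEvent] = []
    for evt in events:
        start = evt.time - window_s
        if start < series.warmup_end - 1e-9:
            skipped.append(evt)
            continue
        try:
            w = summarize_window(series, start, evt.time)
        except ValueError:
            skipped.append(evt)
            continue
        group = GROUP_AT_OR_BELOW if evt.ph <= PH_THRESHOLD else GROUP_ABOVE
        summaries.append(EventSummary(event=evt, window=w, group=group))
    if not summaries:
        raise ValueError("no event window is covered by the FSI series")
    return summaries, skipped


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample is small and
    tie-free; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of any difference
        return TestResult(
            statistic=float(len(x) * len(y) / 2.0),
            p_value=1.0,
            n=len(pooled),
            method="mann-whitney (degenerate)",
        )
    exact = (len(pooled) <= EXACT_RANKSUM_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n=len(pooled),
        method="mann-whitney exact" if exact else "mann-whitney asymptotic",
    )


def compare_groups(
    summaries: list[EventSummary],
    variable: str = "fsi_min",
    mode: str = "rank_sum",
) -> TestResult:
    """Compare a variable between the pH > 7.20 and pH <= 7.20 groups.

    ``mode='rank_sum'`` (default) treats events as independent
    observations; ``mode='signed_rank'`` pairs each subject's group means
    (sensitivity analysis for within-subject dependence).
    """
    above = [s.value(variable) for s in summaries if s.group == GROUP_ABOVE]
    below = [s.value(variable) for s in summaries if s.group == GROUP_AT_OR_BELOW]
    if not above or not below:
        raise ValueError("both pH groups must be non-empty")
    if mode == "signed_rank":
        df = pd.DataFrame(
            {
                "subject": [s.event.subject_id for s in summaries],
                "group": [s.group for s in summaries],
                "value": [s.value(variable) for s in summaries],
            }
        )
        wide = df.pivot_table(index="subject", columns="group", values="value")
        wide = wide.dropna()
        if len(wide) < 2:
            raise ValueError("too few paired subjects for signed-rank mode")
        diff = wide[GROUP_AT_OR_BELOW] - wide[GROUP_ABOVE]
        if np.allclose(diff, 0):
            result = TestResult(0.0, 1.0, len(wide), "wilcoxon signed-rank")
        else:
            res = stats.wilcoxon(diff, alternative="two-sided")
            result = TestResult(
                float(res.statistic),
                float(res.pvalue),
                len(wide),
                "wilcoxon signed-rank",
            )
    else:
        result = wilcoxon_rank_sum(np.asarray(above), np.asarray(below))
    result.detail = {
        "variable": variable,
        "above_median": float(np.median(above)),
        "above_iqr": tuple(np.percentile(above, [25, 75])),
        "below_median": float(np.median(below)),
        "below_iqr": tuple(np.percentile(below, [25, 75])),
        "n_above": len(above),
        "n_below": len(below),
    }
    return result


def friedman_over_time(values: np.ndarray) -> TestResult:
    """Friedman test on a complete subjects x timepoints matrix.

    Chi-square statistic with average-rank tie handling; an all-tie
    matrix has statistic 0 and p = 1 by convention.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects x timepoints matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete (no missing cells)")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    # tie correction: per row, sum of (t^3 - t) over tie groups
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        return TestResult(0.0, 1.0, n, "friedman (all ties)")
    stat /= correction
    p = float(stats.chi2.sf(stat, k - 1))
    return TestResult(float(stat), p, n, "friedman")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (scipy engine)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def statistic(permuted_rx, axis=-1):
        rxc = permuted_rx - np.mean(permuted_rx, axis=axis, keepdims=True)
        ryc = ry - ry.mean()
        num = np.sum(rxc * ryc, axis=axis)
        den = np.sqrt(np.sum(rxc**2, axis=axis) * np.sum(ryc**2))
        return num / den

    res = stats.permutation_test(
        (rx,),
        statistic,
        permutation_type="pairings",
        n_resamples=np.inf,
        alternative="two-sided",
        vectorized=True,
    )
    return float(min(1.0, res.pvalue))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Spearman rho with exact permutation p for n <= 9, t-approx beyond."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    rho, p_asym = stats.spearmanr(x, y)
    if len(x) <= EXACT_SPEARMAN_MAX_N:
        return float(rho), _exact_spearman_p(x, y, float(rho)), "exact"
    return float(rho), float(p_asym), "t-approx"


def correlate(
    summaries: list[EventSummary], x: str, y: str
) -> CorrelationResult:
    """Spearman correlation between two event/summary variables."""
    xv = np.array([s.value(x) for s in summaries])
    yv = np.array([s.value(y) for s in summaries])
    rho, p, method = spearman(xv, yv)
    return CorrelationResult(
        variable=f"{y}~{x}", rho=rho, p_value=p, n=len(xv),
        method=f"spearman ({method})",
    )


def occlusion_summaries(
    records: list[ExperimentRecord],
    cfg: FSIConfig | None = None,
    window_s: float = 600.0,
    clean: bool = True,
) -> list[EventSummary]:
    """Pre-sampling summaries for occlusion-period events only.

    The RR series is trimmed to the stretch actually needed (pre-sampling
    window plus averaging and filter warm-up before the first occlusion
    event), which makes repeated Monte-Carlo evaluation cheap.
    """
    cfg = cfg or FSIConfig()
    out: list[EventSummary] = []
    for rec in records:
        occl_events = [e for e in rec.events if e.time > rec.occlusion_start]
        if not occl_events:
            continue
        t_first = min(e.time for e in occl_events)
        t_keep = t_first - window_s - cfg.avg_s - cfg.window_s - 10.0
        keep = rec.rr.beat_times >= t_keep
        rr = rec.rr
        if keep.sum() < len(rr):
            from .ecg_rr import RRSeries

            rr = RRSeries(
                beat_times=rr.beat_times[keep],
                intervals=rr.intervals[keep],
                flags=rr.flags[keep],
            )
        series = fsi_from_rr(rr, cfg, clean=clean)
        summaries, _ = pre_sample_summaries(series, occl_events, window_s)
        out.extend(summaries)
    if not out:
        raise ValueError("no occlusion event is covered by any FSI series")
    return out


@dataclass
class StudyResult:
    """The three result tables plus run metadata."""

    time_evolution: pd.DataFrame  # medians(IQR) per sampling point + Friedman p
    group_comparison: pd.DataFrame  # pH-group medians(IQR) + Wilcoxon p
    correlations: pd.DataFrame  # Spearman rho of FSI_min vs panel variables
    summaries: list[EventSummary]
    metadata: dict


_PANEL_VARS = ("hr", "map", "ph", "po2", "pco2", "lactate", "base_deficit")
_FSI_VARS = ("fsi_min", "fsi_max", "fsi_mean")


def _fmt_med_iqr(values: np.ndarray) -> str:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{med:.2f}({q1:.2f}-{q3:.2f})"


def run_study(
    records: list[ExperimentRecord],
    cfg: FSIConfig | None = None,
    window_s: float = 600.0,
    clean: bool = True,
) -> StudyResult:
    """Run the full analysis pipeline over a cohort.

    Per subject: compute the FSI series from the RR series, summarize the
    10 minutes before each blood-gas event, then build (a) a
    time-evolution table of medians(IQR) per sampling point with Friedman
    p-values over subjects with complete panels, (b) a pH-group
    comparison of every panel and FSI variable with rank-sum p-values
    (occlusion events only — the pre-occlusion sample is excluded), and
    (c) Spearman correlations of FSI_min against the panel during
    occlusion.  Deterministic given its inputs.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 subjects")
    cfg = cfg or FSIConfig()

    all_summaries: list[EventSummary] = []
    skipped_total = 0
    for rec in records:
        series = fsi_from_rr(rec.rr, cfg, clean=clean)
        summaries, skipped = pre_sample_summaries(series, rec.events, window_s)
        skipped_total += len(skipped)
        all_summaries.extend(summaries)

    # event index k relative to occlusion onset (k = 0: pre-occlusion)
    def event_index(s: EventSummary) -> int:
        rec = next(r for r in records if r.subject_id == s.event.subject_id)
        return int(round((s.event.time - rec.occlusion_start) / 900.0))

    by_k: dict[int, list[EventSummary]] = {}
    for s in all_summaries:
        by_k.setdefault(event_index(s), []).append(s)
    ks = sorted(by_k)

    # --- time evolution table -------------------------------------------
    rows = []
    for var in _PANEL_VARS + _FSI_VARS:
        row: dict[str, object] = {"variable": var}
        for k in ks:
            vals = np.array([s.value(var) for s in by_k[k]])
            label = "baseline" if k == 0 else f"T{int(k * 15)}mn"
            row[label] = _fmt_med_iqr(vals)
        # Friedman over subjects with all time points
        subj_vals: dict[str, dict[int, float]] = {}
        for s in all_summaries:
            subj_vals.setdefault(s.event.subject_id, {})[event_index(s)] = s.value(var)
        complete = [
            [d[k] for k in ks] for d in subj_vals.values() if set(ks) <= set(d)
        ]
        if len(complete) >= 2 and len(ks) >= 2:
            fr = friedman_over_time(np.asarray(complete))
            row["friedman_p"] = fr.p_value
            row["n_complete"] = len(complete)
        else:
            row["friedman_p"] = np.nan
            row["n_complete"] = len(complete)
        rows.append(row)
    time_evolution = pd.DataFrame(rows)

    # --- pH-group comparison (occlusion events only) --------------------
    occl = [s for s in all_summaries if event_index(s) >= 1]
    rows = []
    for var in _PANEL_VARS + _FSI_VARS:
        row = {"variable": var}
        try:
            res = compare_groups(occl, variable=var)
            d = res.detail or {}
            row["above_7_20"] = (
                f"{d['above_median']:.2f}"
                f"({d['above_iqr'][0]:.2f}-{d['above_iqr'][1]:.2f})"
            )
            row["at_or_below_7_20"] = (
                f"{d['below_median']:.2f}"
                f"({d['below_iqr'][0]:.2f}-{d['below_iqr'][1]:.2f})"
            )
            row["wilcoxon_p"] = res.p_value
            row["n_above"] = d["n_above"]
            row["n_below"] = d["n_below"]
        except ValueError:
            row["above_7_20"] = row["at_or_below_7_20"] = ""
            row["wilcoxon_p"] = np.nan
        rows.append(row)
    group_comparison = pd.DataFrame(rows)

    # --- correlations of FSI_min vs panel (occlusion events) ------------
    rows = []
    for var in _PANEL_VARS:
        try:
            c = correlate(occl, x=var, y="fsi_min")
            rows.append(
                {"variable": var, "rho": c.rho, "p": c.p_value, "n": c.n}
            )
        except ValueError:
            rows.append({"variable": var, "rho": np.nan, "p": np.nan, "n": 0})
    correlations = pd.DataFrame(rows)

    metadata = {
        "n_subjects": len(records),
        "n_events": len(all_summaries),
        "n_skipped_events": skipped_total,
        "window_s": window_s,
        "ph_threshold": PH_THRESHOLD,
        "multiple_testing_correction": "none",
        "config": cfg,
    }
    return StudyResult(
        time_evolution=time_evolution,
        group_comparison=group_comparison,
        correlations=correlations,
        summaries=all_summaries,
        metadata=metadata,
    )
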
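"""Glycaemic endpoints and between-arm statistics.

Time-in-band metrics use sample-hold weighting on the 5-minute CGM grid
(fraction of readings in band), matching how percentage-of-readings metrics
are reported clinically.  Band conventions: target [4.0, 8.0] mmol/L
inclusive, wide band [2.6, 10.0] inclusive, hyperglycaemia strictly
> 10.0, hypoglycaemia strictly < 2.6 — non-overlapping at the edges up to
ties.  Between-arm comparisons use the Mann-Whitney U test (exact for small
tie-free samples) for skewed variables and the pooled-variance unpaired t
test otherwise, at the conventional 0.05 significance level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .trial import TrialDataset, TrialRecord


def time_in_range(series: Sequence[float], lo: float, hi: float) -> float:
    """Percent of samples with lo <= value <= hi (sample-hold weighting)."""
    arr = _clean(series)
    return float(((arr >= lo) & (arr <= hi)).mean() * 100.0)


def pct_above(series: Sequence[float], threshold: float) -> float:
    """Percent of samples strictly above ``threshold``."""
    arr = _clean(series)
    return float((arr > threshold).mean() * 100.0)


def pct_below(series: Sequence[float], threshold: float) -> float:
    """Percent of samples strictly below ``threshold``."""
    arr = _clean(series)
    return float((arr < threshold).mean() * 100.0)


def _clean(series: Sequence[float]) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty glucose series")
    return arr


def percent_to_hours(pct: float, window_h: float) -> Tuple[float, int]:
    """Convert a percentage of a window to hours: (exact, rounded)."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("pct must lie in [0, 100]")
    exact = pct / 100.0 * window_h
    return exact, int(math.floor(exact + 0.5))


@dataclass(frozen=True)
class Episode:
    start: float      # min
    end: float        # min (inclusive last sample time)
    duration: float   # min, sample-hold
    nadir: float      # mmol/L


def episodes_below(times: Sequence[float], values: Sequence[float],
                   threshold: float = 2.6,
                   min_duration: float = 10.0) -> List[Episode]:
    """Maximal runs of consecutive samples strictly below ``threshold``.

    Duration is sample-hold: a run of n consecutive samples on a grid of
    spacing dt lasts n*dt minutes.  Runs shorter than ``min_duration`` are
    suppressed (two 5-min samples by default, filtering one-sample noise).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    dt = float(np.median(np.diff(t))) if t.size > 1 else min_duration
    episodes: List[Episode] = []
    start = None
    for i in range(t.size):
        below = not np.isnan(v[i]) and v[i] < threshold
        if below and start is None:
            start = i
        elif not below and start is not None:
            episodes.append(_make_episode(t, v, start, i - 1, dt))
            start = None
    if start is not None:
        episodes.append(_make_episode(t, v, start, t.size - 1, dt))
    return [e for e in episodes if e.duration >= min_duration]


def _make_episode(t, v, i0, i1, dt) -> Episode:
    return Episode(start=float(t[i0]), end=float(t[i1]),
                   duration=(i1 - i0 + 1) * dt,
                   nadir=float(np.nanmin(v[i0:i1 + 1])))


def summary_stats(series: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and SD (n-1 denominator); SD is NaN below n=2."""
    arr = _clean(series)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return mean, sd


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """Median and quartiles by linear interpolation (type-7 convention)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples.

    Exact enumeration when min(n) <= 8 with no ties across the pooled
    sample; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def unpaired_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pooled-variance two-sample t test, two-sided."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# -- per-record summaries -------------------------------------------------

@dataclass
class GlycaemicSummary:
    pct_4_8: float
    pct_2p6_10: float
    pct_gt10: float
    pct_lt2p6: float
    baseline_sg: float
    mean_sg: float
    sd_sg: float
    hypo_episodes: int
    hypo_durations: Tuple[float, ...]
    insulin_mean: float          # U/kg/h
    dextrose_mean: float         # mg/kg/min, total exogenous glucose

    def __post_init__(self) -> None:
        if not self.pct_4_8 <= self.pct_2p6_10 + 1e-9:
            raise ValueError("target band cannot exceed the wide band")


PERIODS = {"intervention": (48.0, 72.0), "post": (72.0, 160.0),
           "pre": (0.0, 48.0), "all": (0.0, float("inf"))}


def slice_period(record: TrialRecord, period: str,
                 protocol_hours: Optional[Tuple[float, float]] = None
                 ) -> pd.DataFrame:
    lo_h, hi_h = protocol_hours or PERIODS[period]
    df = record.data
    return df[(df["time_min"] >= lo_h * 60) & (df["time_min"] < hi_h * 60)]


def summarise_record(record: TrialRecord, period: str = "intervention"
                     ) -> GlycaemicSummary:
    df = slice_period(record, period)
    sg = df["sg"].to_numpy()
    if np.all(np.isnan(sg)):
        raise ValueError(f"no SG data in period {period!r}")
    mean_sg, sd_sg = summary_stats(sg)
    eps = episodes_below(df["time_min"].to_numpy()[~np.isnan(sg)],
                         sg[~np.isnan(sg)], 2.6)
    first = sg[~np.isnan(sg)][0]
    dex_flux = (df["maintenance_dextrose"]
                + df["dextrose20_ml_kg_h"] * 200.0 / 60.0).mean()
    return GlycaemicSummary(
        pct_4_8=time_in_range(sg, 4.0, 8.0),
        pct_2p6_10=time_in_range(sg, 2.6, 10.0),
        pct_gt10=pct_above(sg, 10.0),
        pct_lt2p6=pct_below(sg, 2.6),
        baseline_sg=float(first),
        mean_sg=mean_sg, sd_sg=sd_sg,
        hypo_episodes=len(eps),
        hypo_durations=tuple(e.duration for e in eps),
        insulin_mean=float(df["insulin_u_kg_h"].mean()),
        dextrose_mean=float(dex_flux))


#: Table rows in study order: (label, summary attribute, test)
TABLE_ROWS = (
    ("Time 4.0-8.0 mmol/L (%)", "pct_4_8", "mann_whitney"),
    ("Time 2.6-10.0 mmol/L (%)", "pct_2p6_10", "mann_whitney"),
    ("Time >10.0 mmol/L (%)", "pct_gt10", "mann_whitney"),
    ("Time <2.6 mmol/L (%)", "pct_lt2p6", "mann_whitney"),
    ("Baseline sensor glucose (mmol/L)", "baseline_sg", "mann_whitney"),
    ("Mean sensor glucose (mmol/L)", "mean_sg", "mann_whitney"),
    ("SD of sensor glucose (mmol/L)", "sd_sg", "mann_whitney"),
    ("Insulin (U/kg/hour)", "insulin_mean", "mann_whitney"),
    ("Dextrose (mg/kg/min)", "dextrose_mean", "mann_whitney"),
)


def outcome_table(dataset_or_records, period: str = "intervention",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-arm median (IQR) of each glycaemic summary plus between-arm p.

    Accepts a TrialDataset or a plain list of TrialRecords containing both
    arms.  Rows mirror the study's glucose-control comparison tables.
    """
    if isinstance(dataset_or_records, TrialDataset):
        records = dataset_or_records.records
    else:
        records = list(dataset_or_records)
    by_arm: Dict[str, List[GlycaemicSummary]] = {"closed_loop": [],
                                                 "control": []}
    for rec in sorted(records, key=lambda r: r.infant_id):
        by_arm[rec.arm].append(summarise_record(rec, period))
    for arm, summaries in by_arm.items():
        if not summaries:
            raise ValueError(f"no records in arm {arm!r}")
    rows = []
    for label, attr, test in TABLE_ROWS:
        vals = {arm: [getattr(s, attr) for s in summ]
                for arm, summ in by_arm.items()}
        if test == "mann_whitney":
            _, p = mann_whitney(vals["closed_loop"], vals["control"])
            test_name = "Mann-Whitney U"
        else:
            _, p = unpaired_t(vals["closed_loop"], vals["control"])
            test_name = "unpaired t"
        row = {"outcome": label}
        for arm in ("closed_loop", "control"):
            med, q1, q3 = median_iqr(vals[arm])
            row[f"{arm}_median"] = med
            row[f"{arm}_q1"] = q1
            row[f"{arm}_q3"] = q3
        row["p_value"] = p
        row["test"] = test_name
        row["significant"] = p < alpha
        rows.append(row)
    return pd.DataFrame(rows)


def format_table(table: pd.DataFrame) -> str:
    """Human-readable median (IQR) rendering of :func:`outcome_table`."""
    lines = [f"{'outcome':40s} {'closed loop':>22s} {'control':>22s} "
             f"{'p':>7s}"]
    for _, r in table.iterrows():
        cl = (f"{r['closed_loop_median']:.1f} "
              f"({r['closed_loop_q1']:.1f}-{r['closed_loop_q3']:.1f})")
        co = (f"{r['control_median']:.1f} "
              f"({r['control_q1']:.1f}-{r['control_q3']:.1f})")
        lines.append(f"{r['outcome']:40s} {cl:>22s} {co:>22s} "
                     f"{r['p_value']:7.3f}")
    return "\n".join(lines)


def plot_summary(dataset: TrialDataset, path: Optional[str] = None):
    """Median +/- IQR SG and insulin over time by arm, window marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    colors = {"closed_loop": "tab:blue", "control": "tab:orange"}
    for arm in ("closed_loop", "control"):
        recs = [r for r in dataset.records if r.arm == arm]
        if not recs:
            continue
        frames = [r.data.set_index("time_min")[["sg", "insulin_u_kg_h"]]
                  for r in recs]
        merged = pd.concat(frames, axis=1, keys=range(len(frames)))
        t = merged.index / 60.0
        for ax, var in zip(axes, ("sg", "insulin_u_kg_h")):
            block = merged.xs(var, axis=1, level=1)
            med = block.median(axis=1)
            q1, q3 = block.quantile(0.25, axis=1), block.quantile(0.75, axis=1)
            ax.plot(t, med, color=colors[arm], label=arm.replace("_", " "))
            ax.fill_between(t, q1, q3, alpha=0.2, color=colors[arm])
    axes[0].axhspan(4.0, 8.0, color="grey", alpha=0.15)
    axes[0].set_ylabel("sensor glucose (mmol/L)")
    axes[1].set_ylabel("insulin (U/kg/h)")
    axes[1].set_xlabel("hours from birth")
    for ax in axes:
        for h in (48, 72):
            ax.axvline(h, color="k", linestyle=":")
    axes[0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
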
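"""Fold changes, normality diagnostics, and response classification.

Fold change is computed per entity and time point as the replicate-mean
abundance divided by the replicate-mean abundance at time zero (the
nitrogen-replete control). An entity is differential when it crosses the
fold-change cutoff (2-fold by default, symmetric in log space) at any point
of the analysis window; its response is timed by the first crossing — the
early window (0.5-4 h) precedes the onset of TAG accumulation, the late
window (6-24 h) follows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import (
    REGULATOR_CLASSES,
    ResponseCall,
    TimeCourseMatrix,
)


@dataclass
class FoldChangeMatrix:
    """Per-entity fold changes relative to time zero.

    ``log2fc`` is an entities x times DataFrame over the non-baseline time
    grid (NaN where a value is absent). ``excluded`` lists entities dropped
    with a reason (e.g. zero baseline) rather than silently.
    """

    log2fc: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def fc(self) -> pd.DataFrame:
        return 2.0 ** self.log2fc

    @property
    def entity_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def times(self) -> np.ndarray:
        return self.log2fc.columns.to_numpy(dtype=float)

    def window(self, lo: float, hi: float) -> pd.DataFrame:
        cols = [t for t in self.log2fc.columns if lo <= t <= hi]
        return self.log2fc[cols]


def fold_change(tc: TimeCourseMatrix) -> FoldChangeMatrix:
    """Replicate-mean fold change of every entity relative to time zero."""
    means = tc.replicate_means()
    baseline = means[0.0]
    excluded = [
        (eid, "zero baseline")
        for eid in means.index[(baseline <= 0) | baseline.isna()]
    ]
    keep = means.index[(baseline > 0) & baseline.notna()]
    nonzero_times = [t for t in means.columns if t != 0.0]
    fc = means.loc[keep, nonzero_times].div(baseline.loc[keep], axis=0)
    log2fc = np.log2(fc)
    log2fc.columns = [float(t) for t in log2fc.columns]
    return FoldChangeMatrix(log2fc=log2fc, excluded=excluded)


def classify_response(log2fc_row: pd.Series, config: AnalysisConfig) -> ResponseCall:
    """Call direction (up/down/unchanged) and timing (early/late/unaltered).

    Only time points inside the analysis window are considered. The onset is
    the first time point at which |log2fc| crosses log2(fc_threshold); the
    direction is the sign of that first crossing.
    """
    lo, hi = config.correlation_window
    row = log2fc_row[[t for t in log2fc_row.index if lo <= float(t) <= hi]]
    vals = row.to_numpy(dtype=float)
    times = np.asarray([float(t) for t in row.index])
    cut = math.log2(config.fc_threshold)
    finite = np.isfinite(vals)
    max_abs = float(np.nanmax(np.abs(vals))) if finite.any() else 0.0
    crossing = finite & (np.abs(vals) >= cut)
    name = str(log2fc_row.name) if log2fc_row.name is not None else ""
    if not crossing.any():
        return ResponseCall(name, "unchanged", "unaltered", None, max_abs)
    i = int(np.flatnonzero(crossing)[0])
    onset = float(times[i])
    direction = "up" if vals[i] > 0 else "down"
    # the default grid has no point between the two windows; any onset
    # before the late window counts as early
    timing = "early_BTS" if onset < config.ats_window[0] else "late_ATS"
    return ResponseCall(name, direction, timing, onset, max_abs)


def classify_all(fcm: FoldChangeMatrix, config: AnalysisConfig) -> dict[str, ResponseCall]:
    return {
        eid: classify_response(fcm.log2fc.loc[eid], config)
        for eid in fcm.entity_ids
    }


# ---------------------------------------------------------------------------
# normality diagnostics
# ---------------------------------------------------------------------------

def se_skewness(n: int) -> float:
    """Exact small-sample standard error of the sample skewness."""
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def se_kurtosis(n: int) -> float:
    """Exact small-sample standard error of the sample excess kurtosis."""
    return 2.0 * se_skewness(n) * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))


def normality_report(values: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point normality diagnostics across entities.

    ``values`` is an entities x times DataFrame (raw replicate means or fold
    changes — both are accepted). Returns one row per time point with
    Shapiro-Wilk W/p, bias-corrected skewness and excess kurtosis, their
    small-sample standard errors and z ratios. Fields are NaN with a reason
    when the sample is too small (n < 3 for Shapiro-Wilk/skewness SE, n < 4
    for the kurtosis SE).
    """
    rows = []
    for t in values.columns:
        x = values[t].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        n = len(x)
        row = {
            "time": float(t),
            "n": n,
            "shapiro_W": np.nan,
            "shapiro_p": np.nan,
            "skewness": np.nan,
            "se_skew": np.nan,
            "z_skew": np.nan,
            "kurtosis": np.nan,
            "se_kurt": np.nan,
            "z_kurt": np.nan,
            "reason": "",
        }
        if n < 3:
            row["reason"] = "n too small"
            rows.append(row)
            continue
        w, p = stats.shapiro(x)
        skew = float(stats.skew(x, bias=False))
        se_s = se_skewness(n)
        row.update(shapiro_W=float(w), shapiro_p=float(p), skewness=skew,
                   se_skew=se_s, z_skew=skew / se_s)
        if n >= 4:
            kurt = float(stats.kurtosis(x, bias=False, fisher=True))
            se_k = se_kurtosis(n)
            row.update(kurtosis=kurt, se_kurt=se_k, z_kurt=kurt / se_k)
        else:
            row["reason"] = "n too small for kurtosis SE"
        rows.append(row)
    return pd.DataFrame(rows).set_index("time")


def plot_normality(values: pd.DataFrame, out_dir, prefix: str = "normality") -> list:
    """Histogram, Q-Q and box plots per time point (diagnostic images)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = list(values.columns)
    written = []
    for kind in ("hist", "qq", "box"):
        fig, axes = plt.subplots(1, len(times), figsize=(3 * len(times), 3), squeeze=False)
        for ax, t in zip(axes[0], times):
            x = values[t].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if kind == "hist":
                ax.hist(x, bins=20)
            elif kind == "qq":
                stats.probplot(x, dist="norm", plot=ax)
            else:
                ax.boxplot(x, vert=True)
            ax.set_title(f"{t:g} h")
        fig.tight_layout()
        path = out_dir / f"{prefix}_{kind}.png"
        fig.savefig(path, dpi=80)
        plt.close(fig)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# differential selection
# ---------------------------------------------------------------------------

@dataclass
class DifferentialSelection:
    """Entities crossing the fold-change cutoff, partitioned by class."""

    calls: dict[str, ResponseCall]
    tf_ids: list[str]
    metabolite_ids: list[str]
    process_gene_ids: dict[str, list[str]]

    @property
    def responder_ids(self) -> list[str]:
        return [e for e, c in self.calls.items() if c.direction != "unchanged"]


def select_differential(
    fcm: FoldChangeMatrix,
    annotations: pd.DataFrame,
    config: AnalysisConfig,
    calls: Optional[dict[str, ResponseCall]] = None,
) -> DifferentialSelection:
    """Partition the differential entities into the three network sides."""
    if calls is None:
        calls = classify_all(fcm, config)
    responders = [e for e, c in calls.items() if c.direction != "unchanged"]
    cls = annotations["entity_class"]
    tf_ids = [e for e in responders if cls.get(e) in REGULATOR_CLASSES]
    metabolite_ids = [e for e in responders if cls.get(e) == "metabolite"]
    process_gene_ids: dict[str, list[str]] = {}
    for e in responders:
        if cls.get(e) in ("metabolic_gene", "protein"):
            for proc in annotations.loc[e, "processes"]:
                process_gene_ids.setdefault(proc, []).append(e)
    return DifferentialSelection(calls, tf_ids, metabolite_ids, process_gene_ids)
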
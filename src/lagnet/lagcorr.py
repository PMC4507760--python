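"""Time-lagged Pearson correlation and edge calling.

For a lag of ``l`` sample steps the paired points are ``(x[i], y[i+l])`` —
a positive lag means the regulator series ``x`` leads the target series
``y``. Lags act in index space, not hours, because the sampling grid is
uneven; on the default 7-point analysis window a lag of one step therefore
spans 0.5 h early in the course and 12 h late in it.

The returned correlation is the lag in the allowed set maximizing |r|
(ties broken toward the smaller |lag|, then the positive one). Two-sided
p-values come from the exact t transform ``t = r*sqrt((n-2)/(1-r^2))`` with
n-2 degrees of freedom; a seeded permutation alternative is available.
Edges are retained under the published criteria |r| >= 0.9 and p <= 0.05,
with no multiple-testing correction applied to the filter (a
Benjamini-Hochberg column is emitted in the audit table for reference).
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import CorrelationEdge


class ZeroVarianceError(ValueError):
    """Raised when a series is constant over every evaluable overlap."""


class OverlapError(ValueError):
    """Raised when no lag leaves enough paired points."""


class LagCorrResult(NamedTuple):
    r: float
    lag: int
    n_pairs: int
    p: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ZeroVarianceError("zero variance")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def pearson_pvalue(r: float, n_pairs: int) -> float:
    """Two-sided p-value from the t transform; exactly 0 for |r| = 1."""
    if abs(r) >= 1.0:
        return 0.0
    df = n_pairs - 2
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def _permutation_pvalue(
    a: np.ndarray, b: np.ndarray, r_obs: float, n_shuffles: int, rng: np.random.Generator
) -> float:
    count = 0
    b = b.copy()
    for _ in range(n_shuffles):
        rng.shuffle(b)
        if abs(_pearson(a, b)) >= abs(r_obs) - 1e-15:
            count += 1
    return (count + 1) / (n_shuffles + 1)


def lagged_pearson(
    x: Sequence[float],
    y: Sequence[float],
    lag_set: Sequence[int] = (0, 1),
    min_overlap: int = 5,
    p_method: str = "t",
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> LagCorrResult:
    """Best-lag Pearson correlation between two aligned series.

    Raises OverlapError if no lag leaves ``min_overlap`` paired points and
    ZeroVarianceError if every evaluable overlap is constant in x or y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share a time grid")
    n = len(x)
    best: Optional[LagCorrResult] = None
    any_overlap = False
    for lag in sorted(lag_set, key=lambda l: (abs(l), -l)):
        n_pairs = n - abs(lag)
        if n_pairs < min_overlap:
            continue
        any_overlap = True
        if lag >= 0:
            a, b = x[: n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: n + lag]
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < min_overlap:
            continue
        a, b = a[mask], b[mask]
        try:
            r = _pearson(a, b)
        except ZeroVarianceError:
            continue
        if best is None or abs(r) > abs(best.r):
            if p_method == "permutation":
                p = _permutation_pvalue(
                    a, b, r, n_permutations, rng or np.random.default_rng(0)
                )
            else:
                p = pearson_pvalue(r, int(mask.sum()))
            best = LagCorrResult(r, lag, int(mask.sum()), p)
    if not any_overlap:
        raise OverlapError("overlap below minimum")
    if best is None:
        raise ZeroVarianceError("zero variance")
    return best


def correlate_all(
    tf_fc: pd.DataFrame,
    target_fc: pd.DataFrame,
    target_class: pd.Series,
    config: AnalysisConfig,
    keep_audit: bool = False,
) -> tuple[list[CorrelationEdge], Optional[pd.DataFrame]]:
    """All TF x target lagged correlations under the retention thresholds.

    ``tf_fc`` and ``target_fc`` are entities x times log2 fold-change
    matrices already restricted to the analysis window; the index sets must
    be disjoint (the comparison is strictly bipartite — regulator vs gene or
    regulator vs metabolite, never regulator vs regulator).
    """
    overlap = set(tf_fc.index) & set(target_fc.index)
    if overlap:
        raise ValueError(f"TF and target sets overlap: {sorted(overlap)[:3]}")
    rng = np.random.default_rng(config.seed)
    edges: list[CorrelationEdge] = []
    audit_rows = [] if keep_audit else None
    tvals = target_fc.to_numpy(dtype=float)
    xvals = tf_fc.to_numpy(dtype=float)
    for i, tf in enumerate(tf_fc.index):
        for j, tgt in enumerate(target_fc.index):
            reason = ""
            r = lag = n_pairs = p = None
            try:
                res = lagged_pearson(
                    xvals[i],
                    tvals[j],
                    lag_set=config.lag_set,
                    min_overlap=config.min_overlap,
                    p_method=config.p_method,
                    n_permutations=config.n_permutations,
                    rng=rng,
                )
                r, lag, n_pairs, p = res
                retained = abs(r) >= config.r_min and p <= config.p_max
                if retained:
                    edges.append(
                        CorrelationEdge(
                            tf_id=tf,
                            target_id=tgt,
                            target_class=str(target_class.get(tgt, "")),
                            r=r,
                            lag=lag,
                            n_pairs=n_pairs,
                            p=p,
                        )
                    )
            except OverlapError:
                retained, reason = False, "overlap below minimum"
            except ZeroVarianceError:
                retained, reason = False, "zero variance"
            if audit_rows is not None:
                audit_rows.append(
                    {
                        "tf_id": tf,
                        "target_id": tgt,
                        "r": r,
                        "lag": lag,
                        "n_pairs": n_pairs,
                        "p": p,
                        "retained": retained,
                        "reason": reason,
                    }
                )
    audit = None
    if audit_rows is not None:
        audit = pd.DataFrame(
            audit_rows,
            columns=["tf_id", "target_id", "r", "lag", "n_pairs", "p", "retained", "reason"],
        )
        ok = audit["p"].notna()
        audit["p_bh"] = np.nan
        if ok.any():
            audit.loc[ok, "p_bh"] = stats.false_discovery_control(
                audit.loc[ok, "p"].to_numpy(), method="bh"
            )
    return edges, audit
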
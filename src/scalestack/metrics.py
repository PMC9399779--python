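"""Multi-label AUC evaluation, fold aggregation, and ensemble-gain analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["FoldedScore", "auc", "aggregate_folds", "render_score", "gain_analysis"]


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random negative,
    with ties counted 1/2. Requires both classes present.
    """
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(s)  # average ranks implement the tie=1/2 convention
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class FoldedScore:
    """Per-fold values for one (finding, model) cell with mean +- std."""

    finding: str
    model: str  # scale tag (e.g. "256") or "ensemble"
    values: np.ndarray
    mean: float
    std: float


def aggregate_folds(finding: str, model: str, values) -> FoldedScore:
    """Mean and sample (n-1) standard deviation over >= 2 folds."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("fold aggregation needs at least 2 folds")
    return FoldedScore(finding, model, v, float(v.mean()), float(v.std(ddof=1)))


def render_score(score: FoldedScore) -> str:
    """Render as ``m +- s`` with 1-decimal percent formatting (half-up)."""

    def one_dec(x: float) -> float:
        return float(np.floor(x * 10.0 + 0.5) / 10.0)

    return f"{one_dec(score.mean):.1f} ± {one_dec(score.std):.1f}"


def gain_analysis(table: pd.DataFrame, ensemble_tag: str = "ensemble") -> pd.DataFrame:
    """Ensemble gain over the best single-scale model, per finding.

    ``table`` has columns (finding, model, mean_auc) in AUC percentage
    points; the result adds a per-finding gain column and a final row with
    the average gain. Negative gains are flagged. Invariant to row order.
    """
    findings = sorted(table["finding"].unique())
    rows = []
    for f in findings:
        sub = table[table["finding"] == f]
        ens = sub[sub["model"] == ensemble_tag]["mean_auc"]
        if ens.empty:
            raise ValueError(f"missing ensemble row for finding {f!r}")
        singles = sub[sub["model"] != ensemble_tag]
        if len(singles) < 2:
            raise ValueError(f"need >= 2 single-scale rows for finding {f!r}")
        best = singles["mean_auc"].max()
        best_model = singles.loc[singles["mean_auc"].idxmax(), "model"]
        gain = float(ens.iloc[0] - best)
        rows.append({"finding": f, "best_single": str(best_model),
                     "best_single_auc": float(best),
                     "ensemble_auc": float(ens.iloc[0]),
                     "gain": gain, "negative": gain < 0})
    out = pd.DataFrame(rows)
    out.attrs["average_gain"] = float(out["gain"].mean())
    out.attrs["min_gain"] = float(out["gain"].min())
    return out
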
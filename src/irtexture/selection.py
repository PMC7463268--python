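"""ANOVA filter feature selection.

Each feature is scored by a one-way ANOVA F statistic between the two
groups (for two groups F equals the squared pooled-variance t statistic,
with 1 and n-2 degrees of freedom) and features are kept in descending-F
order. Selection is a pure filter on the full table by default; nested
per-fold re-ranking lives in the cross-validation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image import ParameterError

POSITIVE_LABEL = "case"
NEGATIVE_LABEL = "control"


@dataclass
class RankedFeatures:
    """Descending-F ranking with group means; excluded = non-finite features."""

    table: pd.DataFrame  # columns: rank, feature, F, p, mean_control, mean_case
    excluded: list[str]

    @property
    def names(self) -> list[str]:
        return list(self.table["feature"])


def anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for exactly two groups.

    Degenerate policies: zero within-group variance with distinct means
    gives (inf, 0); zero between-group variance gives (0, 1).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in (NEGATIVE_LABEL, POSITIVE_LABEL)]
    if any(len(g) < 2 for g in groups):
        raise ParameterError("each group needs at least 2 values")
    if not np.isfinite(values).all():
        raise ParameterError("non-finite feature values")
    n = len(values)
    grand = values.mean()
    means = [g.mean() for g in groups]
    ss_between = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ss_within = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    if ss_within == 0:
        if means[0] != means[1]:
            return float("inf"), 0.0
        return 0.0, 1.0
    if ss_between == 0:
        return 0.0, 1.0
    f = (ss_between / 1.0) / (ss_within / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p


def rank_features(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> RankedFeatures:
    """Rank every usable feature column by descending ANOVA F.

    Columns containing non-finite values (undefined features) are excluded
    and listed. Infinite F ranks above all finite F; ties break by feature
    name (lexicographic).
    """
    labels = np.asarray(labels)
    rows, excluded = [], []
    for name in table.columns:
        vals = table[name].to_numpy(dtype=np.float64)
        if not np.isfinite(vals).all():
            excluded.append(name)
            continue
        f, p = anova_f(vals, labels)
        rows.append(
            {
                "feature": name,
                "F": f,
                "p": p,
                "mean_control": float(vals[labels == NEGATIVE_LABEL].mean()),
                "mean_case": float(vals[labels == POSITIVE_LABEL].mean()),
            }
        )
    if not rows:
        raise ParameterError("no feature with complete finite values")
    df = pd.DataFrame(rows)
    df = df.sort_values(["F", "feature"], ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RankedFeatures(table=df.reset_index(drop=True), excluded=excluded)


def select_top_k(ranked: RankedFeatures, k: int = 5) -> list[str]:
    """First ``k`` feature names in rank order."""
    names = ranked.names
    if not 1 <= k <= len(names):
        raise ParameterError(f"k must be in [1, {len(names)}], got {k}")
    return names[:k]
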
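"""Variable ranking and top-G selection, computed on the training set only.

The default statistic is the two-sample equal-variance (pooled) t; Welch t,
Wilcoxon rank-sum and fold change are available behind the same interface.
All statistics return nonnegative scores (absolute values), so "largest
score" always means "most class-discriminating under that metric".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CLASS1, CLASS2, ExpressionDataset


@dataclass
class SelectionResult:
    """Top-G variable selection: absolute scores and chosen column indices."""

    scores: np.ndarray
    selected_indices: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)


def _class_split(train: ExpressionDataset, min_per_class: int = 2):
    x1 = train.values[train.labels == CLASS1]
    x2 = train.values[train.labels == CLASS2]
    if len(x1) < min_per_class or len(x2) < min_per_class:
        raise ValueError(
            f"each class needs >= {min_per_class} samples "
            f"(got {len(x1)} vs {len(x2)})"
        )
    return x1, x2


def equal_variance_t(train: ExpressionDataset) -> np.ndarray:
    """|t| per variable with the pooled-variance two-sample formula.

    Variables with zero pooled variance score 0 (they carry no class signal
    under the model and would otherwise divide by zero).
    """
    x1, x2 = _class_split(train)
    n1, n2 = len(x1), len(x2)
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    sp2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.abs(diff) / denom
    return np.where(denom > 0, scores, 0.0)


def welch_t(train: ExpressionDataset) -> np.ndarray:
    """|t| per variable with Welch's unequal-variance denominator."""
    x1, x2 = _class_split(train)
    denom = np.sqrt(
        x1.var(axis=0, ddof=1) / len(x1) + x2.var(axis=0, ddof=1) / len(x2)
    )
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.abs(diff) / denom
    return np.where(denom > 0, scores, 0.0)


def wilcoxon(train: ExpressionDataset) -> np.ndarray:
    """Distance of the Wilcoxon rank-sum statistic from its null expectation.

    Ranks are midranks (average ties); the score is |U - n1*n2/2|, maximal
    under complete separation of the classes.
    """
    x1, x2 = _class_split(train, min_per_class=1)
    n1, n2 = len(x1), len(x2)
    ranks = stats.rankdata(train.values, axis=0)
    r1 = ranks[train.labels == CLASS1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return np.abs(u1 - n1 * n2 / 2.0)


def fold_change(train: ExpressionDataset) -> np.ndarray:
    """Absolute difference of class means (log-scale fold change)."""
    x1, x2 = _class_split(train, min_per_class=1)
    return np.abs(x1.mean(axis=0) - x2.mean(axis=0))


_STATISTICS = {
    "t_equal": equal_variance_t,
    "welch_t": welch_t,
    "wilcoxon": wilcoxon,
    "fold_change": fold_change,
}


def compute_scores(train: ExpressionDataset, method: str = "t_equal") -> np.ndarray:
    try:
        fn = _STATISTICS[method]
    except KeyError:
        raise ValueError(
            f"unknown selection method {method!r}; supported: {sorted(_STATISTICS)}"
        ) from None
    return fn(train)


def select_top(scores: np.ndarray, G: int) -> SelectionResult:
    """Indices of the ``min(G, p)`` largest scores, descending; ties go to the
    lowest index so runs are reproducible.  ``G = p`` reproduces the
    no-selection arm."""
    if G < 1:
        raise ValueError("G must be >= 1")
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    return SelectionResult(scores, order[: min(G, scores.size)], method="top_g")


def select_variables(
    train: ExpressionDataset, G: int, method: str = "t_equal"
) -> SelectionResult:
    """Rank on the training set and keep the top G variables."""
    result = select_top(compute_scores(train, method), G)
    result.method = method
    return result
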
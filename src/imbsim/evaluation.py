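"""Performance measures and across-replication summaries.

Per replication: overall predictive accuracy PA, class-specific PA1
(sensitivity, Class 1 positive) and PA2 (specificity), predictive values
PV1/PV2 under an assumed population prevalence kappa1, and AUC from
continuous Class-1-oriented scores.  Across replications: means and 95%
prediction intervals (empirical 2.5th-97.5th percentiles).

Identities used throughout:

* ``PA = PA1 * k1test + PA2 * k2test`` (exact when the weights are the
  empirical test-set proportions);
* ``PV1 = kappa1*PA1 / (kappa1*PA1 + (1-kappa1)*(1-PA2))`` and symmetrically
  for PV2; an uninformative classifier (PA1 = 1 - PA2) gives PV1 = kappa1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLASS1, CLASS2

METRIC_COLUMNS = ("PA", "PA1", "PA2", "PV1", "PV2", "AUC")


@dataclass
class PredictionOutcome:
    """Test-set truth, hard predictions and continuous scores for one replication."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (
            len(self.true_labels) == len(self.predicted_labels) == len(self.scores)
        ):
            raise ValueError("true labels, predictions and scores must align")


def class_accuracies(outcome: PredictionOutcome) -> Tuple[float, float, float]:
    """(PA, PA1, PA2): overall and class-specific fractions correct."""
    true, pred = outcome.true_labels, outcome.predicted_labels
    n1 = (true == CLASS1).sum()
    n2 = (true == CLASS2).sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present in the test set")
    correct = pred == true
    pa1 = correct[true == CLASS1].mean()
    pa2 = correct[true == CLASS2].mean()
    return float(correct.mean()), float(pa1), float(pa2)


def predictive_values(pa1: float, pa2: float, kappa1: float) -> Tuple[float, float]:
    """(PV1, PV2) under population Class-1 prevalence ``kappa1``.

    A zero denominator (no predictions into a class) yields NaN for that PV
    rather than a misleading 0.
    """
    for name, v in (("PA1", pa1), ("PA2", pa2), ("kappa1", kappa1)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    den1 = kappa1 * pa1 + (1 - kappa1) * (1 - pa2)
    den2 = (1 - kappa1) * pa2 + kappa1 * (1 - pa1)
    pv1 = kappa1 * pa1 / den1 if den1 > 0 else float("nan")
    pv2 = (1 - kappa1) * pa2 / den2 if den2 > 0 else float("nan")
    return pv1, pv2


def auc(outcome: PredictionOutcome) -> float:
    """Concordance-form AUC with tie correction.

    ``P(score_1 > score_2) + 0.5 P(score_1 = score_2)`` for random Class-1 /
    Class-2 test samples, computed from midranks; identical scores for all
    samples give 0.5.
    """
    true, scores = outcome.true_labels, outcome.scores
    n1 = int((true == CLASS1).sum())
    n2 = int((true == CLASS2).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present in the test set")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    ranks = stats.rankdata(scores)
    r1 = ranks[true == CLASS1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2))


def prediction_interval(values: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """Empirical (2.5th, 97.5th)-percentile interval with linear interpolation."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]  # undefined replications (e.g. NaN PVs)
    if values.size == 0:
        return float("nan"), float("nan")
    if values.size < 40:
        warnings.warn(
            f"only {values.size} replications: the {level:.0%} prediction "
            "interval will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = (1 - level) / 2
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def replication_metrics(outcome: PredictionOutcome, kappa1: float) -> dict:
    """All per-replication metrics as one dict (one tidy results row)."""
    pa, pa1, pa2 = class_accuracies(outcome)
    pv1, pv2 = predictive_values(pa1, pa2, kappa1)
    return {
        "PA": pa,
        "PA1": pa1,
        "PA2": pa2,
        "PV1": pv1,
        "PV2": pv2,
        "AUC": auc(outcome),
    }


@dataclass
class MetricsSummary:
    """Per-replication metric table plus across-replication summaries."""

    per_replication: pd.DataFrame  # columns: replication + METRIC_COLUMNS
    kappa1: float

    def mean(self, metric: str) -> float:
        return float(self.per_replication[metric].mean())

    def variance(self, metric: str) -> float:
        return float(self.per_replication[metric].var(ddof=1))

    def interval(self, metric: str, level: float = 0.95) -> Tuple[float, float]:
        return prediction_interval(self.per_replication[metric].to_numpy(), level)

    def summary(self) -> pd.DataFrame:
        """One row per metric: mean and 95% prediction-interval endpoints."""
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for m in METRIC_COLUMNS:
                lo, hi = self.interval(m)
                rows.append({"metric": m, "mean": self.mean(m), "pi_low": lo, "pi_high": hi})
        return pd.DataFrame(rows)
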
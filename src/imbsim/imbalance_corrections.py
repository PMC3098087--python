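"""Training-set corrections for class imbalance.

* over-sampling: duplicate randomly chosen minority samples up to the
  majority count (with replacement whenever the deficit exceeds the minority
  size), giving a balanced set of size 2*max(n1, n2);
* down-sizing: discard randomly chosen majority samples down to the minority
  count, giving a balanced set of size 2*min(n1, n2);
* multiple down-sizing (MultDS): asymmetric bagging — B independent
  down-sized sets (each keeps all minority samples), variable selection
  re-run inside every one, one classifier per set, combined by majority
  vote.  B is odd so a two-class vote cannot tie; the ensemble's continuous
  score is the fraction of members voting Class 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import CLASS1, CLASS2, ExpressionDataset
from .classifiers import FittedClassifier, make_classifier
from .feature_selection import SelectionResult, select_variables


def _minority_majority(train: ExpressionDataset) -> tuple[int, int]:
    """Return (minority_label, majority_label); ties treat Class 1 as minority."""
    return (CLASS1, CLASS2) if train.n1 <= train.n2 else (CLASS2, CLASS1)


def oversample(train: ExpressionDataset, rng: np.random.Generator) -> ExpressionDataset:
    """Balance by duplicating minority samples; size becomes 2*max(n1, n2)."""
    if train.n1 == 0 or train.n2 == 0:
        raise ValueError("both classes must be nonempty")
    if train.n1 == train.n2:
        return train
    mino, _ = _minority_majority(train)
    mino_idx = train.class_indices(mino)
    deficit = abs(train.n1 - train.n2)
    extra = rng.choice(mino_idx, size=deficit, replace=deficit > mino_idx.size)
    rows = np.concatenate([np.arange(train.n), extra])
    return train.subset_samples(rows)


def downsize(train: ExpressionDataset, rng: np.random.Generator) -> ExpressionDataset:
    """Balance by removing random majority samples; size becomes 2*min(n1, n2)."""
    if min(train.n1, train.n2) < 2:
        raise ValueError(
            "down-sizing needs >= 2 minority samples (variance estimates undefined below)"
        )
    if train.n1 == train.n2:
        return train
    mino, majo = _minority_majority(train)
    keep_majo = rng.choice(
        train.class_indices(majo), size=min(train.n1, train.n2), replace=False
    )
    rows = np.sort(np.concatenate([train.class_indices(mino), keep_majo]))
    return train.subset_samples(rows)


@dataclass
class MultDSEnsemble:
    """B down-sized member classifiers, each with its own variable selection."""

    B: int
    selections: List[SelectionResult] = field(default_factory=list)
    models: List[FittedClassifier] = field(default_factory=list)

    def member_votes(self, X: np.ndarray) -> np.ndarray:
        """(B, n) matrix of member label predictions."""
        return np.stack(
            [
                model.predict(np.asarray(X)[:, sel.selected_indices])
                for sel, model in zip(self.selections, self.models)
            ]
        )

    def score(self, X: np.ndarray) -> np.ndarray:
        """Fraction of members voting Class 1."""
        return (self.member_votes(X) == CLASS1).mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.score(X) > 0.5, CLASS1, CLASS2)


def fit_multds(
    train: ExpressionDataset,
    classifier: str,
    G: int,
    rng: np.random.Generator,
    selection_method: str = "t_equal",
    B: int = 101,
    k1train: Optional[float] = None,
    **classifier_kwargs,
) -> MultDSEnsemble:
    """Fit a MultDS ensemble on the (possibly imbalanced) training set.

    Member resamples draw independent RNG substreams from ``rng``, so members
    are exchangeable and the ensemble is reproducible from one generator
    state.  After down-sizing every member is balanced, so thresholded
    classifier variants see k1train = 0.5 within members.
    """
    if B % 2 == 0 or B < 1:
        raise ValueError("B must be a positive odd number")
    ensemble = MultDSEnsemble(B=B)
    member_rngs = rng.spawn(B)
    for b in range(B):
        sub = downsize(train, member_rngs[b])
        sel = select_variables(sub, G, selection_method)
        model = make_classifier(
            classifier,
            k1train=0.5 if k1train is None else sub.n1 / sub.n,
            seed=int(member_rngs[b].integers(2**31)),
            **classifier_kwargs,
        )
        model.fit(sub.values[:, sel.selected_indices], sub.labels)
        ensemble.selections.append(sel)
        ensemble.models.append(model)
    return ensemble


def predict_multds(ensemble: MultDSEnsemble, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels of the ensemble for sample matrix ``X``."""
    return ensemble.predict(X)
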
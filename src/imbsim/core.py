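"""Core containers and configuration for the imbalanced-classification study.

Two-class expression data are held in :class:`ExpressionDataset` (samples in
rows, variables in columns, labels coded 1 / 2 with Class 1 conventionally the
minority / "positive" class).  A full simulation arm — generator settings,
normalization, selection, classifier, imbalance correction, replication count
and seed — is one :class:`ScenarioConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

CLASS1 = 1
CLASS2 = 2

NORMALIZATIONS = ("raw", "samples", "variables")
CORRECTIONS = ("none", "oversample", "downsize", "multds")
SELECTION_METHODS = ("t_equal", "welch_t", "wilcoxon", "fold_change")
CLASSIFIER_NAMES = (
    "knn1", "knn3", "knn5", "dlda", "dqda", "pam",
    "plr", "plr_thr", "rf", "rf_thr", "svm",
)


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


def class_count(k1: float, n: int) -> int:
    """Number of Class-1 samples in a set of size ``n`` at proportion ``k1``.

    Uses round-half-up so that the .5 boundary favours Class 1; e.g.
    ``class_count(0.05, 80) == 4`` (giving the 4-vs-76 design).
    """
    return int(np.floor(k1 * n + 0.5))


@dataclass
class ExpressionDataset:
    """Samples-by-variables expression matrix with binary class labels.

    Parameters
    ----------
    values
        ``(n, p)`` float matrix of expression values ``x_ij``.
    labels
        Length-``n`` integer labels, each 1 (Class 1) or 2 (Class 2).
    variable_ids
        Length-``p`` variable identifiers.
    truth_mask
        Optional length-``p`` boolean array flagging the non-null variables
        (those whose Class-2 population mean differs from 0).
    """

    values: np.ndarray
    labels: np.ndarray
    variable_ids: np.ndarray = None  # type: ignore[assignment]
    truth_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x variables) matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length must equal the number of rows")
        if not np.isin(self.labels, (CLASS1, CLASS2)).all():
            raise ValueError("labels must be coded 1 (Class 1) or 2 (Class 2)")
        if np.isnan(self.values).any():
            raise ValueError(
                "values contain missing entries; replace them (with 0) on ingestion"
            )
        if self.variable_ids is None:
            self.variable_ids = np.array(
                [f"V{j + 1}" for j in range(self.values.shape[1])]
            )
        else:
            self.variable_ids = np.asarray(self.variable_ids)
            if self.variable_ids.shape != (self.values.shape[1],):
                raise ValueError("variable_ids length must equal the number of columns")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != (self.values.shape[1],):
                raise ValueError("truth_mask length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int((self.labels == CLASS1).sum())

    @property
    def n2(self) -> int:
        return int((self.labels == CLASS2).sum())

    def class_indices(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cls)

    def subset_samples(self, rows: Sequence[int]) -> "ExpressionDataset":
        rows = np.asarray(rows, dtype=int)
        return ExpressionDataset(
            self.values[rows], self.labels[rows], self.variable_ids, self.truth_mask
        )

    def subset_variables(self, cols: Sequence[int]) -> "ExpressionDataset":
        cols = np.asarray(cols, dtype=int)
        mask = self.truth_mask[cols] if self.truth_mask is not None else None
        return ExpressionDataset(
            self.values[:, cols], self.labels, self.variable_ids[cols], mask
        )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(values, self.labels, self.variable_ids, self.truth_mask)


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation arm.

    Defaults mirror the core study design: n=100 samples split 80/20,
    p independent N(0, sigma^2) variables, p_DE of them shifted to mean
    ``mu2`` in Class 2, top-``G`` selection by equal-variance t statistic,
    sample (row) mean-centering, balanced test set.
    """

    p: int = 1000
    p_de: int = 0
    mu2: float = 0.0
    sigma: float = 1.0
    n_train: int = 80
    n_test: int = 20
    k1train: float = 0.5
    k1test: float = 0.5
    G: int = 40
    normalization: str = "samples"
    selection_method: str = "t_equal"
    classifier: str = "dlda"
    correction: str = "none"
    multds_B: int = 101
    rf_trees: int = 500
    rf_mtry: str = "sqrt"
    plr_lambda: float = 1.0
    replications: int = 200
    master_seed: int = 0
    kappa1: Optional[float] = None  # population Class-1 prevalence; defaults to k1train

    def __post_init__(self) -> None:
        if not 0 < self.k1train < 1 or not 0 < self.k1test < 1:
            raise ConfigurationError("k1train and k1test must lie strictly in (0, 1)")
        if self.p_de > self.p:
            raise ConfigurationError("p_de cannot exceed p")
        if self.G > self.p:
            raise ConfigurationError("G cannot exceed p")
        if self.G < 1 or self.p < 1:
            raise ConfigurationError("p and G must be positive")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )
        if self.correction not in CORRECTIONS:
            raise ConfigurationError(
                f"correction must be one of {CORRECTIONS}, got {self.correction!r}"
            )
        if self.selection_method not in SELECTION_METHODS:
            raise ConfigurationError(
                f"selection_method must be one of {SELECTION_METHODS}, "
                f"got {self.selection_method!r}"
            )
        if self.classifier not in CLASSIFIER_NAMES:
            raise ConfigurationError(
                f"classifier must be one of {CLASSIFIER_NAMES}, got {self.classifier!r}"
            )
        if self.multds_B % 2 == 0 or self.multds_B < 1:
            raise ConfigurationError("multds_B must be a positive odd number")
        for k1, n, which in (
            (self.k1train, self.n_train, "training"),
            (self.k1test, self.n_test, "test"),
        ):
            n1 = class_count(k1, n)
            if n1 < 1 or n - n1 < 1:
                raise ConfigurationError(
                    f"{which} set would have an empty class "
                    f"(k1={k1}, n={n} -> {n1} vs {n - n1})"
                )
        if self.kappa1 is None:
            self.kappa1 = self.k1train

    @property
    def n1_train(self) -> int:
        return class_count(self.k1train, self.n_train)

    @property
    def n2_train(self) -> int:
        return self.n_train - self.n1_train

    @property
    def n1_test(self) -> int:
        return class_count(self.k1test, self.n_test)

    @property
    def n2_test(self) -> int:
        return self.n_test - self.n1_test

    def to_dict(self) -> dict:
        return asdict(self)

    def updated(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def replication_rng(master_seed: int, replication_index: int, stream: int = 0) -> np.random.Generator:
    """Counter-based substream generator for one replication.

    ``stream`` separates independent uses within a replication (0: data
    generation, 1: imbalance correction, 2: classifier randomness), so adding
    a consumer never perturbs the draws of another.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(replication_index, stream))
    return np.random.default_rng(ss)
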
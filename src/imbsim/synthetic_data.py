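"""Synthetic two-class expression data generators.

Implements the study's generating model: ``p`` independent Gaussian variables,
all N(0, sigma^2) under the null case; under the alternative case ``p_DE`` of
them have mean ``mu2`` (same sigma) for Class-2 samples.  Training and test
sets are generated directly with their target class counts, which exactly
controls the imbalance in both sets and is distributionally equivalent to
simulating one pool and splitting it.

Also provides a microarray-like fixture (synthetic stand-in for a real
breast-cancer cDNA set: 99 samples x 7650 probes by default) and stratified
non-overlapping subsampling used to build imbalanced designs from it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    CLASS1,
    CLASS2,
    ConfigurationError,
    ExpressionDataset,
    ScenarioConfig,
    replication_rng,
)


def _generate(
    rng: np.random.Generator, n1: int, n2: int, p: int, p_de: int, mu2: float, sigma: float
) -> ExpressionDataset:
    n = n1 + n2
    values = rng.standard_normal((n, p)) * sigma
    truth = np.zeros(p, dtype=bool)
    truth[:p_de] = True
    if p_de and mu2 != 0.0:
        values[n1:, :p_de] += mu2
    labels = np.concatenate([np.full(n1, CLASS1), np.full(n2, CLASS2)])
    return ExpressionDataset(values, labels, truth_mask=truth)


def simulate_pair(
    config: ScenarioConfig, replication_index: int
) -> Tuple[ExpressionDataset, ExpressionDataset]:
    """Generate one (train, test) pair for a replication.

    Reproducible: the same ``(master_seed, replication_index)`` yields
    bit-identical matrices regardless of how many other replications ran.
    """
    if replication_index < 0:
        raise ValueError("replication_index must be >= 0")
    rng = replication_rng(config.master_seed, replication_index, stream=0)
    train = _generate(
        rng, config.n1_train, config.n2_train, config.p, config.p_de, config.mu2, config.sigma
    )
    test = _generate(
        rng, config.n1_test, config.n2_test, config.p, config.p_de, config.mu2, config.sigma
    )
    return train, test


def make_microarray_fixture(
    n_class1: int = 34,
    n_class2: int = 65,
    p: int = 7650,
    seed: int = 0,
    n_informative: int | None = None,
    effect_size: float = 0.8,
    missing_rate: float = 0.0,
    block_size: int = 1,
    block_rho: float = 0.0,
) -> ExpressionDataset:
    """Synthetic microarray-shaped dataset (no real data involved).

    Emulates the shape of a two-endpoint breast-cancer expression study
    (default 99 samples x 7650 probes, 34 vs 65).  ``n_informative`` variables
    (default ``min(100, p // 2)``) receive a Class-2 mean shift of
    ``effect_size``.  Optionally variables form
    equicorrelated blocks of ``block_size`` with correlation ``block_rho``.
    Injected missing values are replaced with 0, mirroring the usual
    missing-log-expression convention.
    """
    if n_class1 < 2 or n_class2 < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_informative is None:
        n_informative = min(100, p // 2)
    if not 0 <= n_informative <= p:
        raise ValueError("n_informative must lie in [0, p]")
    rng = np.random.default_rng(seed)
    n = n_class1 + n_class2
    if block_size > 1 and block_rho > 0:
        # equicorrelated block: x = sqrt(rho)*z_block + sqrt(1-rho)*eps
        n_blocks = -(-p // block_size)
        z = np.repeat(rng.standard_normal((n, n_blocks)), block_size, axis=1)[:, :p]
        values = np.sqrt(block_rho) * z + np.sqrt(1 - block_rho) * rng.standard_normal((n, p))
    else:
        values = rng.standard_normal((n, p))
    truth = np.zeros(p, dtype=bool)
    if n_informative:
        informative = rng.choice(p, size=n_informative, replace=False)
        truth[informative] = True
        values[n_class1:, informative] += effect_size
    if missing_rate > 0:
        miss = rng.random((n, p)) < missing_rate
        values[miss] = np.nan
    values = np.nan_to_num(values, nan=0.0)
    labels = np.concatenate([np.full(n_class1, CLASS1), np.full(n_class2, CLASS2)])
    ids = np.array([f"probe{j + 1}" for j in range(p)])
    return ExpressionDataset(values, labels, variable_ids=ids, truth_mask=truth)


def subsample_design(
    dataset: ExpressionDataset,
    n1_train: int,
    n2_train: int,
    n1_test: int,
    n2_test: int,
    seed: int,
) -> Tuple[ExpressionDataset, ExpressionDataset]:
    """Label-stratified, non-overlapping train/test subsets with exact counts."""
    rng = np.random.default_rng(seed)
    train_rows, test_rows = [], []
    for cls, n_tr, n_te in ((CLASS1, n1_train, n1_test), (CLASS2, n2_train, n2_test)):
        avail = dataset.class_indices(cls)
        if n_tr + n_te > avail.size:
            raise ValueError(
                f"Class {cls}: requested {n_tr}+{n_te} samples but only "
                f"{avail.size} available"
            )
        chosen = rng.choice(avail, size=n_tr + n_te, replace=False)
        train_rows.append(chosen[:n_tr])
        test_rows.append(chosen[n_tr:])
    train = dataset.subset_samples(np.sort(np.concatenate(train_rows)))
    test = dataset.subset_samples(np.sort(np.concatenate(test_rows)))
    return train, test


def write_dataset_csv(dataset: ExpressionDataset, path: str | Path, sep: str = ",") -> None:
    """Write samples-in-rows CSV/TSV with a final ``label`` column."""
    frame = pd.DataFrame(dataset.values, columns=dataset.variable_ids)
    frame["label"] = dataset.labels
    frame.to_csv(path, sep=sep, index=False)


def read_dataset_csv(path: str | Path, sep: str = ",") -> ExpressionDataset:
    """Read a delimited expression matrix with a ``label`` column.

    Missing expression values are replaced with 0 on ingestion.
    """
    frame = pd.read_csv(path, sep=sep)
    if "label" not in frame.columns:
        raise ValueError("expected a 'label' column")
    labels = frame.pop("label").to_numpy(dtype=int)
    values = frame.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    return ExpressionDataset(values, labels, variable_ids=np.asarray(frame.columns))


def write_sidecar(config: ScenarioConfig, truth_mask: Optional[np.ndarray], path: str | Path) -> None:
    payload = {"config": config.to_dict()}
    if truth_mask is not None:
        payload["truth_mask"] = [bool(v) for v in truth_mask]
    Path(path).write_text(json.dumps(payload, indent=2))
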
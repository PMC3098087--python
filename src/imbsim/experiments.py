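"""Scenario orchestration: replicated runs, grids and figure-style presets.

One replication of a scenario is: simulate a (train, test) pair, normalize
each set separately, apply the imbalance correction to the training set,
select variables on the (corrected) training set — inside every member when
the correction is MultDS — fit the classifier, predict the test set, and
score the predictions.  ``run_scenario`` repeats this R times and summarizes;
``run_grid`` expands swept axes into scenarios and concatenates tidy results.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import ExpressionDataset, ScenarioConfig, replication_rng
from .classifiers import make_classifier
from .evaluation import METRIC_COLUMNS, MetricsSummary, PredictionOutcome, replication_metrics
from .feature_selection import SelectionResult, select_variables
from .imbalance_corrections import downsize, fit_multds, oversample
from .preprocessing import normalize
from .synthetic_data import simulate_pair

logger = logging.getLogger(__name__)

PRESET_NAMES = ("fig1", "fig2", "fig3", "fig4", "fig5")
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_K1_SWEEP = tuple(float(v) for v in np.round(np.arange(0.05, 0.96, 0.05), 2))
_NINE_CLASSIFIERS = ("knn1", "knn3", "knn5", "dlda", "dqda", "pam", "rf", "svm", "plr")


def classify_replication(
    train: ExpressionDataset,
    test: ExpressionDataset,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> Tuple[PredictionOutcome, Optional[SelectionResult]]:
    """Run the post-simulation pipeline for one already-generated pair.

    Normalization, correction, selection and fitting see only the training
    set; the test matrix enters solely at prediction time.  Returns the
    prediction outcome and, for non-ensemble arms, the selection used
    (MultDS embeds one selection per member and returns ``None`` here).
    """
    train = normalize(train, config.normalization)
    test = normalize(test, config.normalization)

    if config.correction == "multds":
        ensemble = fit_multds(
            train,
            classifier=config.classifier,
            G=config.G,
            rng=rng,
            selection_method=config.selection_method,
            B=config.multds_B,
            rf_trees=config.rf_trees,
            rf_mtry=config.rf_mtry,
            plr_lambda=config.plr_lambda,
        )
        outcome = PredictionOutcome(
            test.labels, ensemble.predict(test.values), ensemble.score(test.values)
        )
        return outcome, None

    if config.correction == "oversample":
        train = oversample(train, rng)
    elif config.correction == "downsize":
        train = downsize(train, rng)

    selection = select_variables(train, config.G, config.selection_method)
    cols = selection.selected_indices
    model = make_classifier(
        config.classifier,
        k1train=train.n1 / train.n,
        seed=int(rng.integers(2**31)),
        rf_trees=config.rf_trees,
        rf_mtry=config.rf_mtry,
        plr_lambda=config.plr_lambda,
    )
    model.fit(train.values[:, cols], train.labels)
    x_test = test.values[:, cols]
    outcome = PredictionOutcome(test.labels, model.predict(x_test), model.score(x_test))
    return outcome, selection


def run_scenario(config: ScenarioConfig, max_failure_rate: float = 0.05) -> MetricsSummary:
    """Run all replications of one scenario and summarize.

    Fully reproducible from ``config.master_seed``: each replication draws
    from its own counter-based substream.  Failures are logged with
    (scenario, replication) provenance; the scenario aborts loudly if more
    than ``max_failure_rate`` of replications fail.
    """
    rows: List[dict] = []
    failures = 0
    for r in range(config.replications):
        try:
            train, test = simulate_pair(config, r)
            rng = replication_rng(config.master_seed, r, stream=1)
            outcome, _ = classify_replication(train, test, config, rng)
            row = {"replication": r}
            row.update(replication_metrics(outcome, config.kappa1))
            rows.append(row)
        except Exception:
            failures += 1
            logger.exception(
                "replication failed (classifier=%s correction=%s seed=%s rep=%d)",
                config.classifier, config.correction, config.master_seed, r,
            )
            if failures > max_failure_rate * config.replications:
                raise RuntimeError(
                    f"more than {max_failure_rate:.0%} of replications failed "
                    f"({failures}/{config.replications})"
                )
    return MetricsSummary(pd.DataFrame(rows), kappa1=config.kappa1)


@dataclass
class ScenarioGrid:
    """A base scenario plus swept axes.

    ``axes`` maps names to value lists and is expanded as a cartesian
    product.  Axis names that are not :class:`ScenarioConfig` fields are
    carried through to the results table but not passed to the config;
    ``derived`` maps config fields to functions of the axis assignment
    (used e.g. to tie k1test to k1train, or p_DE to p).
    """

    base: Dict = field(default_factory=dict)
    axes: Dict[str, Sequence] = field(default_factory=dict)
    derived: Dict[str, Callable[[Dict], object]] = field(default_factory=dict)
    replications: int = 200
    master_seed: int = 0

    def expand(self) -> List[Tuple[Dict, ScenarioConfig]]:
        """All grid cells as (axis-assignment, ScenarioConfig) pairs."""
        cells = []
        names = list(self.axes)
        for combo in product(*(self.axes[a] for a in names)):
            assignment = dict(zip(names, combo))
            params = dict(self.base)
            params.update({k: v for k, v in assignment.items() if k in _CONFIG_FIELDS})
            for key, fn in self.derived.items():
                params[key] = fn(assignment)
                assignment = {**assignment, key: params[key]}
            params["replications"] = self.replications
            params["master_seed"] = self.master_seed
            cells.append((assignment, ScenarioConfig(**params)))
        return cells


def _run_cell(assignment: Dict, cfg: ScenarioConfig) -> pd.DataFrame:
    frame = run_scenario(cfg).per_replication.copy()
    for key, value in assignment.items():
        frame[key] = value
    return frame


def run_grid(grid: ScenarioGrid, n_jobs: int = 1) -> pd.DataFrame:
    """Long-format per-replication results over all grid cells.

    Every cell is seeded per replication from the grid's master seed, so
    serial and parallel execution produce identical tables.
    """
    cells = grid.expand()
    frames = Parallel(n_jobs=n_jobs)(
        delayed(_run_cell)(assignment, cfg) for assignment, cfg in cells
    )
    return pd.concat(frames, ignore_index=True)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Across-replication metric means keyed by the grid's axis columns."""
    keys = [c for c in results.columns if c not in METRIC_COLUMNS and c != "replication"]
    if not keys:
        return results[list(METRIC_COLUMNS)].mean().to_frame().T
    return results.groupby(keys, as_index=False)[list(METRIC_COLUMNS)].mean()


def preset(name: str, replications: int = 200, master_seed: int = 0) -> ScenarioGrid:
    """Grids for the study's figure scenarios, at a configurable R.

    fig1: null case, p = G = 40 (no selection), nine classifiers, equal
          train/test imbalance swept 0.05..0.95.
    fig2: null case, p in {40, 1000, 10000}, G = 40 selected, balanced test.
    fig3: alternative case (mu2 = 1), p in {40, 1000, 10000},
          p_DE in {20, p}, balanced test.
    fig4: mu2 sweep (0..3) at p = 1000, p_DE = 20, sample- vs
          variable-centering arms.
    fig5: corrections {none, oversample, downsize, multds} on the fig3
          p = 1000 setting.
    """
    common = dict(n_train=80, n_test=20, G=40, normalization="samples")
    if name == "fig1":
        return ScenarioGrid(
            base={**common, "p": 40, "p_de": 0, "mu2": 0.0},
            axes={"k1train": _K1_SWEEP, "classifier": _NINE_CLASSIFIERS},
            derived={"k1test": lambda a: a["k1train"]},
            replications=replications,
            master_seed=master_seed,
        )
    if name == "fig2":
        return ScenarioGrid(
            base={**common, "p_de": 0, "mu2": 0.0, "k1test": 0.5},
            axes={"p": (40, 1000, 10000), "k1train": _K1_SWEEP,
                  "classifier": _NINE_CLASSIFIERS},
            replications=replications,
            master_seed=master_seed,
        )
    if name == "fig3":
        return ScenarioGrid(
            base={**common, "mu2": 1.0, "k1test": 0.5},
            axes={"p": (40, 1000, 10000), "de_mode": ("20", "all"),
                  "k1train": _K1_SWEEP, "classifier": ("knn1", "dlda", "plr")},
            derived={"p_de": lambda a: a["p"] if a["de_mode"] == "all" else 20},
            replications=replications,
            master_seed=master_seed,
        )
    if name == "fig4":
        return ScenarioGrid(
            base={**common, "p": 1000, "p_de": 20, "k1test": 0.5},
            axes={
                "mu2": (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0),
                "normalization": ("samples", "variables"),
                "k1train": (0.1, 0.3, 0.5),
                "classifier": ("knn1", "dlda", "plr"),
            },
            replications=replications,
            master_seed=master_seed,
        )
    if name == "fig5":
        return ScenarioGrid(
            base={**common, "p": 1000, "p_de": 20, "mu2": 1.0, "k1test": 0.5},
            axes={
                "correction": ("none", "oversample", "downsize", "multds"),
                "k1train": _K1_SWEEP,
                "classifier": ("knn1", "dlda", "plr"),
            },
            replications=replications,
            master_seed=master_seed,
        )
    raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
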
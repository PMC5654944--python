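"""Bootstrap Gini-importance feature selection.

Bins are ranked by the mean decrease in Gini impurity they contribute across a
random-forest ensemble (the estimator behind a classical Variable Importance
Plot), under a bootstrap scheme in which every replicate is balanced in the
number of cases per class. The top ``n_select`` bins by mean importance across
replicates are selected for each binary classification task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "SelectionConfig",
    "balanced_bootstrap",
    "gini_importance",
    "select_features",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the bootstrap selection scheme.

    ``min_cases`` bounds the size of each balanced bootstrap replicate from
    below: each replicate draws ``max(min_cases/2, minority class size)``
    cases per class, so no replicate has fewer than ``min_cases`` cases.
    """

    n_bootstrap: int = 100
    n_trees: int = 500
    n_select: int = 6
    min_cases: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bootstrap, self.n_trees, self.n_select, self.min_cases) < 1:
            raise ValueError("all SelectionConfig sizes must be positive")
        if self.min_cases % 2 != 0:
            raise ValueError("min_cases must be even (split equally across two classes)")


def balanced_bootstrap(
    labels: pd.Series | np.ndarray,
    min_cases: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Class-balanced bootstrap indices.

    Draws, with replacement, ``m = max(min_cases/2, minority class size)``
    positional indices from each of the two classes, so the replicate has
    exactly equal class counts. Deterministic given *seed*.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    rng = np.random.default_rng(seed)
    m = max(min_cases // 2, min(int((y == c).sum()) for c in classes))
    idx: list[np.ndarray] = []
    for c in classes:  # np.unique sorts -> class order independent of input order
        pool = np.flatnonzero(y == c)
        idx.append(rng.choice(pool, size=m, replace=True))
    return np.concatenate(idx)


def gini_importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Mean-decrease-in-Gini importance of every bin.

    Fits a random forest (bootstrap samples, sqrt-feature subsetting at each
    split) and returns its impurity importances, indexed by bin name. Rows are
    sorted by patient id before fitting so the result is invariant to input
    row order. A constant bin is never chosen for a split and scores exactly 0.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class; importance is undefined")
    order = np.argsort(np.asarray(X.index.astype(str)), kind="stable")
    Xs, ys = X.iloc[order], y[order]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed) % _MAX_SEED,
        n_jobs=1,
    )
    forest.fit(Xs.values, ys)
    return pd.Series(forest.feature_importances_, index=X.columns, name="gini_importance")


def select_features(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], pd.DataFrame]:
    """Select the ``n_select`` most important bins for a binary task.

    For each of ``n_bootstrap`` balanced replicates, a forest is grown and
    per-bin Gini importances recorded. Bins are ranked by mean importance
    across replicates; exact ties break by higher selection frequency (how
    often the bin made a replicate's top ``n_select``), then genome order.

    Returns the ordered selected bin names and the full importance table
    (columns ``mean_importance``, ``selection_frequency``, genome order
    preserved in the index).
    """
    if config.n_select > X.shape[1]:
        raise ValueError("n_select exceeds the number of bins")
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    imp_sum = np.zeros(X.shape[1])
    top_counts = np.zeros(X.shape[1])
    for _ in range(config.n_bootstrap):
        s_boot = int(rng.integers(_MAX_SEED))
        s_forest = int(rng.integers(_MAX_SEED))
        idx = balanced_bootstrap(y, config.min_cases, seed=s_boot)
        imp = gini_importance(X.iloc[idx], y[idx], config.n_trees, seed=s_forest).values
        imp_sum += imp
        # replicate-level top-n_select membership (ties at the cut resolved by
        # genome order via stable argsort on negated importances)
        top = np.argsort(-imp, kind="stable")[: config.n_select]
        top_counts[top] += 1
    table = pd.DataFrame(
        {
            "mean_importance": imp_sum / config.n_bootstrap,
            "selection_frequency": top_counts / config.n_bootstrap,
        },
        index=X.columns,
    )
    genome_pos = np.arange(X.shape[1])
    order = sorted(
        range(X.shape[1]),
        key=lambda j: (-table["mean_importance"].iloc[j],
                       -table["selection_frequency"].iloc[j],
                       genome_pos[j]),
    )
    selected = [X.columns[j] for j in order[: config.n_select]]
    return selected, table


def write_importance_table(table: pd.DataFrame, path) -> None:
    """Export an importance table as TSV, sorted by descending importance."""
    out = table.sort_values(
        ["mean_importance", "selection_frequency"], ascending=False, kind="stable"
    )
    out.to_csv(path, sep="\t", index_label="bin")
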
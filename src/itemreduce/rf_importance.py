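"""Repeated cross-validated random-forest permutation importance.

Step 1 of the item-reduction procedure: build a hierarchy of feature
importance by training repeated random forests under cross-validation and
scoring each item by mean decrease in accuracy when its values are permuted.

Default configuration follows the study design: 20 forests of 400 trees,
one per fold of a 20-fold stratified cross-validation (95% train / 5% held
fold per run). Each run yields a full importance ranking; the aggregated
hierarchy orders items by mean rank across runs.

Missing codes enter the forests as a distinct sentinel category (-1), so no
subject is dropped: missing values are treated as valid values.

Determinism and column-order invariance: forests are fitted internally on a
canonical (lexicographic item_id) column ordering and every permutation RNG
stream is keyed by (master seed, run index, item_id), so shuffling the
column order of the input table cannot change the aggregated ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._rng import derive_seed
from .item_data import RECODED_CODES, ItemTable

#: sentinel category encoding a missing code in the feature matrix
MISSING_SENTINEL = -1.0


@dataclass
class ForestConfig:
    """Random-forest and resampling settings for the importance stage.

    Defaults mirror the study design (20 runs x 400 trees under 20-fold CV);
    ``mtry`` defaults to sqrt(p), ``min_leaf`` to 1 (standard fully-grown
    classification forests). ``importance_source`` selects where permutation
    accuracy drops are measured: the run's held-out fold (default; avoids
    the optimism of permuting training rows) or out-of-bag samples per tree.
    ``independent_cv_runs`` switches from "run i = fold i of one CV" to 20
    independently shuffled CVs, one held fold each.
    """

    n_trees: int = 400
    n_runs: int = 20
    n_folds: int = 20
    seed: int = 0
    mtry: Optional[int] = None
    min_leaf: int = 1
    importance_source: str = "held_fold"
    independent_cv_runs: bool = False
    n_permutations: int = 5

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.importance_source not in ("held_fold", "oob"):
            raise ValueError("importance_source must be 'held_fold' or 'oob'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ImportanceRun:
    """One run's permutation-importance scores and within-run ranks."""

    run_index: int
    scores: Mapping[str, float]
    ranks: Mapping[str, int]


@dataclass
class FeatureRanking:
    """Aggregated importance hierarchy across runs.

    ``item_ids`` is ordered by mean rank ascending, ties broken by mean
    importance descending, then item_id lexicographically.
    """

    item_ids: tuple[str, ...]
    mean_rank: Mapping[str, float]
    mean_importance: Mapping[str, float]

    def top(self, k: int) -> tuple[str, ...]:
        return self.item_ids[:k]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "item_id": list(self.item_ids),
                "mean_rank": [self.mean_rank[i] for i in self.item_ids],
                "mean_importance": [self.mean_importance[i] for i in self.item_ids],
            }
        )


def make_forest(config: ForestConfig, seed: int) -> RandomForestClassifier:
    max_features = config.mtry if config.mtry is not None else "sqrt"
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=max_features,
        min_samples_leaf=config.min_leaf,
        random_state=seed,
        n_jobs=1,
    )


def vote_scores(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class score = fraction of trees voting for the positive class."""
    pos_idx = int(np.flatnonzero(forest.classes_ == 1)[0])
    votes = np.zeros(X.shape[0])
    for tree in forest.estimators_:
        votes += tree.predict(X) == pos_idx
    return votes / len(forest.estimators_)


def encode_for_forest(table: ItemTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode a recoded table as a dense feature matrix.

    Missing codes become the sentinel category -1, so every subject is kept.
    Columns follow the table's item (schema) order. Tables that still carry
    raw codes (3, 7, 8) are rejected: recode first.
    """
    codes = table.codes
    bad_mask = codes.notna() & ~codes.isin(list(RECODED_CODES))
    if bad_mask.any().any():
        bad_cols = [c for c in codes.columns if bad_mask[c].any()]
        raise ValueError(
            f"un-recoded codes present in items {bad_cols}; "
            "apply recode_item_codes before encoding"
        )
    X = codes.to_numpy(dtype=float, na_value=MISSING_SENTINEL)
    y = table.labels.to_numpy(dtype=int)
    return X, y, list(codes.columns)


def _ranks_from_scores(scores: Mapping[str, float]) -> dict[str, int]:
    order = sorted(scores, key=lambda i: (-scores[i], i))
    return {item: r + 1 for r, item in enumerate(order)}


def _held_fold_importance(
    forest, X_held, y_held, item_ids, seed, run_index, n_permutations
) -> dict[str, float]:
    base_acc = float(np.mean(forest.predict(X_held) == y_held))
    scores = {}
    for j, item_id in enumerate(item_ids):
        rng = np.random.default_rng(derive_seed(seed, "perm", run_index, item_id))
        drops = []
        for _ in range(n_permutations):
            Xp = X_held.copy()
            Xp[:, j] = rng.permutation(X_held[:, j])
            drops.append(base_acc - float(np.mean(forest.predict(Xp) == y_held)))
        scores[item_id] = float(np.mean(drops))
    return scores


def _oob_importance(
    forest, X_train, y_train, item_ids, seed, run_index, n_permutations
) -> dict[str, float]:
    """Classic Breiman MDA: per-tree accuracy drop on out-of-bag samples."""
    n = len(y_train)
    rngs = {
        item_id: np.random.default_rng(derive_seed(seed, "perm", run_index, item_id))
        for item_id in item_ids
    }
    sums = {item_id: 0.0 for item_id in item_ids}
    n_used = 0
    pos_idx = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.asarray([pos_idx[v] for v in y_train])
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sample_idx] = False
        if oob.sum() < 2:
            continue
        n_used += 1
        Xo, yo = X_train[oob], y_enc[oob]
        base = float(np.mean(tree.predict(Xo) == yo))
        for j, item_id in enumerate(item_ids):
            rng = rngs[item_id]
            drops = []
            for _ in range(n_permutations):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xo[:, j])
                drops.append(base - float(np.mean(tree.predict(Xp) == yo)))
            sums[item_id] += float(np.mean(drops))
    if n_used == 0:
        raise ValueError("no tree had out-of-bag samples; increase sample size")
    return {item_id: sums[item_id] / n_used for item_id in item_ids}


def run_cv_importance(train: ItemTable, config: ForestConfig) -> list[ImportanceRun]:
    """Train repeated forests under stratified CV and score items by MDA.

    Default interpretation: one n_folds-fold stratified CV; run i trains on
    all folds but fold i and measures permutation importance on fold i (runs
    cycle through folds if n_runs > n_folds). With ``independent_cv_runs``
    each run shuffles its own CV and holds out that CV's first fold.
    """
    X, y, ids = encode_for_forest(train)
    # canonical column order -> column-order-invariant forests
    order = np.argsort(ids)
    sorted_ids = [ids[i] for i in order]
    Xc = X[:, order]

    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < config.n_folds:
        raise ValueError(
            f"need at least n_folds={config.n_folds} subjects per class, "
            f"got counts {class_counts.tolist()}"
        )

    if config.independent_cv_runs:
        fold_for_run = []
        for r in range(config.n_runs):
            skf = StratifiedKFold(
                n_splits=config.n_folds,
                shuffle=True,
                random_state=derive_seed(config.seed, "cv", r),
            )
            fold_for_run.append(next(iter(skf.split(Xc, y))))
    else:
        skf = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=derive_seed(config.seed, "cv"),
        )
        splits = list(skf.split(Xc, y))
        fold_for_run = [splits[r % config.n_folds] for r in range(config.n_runs)]

    runs = []
    for r, (tr_idx, te_idx) in enumerate(fold_for_run):
        if len(np.unique(y[tr_idx])) < 2:
            raise ValueError(f"run {r}: a class is absent from the training portion")
        forest = make_forest(config, derive_seed(config.seed, "forest", r))
        forest.fit(Xc[tr_idx], y[tr_idx])
        if config.importance_source == "held_fold":
            scores = _held_fold_importance(
                forest, Xc[te_idx], y[te_idx], sorted_ids,
                config.seed, r, config.n_permutations,
            )
        else:
            scores = _oob_importance(
                forest, Xc[tr_idx], y[tr_idx], sorted_ids,
                config.seed, r, config.n_permutations,
            )
        runs.append(ImportanceRun(run_index=r, scores=scores,
                                  ranks=_ranks_from_scores(scores)))
    return runs


def aggregate_ranking(runs: Sequence[ImportanceRun]) -> FeatureRanking:
    """Mean rank per item across runs; total deterministic ordering.

    Order: mean rank ascending, ties by mean importance descending, then
    item_id lexicographic.
    """
    if not runs:
        raise ValueError("no importance runs to aggregate")
    item_set = set(runs[0].scores)
    for run in runs[1:]:
        if set(run.scores) != item_set:
            raise ValueError("importance runs cover inconsistent item sets")
    mean_rank = {
        i: float(np.mean([run.ranks[i] for run in runs])) for i in item_set
    }
    mean_imp = {
        i: float(np.mean([run.scores[i] for run in runs])) for i in item_set
    }
    order = sorted(item_set, key=lambda i: (mean_rank[i], -mean_imp[i], i))
    return FeatureRanking(
        item_ids=tuple(order), mean_rank=mean_rank, mean_importance=mean_imp
    )


def write_ranking_tsv(ranking: FeatureRanking, path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
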
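"""Nested reduced-feature models, Youden thresholds, parsimony-weighted selection.

Step 2 of the procedure: given the aggregated importance ranking, train one
model per prefix of the ranking ({1}, {1,2}, ..., {1..n}), score each by
cross-validated out-of-fold AUC, fix its decision threshold at the Youden
optimum (max sensitivity + specificity - 1), and pick the "optimal model" by
the weighted score

    score_k = w1 * scaled_AUC_k + w2 * scaled_complexity_k,

with w1 = 0.35, w2 = 0.65: both AUC and model size are min-max scaled to the
unit interval over the model family, complexity scaled so that FEWER
features means a HIGHER value (the 2:1 weighting deliberately favors simple
models). The threshold chosen here is frozen and reused verbatim when a
model is later evaluated on the validation holdout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._rng import derive_seed
from .item_data import ItemTable
from .metrics import confusion_metrics, roc_auc
from .rf_importance import (
    FeatureRanking,
    ForestConfig,
    encode_for_forest,
    make_forest,
    vote_scores,
)


@dataclass(frozen=True)
class ThresholdResult:
    """Youden-optimal operating point of a score."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class SelectionWeights:
    """Performance/complexity weights of the model-selection score (0.35/0.65)."""

    w1: float = 0.35
    w2: float = 0.65

    def __post_init__(self):
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class ModelRecord:
    """One reduced-feature model: ranking prefix, CV performance, frozen threshold."""

    k: int
    feature_ids: tuple[str, ...]
    auc: float
    threshold_result: ThresholdResult
    acc: float
    sensitivity: float
    specificity: float

    @property
    def threshold(self) -> float:
        return self.threshold_result.threshold


@dataclass(frozen=True)
class ModelScore:
    """Weighted parsimony score of one model within its family."""

    k: int
    scaled_auc: float
    scaled_complexity: float
    score: float


def youden_threshold(scores, labels) -> ThresholdResult:
    """Exhaustive Youden-index threshold search over the ROC curve.

    Candidates are the midpoints between adjacent sorted unique scores plus
    sentinels below/above all scores; the prediction rule is positive when
    score >= threshold. Returns the candidate maximizing J = sensitivity +
    specificity - 1; ties in J are broken toward higher specificity, then
    toward the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("youden_threshold requires both classes present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = (scores[pos][None, :] >= cands[:, None]).mean(axis=1)
    spec = (scores[neg][None, :] < cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = np.lexsort((cands, spec, j))[-1]
    return ThresholdResult(
        threshold=float(cands[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
    )


def train_reduced_models(
    train: ItemTable,
    ranking: FeatureRanking,
    config: ForestConfig,
    ks: Optional[Sequence[int]] = None,
    plain_acc: bool = False,
) -> list[ModelRecord]:
    """Train the nested model family over prefixes of the ranking.

    The k-th model uses exactly the top-k ranked features. AUC and the
    Youden threshold come from pooled out-of-fold scores of a stratified
    ``config.n_folds``-fold CV on the training partition; the same fold
    assignment is shared across all k, so family members are compared on
    identical resampling. ``ks`` restricts which prefix sizes are built
    (default: all of 1..n). ``acc`` is balanced accuracy unless
    ``plain_acc`` is set.
    """
    if not ranking.item_ids:
        raise ValueError("empty ranking")
    if set(ranking.item_ids) != set(train.item_ids):
        raise ValueError("ranking must cover exactly the table's items")
    X, y, ids = encode_for_forest(train)
    col = {item_id: i for i, item_id in enumerate(ids)}
    n = len(ranking.item_ids)
    if ks is None:
        ks = range(1, n + 1)
    ks = sorted(set(int(k) for k in ks))
    if ks and (ks[0] < 1 or ks[-1] > n):
        raise ValueError(f"ks must lie in 1..{n}")

    skf = StratifiedKFold(
        n_splits=config.n_folds,
        shuffle=True,
        random_state=derive_seed(config.seed, "nested-cv"),
    )
    splits = list(skf.split(X, y))

    records = []
    for k in ks:
        feats = ranking.item_ids[:k]
        cidx = [col[f] for f in feats]
        oof = np.empty(len(y), dtype=float)
        for f, (tr_idx, te_idx) in enumerate(splits):
            forest = make_forest(config, derive_seed(config.seed, "nested", k, f))
            forest.fit(X[np.ix_(tr_idx, cidx)], y[tr_idx])
            oof[te_idx] = vote_scores(forest, X[np.ix_(te_idx, cidx)])
        auc = roc_auc(oof, y)
        thr = youden_threshold(oof, y)
        preds = oof >= thr.threshold
        cm = confusion_metrics(preds, y)
        acc = cm.accuracy if plain_acc else cm.balanced_accuracy
        records.append(
            ModelRecord(
                k=k,
                feature_ids=tuple(feats),
                auc=float(auc),
                threshold_result=thr,
                acc=float(acc),
                sensitivity=float(cm.sensitivity),
                specificity=float(cm.specificity),
            )
        )
    return records


def weighted_scores(
    records: Sequence[ModelRecord], weights: SelectionWeights = SelectionWeights()
) -> list[ModelScore]:
    """Min-max scale AUC and complexity over the family and combine.

    scaled_auc = (auc - min) / (max - min), with the degenerate all-equal
    family mapping to 1 for every model; scaled_complexity = 1 at the
    smallest k and 0 at the largest, so simpler models score higher.
    """
    if not records:
        raise ValueError("empty model family")
    aucs = np.array([r.auc for r in records], dtype=float)
    ks = np.array([r.k for r in records], dtype=float)
    if aucs.max() > aucs.min():
        a_scaled = (aucs - aucs.min()) / (aucs.max() - aucs.min())
    else:
        a_scaled = np.ones_like(aucs)
    if ks.max() > ks.min():
        c_scaled = 1.0 - (ks - ks.min()) / (ks.max() - ks.min())
    else:
        c_scaled = np.ones_like(ks)
    return [
        ModelScore(
            k=r.k,
            scaled_auc=float(a),
            scaled_complexity=float(c),
            score=float(weights.w1 * a + weights.w2 * c),
        )
        for r, a, c in zip(records, a_scaled, c_scaled)
    ]


def optimal_model(
    records: Sequence[ModelRecord], weights: SelectionWeights = SelectionWeights()
) -> tuple[ModelRecord, list[ModelScore]]:
    """The family member maximizing the weighted score; ties go to smaller k."""
    scores = weighted_scores(records, weights)
    best = max(range(len(scores)), key=lambda i: (scores[i].score, -scores[i].k))
    return records[best], scores


def model_family_frame(records: Sequence[ModelRecord]):
    """Family summary table (one row per k): AUC/ACC/sens/spec/J on CV folds."""
    import pandas as pd

    return pd.DataFrame(
        {
            "n_features": [r.k for r in records],
            "auc_test": [r.auc for r in records],
            "acc_test": [r.acc for r in records],
            "sens_test": [r.sensitivity for r in records],
            "spec_test": [r.specificity for r in records],
            "youden_j": [r.threshold_result.youden_j for r in records],
            "threshold": [r.threshold for r in records],
        }
    )
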
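"""Validation-set evaluation and McNemar-based minimal-model search.

Steps 3-4 of the procedure: each reduced-feature model is retrained on the
full training partition, scored on the held-out validation set at its frozen
training threshold, and compared against the full-feature model with the
McNemar test on paired per-subject correctness:

    b = subjects the reduced model gets right and the full model wrong,
    c = subjects the full model gets right and the reduced model wrong,
    chi2 = (b - c)^2 / (b + c),  p = upper tail of chi2(1 df).

No continuity correction is applied (the uncorrected statistic is what the
reference chi-square/p anchor pairs reproduce). The "minimal model" is the
smallest prefix whose validation errors do not differ significantly from
the full model (p > alpha, scanning k upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from ._rng import derive_seed
from .item_data import ItemTable
from .metrics import confusion_metrics, roc_auc
from .nested_models import ModelRecord
from .rf_importance import ForestConfig, encode_for_forest, make_forest, vote_scores


@dataclass(frozen=True)
class PerformanceReport:
    """A model's performance on the validation holdout at its frozen threshold."""

    auc: float
    acc: float  # balanced accuracy by default
    sensitivity: float
    specificity: float
    n_subjects: int
    threshold: float


@dataclass(frozen=True)
class McNemarResult:
    """Uncorrected McNemar test on paired correctness vectors."""

    b: int
    c: int
    chi2: float
    p: float
    df: int = 1


@dataclass
class SelectionResult:
    """Minimal- and optimal-model identities with per-k McNemar comparisons."""

    optimal_k: Optional[int]
    minimal_k: int
    comparisons: list[tuple[int, McNemarResult]] = field(default_factory=list)
    alpha: float = 0.05
    #: True when no k < full passed, so the full model is its own minimal model
    minimal_is_full: bool = False

    def comparison_for(self, k: int) -> McNemarResult:
        for kk, res in self.comparisons:
            if kk == k:
                return res
        raise KeyError(k)

    def to_dict(self) -> dict:
        return {
            "optimal_k": self.optimal_k,
            "minimal_k": self.minimal_k,
            "alpha": self.alpha,
            "minimal_is_full": self.minimal_is_full,
            "per_k": [
                {"k": k, "b": r.b, "c": r.c, "chi2": round(r.chi2, 6),
                 "p": round(r.p, 6)}
                for k, r in self.comparisons
            ],
        }


def mcnemar_p_from_chi2(chi2: float) -> float:
    """Upper-tail probability of the chi-square statistic at 1 df."""
    return float(chi2_dist.sf(chi2, 1))


def mcnemar_test(correct_a, correct_b) -> McNemarResult:
    """Uncorrected McNemar test from paired per-subject correctness.

    ``b`` counts subjects only classifier A gets right, ``c`` those only B
    gets right. With no discordant pairs (b + c = 0) the classifiers are
    indistinguishable: chi2 = 0, p = 1 by convention.
    """
    a = np.asarray(correct_a).astype(bool)
    bvec = np.asarray(correct_b).astype(bool)
    if a.shape != bvec.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~bvec))
    c = int(np.sum(~a & bvec))
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, p=1.0)
    chi2 = (b - c) ** 2 / (b + c)
    return McNemarResult(b=b, c=c, chi2=float(chi2), p=mcnemar_p_from_chi2(chi2))


def _check_disjoint(train: ItemTable, validation: ItemTable) -> None:
    overlap = set(train.subjects) & set(validation.subjects)
    if overlap:
        warnings.warn(
            f"validation set shares {len(overlap)} subjects with the training "
            "partition; performance estimates will be optimistic",
            UserWarning,
            stacklevel=3,
        )


def validation_scores(
    records: Sequence[ModelRecord],
    train: ItemTable,
    validation: ItemTable,
    config: ForestConfig,
) -> dict[int, np.ndarray]:
    """Retrain each family member on the full training partition and score
    the validation subjects. Returns per-k positive-class vote fractions."""
    _check_disjoint(train, validation)
    X_tr, y_tr, ids_tr = encode_for_forest(train)
    X_va, _, ids_va = encode_for_forest(validation)
    col_tr = {item_id: i for i, item_id in enumerate(ids_tr)}
    col_va = {item_id: i for i, item_id in enumerate(ids_va)}
    out: dict[int, np.ndarray] = {}
    for record in records:
        missing = [f for f in record.feature_ids if f not in col_va]
        if missing:
            raise ValueError(f"validation table lacks feature columns {missing}")
        ct = [col_tr[f] for f in record.feature_ids]
        cv = [col_va[f] for f in record.feature_ids]
        forest = make_forest(config, derive_seed(config.seed, "final", record.k))
        forest.fit(X_tr[:, ct], y_tr)
        out[record.k] = vote_scores(forest, X_va[:, cv])
    return out


def evaluate_on_validation(
    record: ModelRecord,
    train: ItemTable,
    validation: ItemTable,
    config: ForestConfig,
    plain_acc: bool = False,
) -> PerformanceReport:
    """Blind performance of one model at its frozen training threshold."""
    scores = validation_scores([record], train, validation, config)[record.k]
    y = validation.labels.to_numpy(dtype=int)
    preds = scores >= record.threshold
    cm = confusion_metrics(preds, y)
    return PerformanceReport(
        auc=float(roc_auc(scores, y)),
        acc=float(cm.accuracy if plain_acc else cm.balanced_accuracy),
        sensitivity=float(cm.sensitivity),
        specificity=float(cm.specificity),
        n_subjects=validation.n_subjects,
        threshold=record.threshold,
    )


def find_minimal_model(
    records: Sequence[ModelRecord],
    train: ItemTable,
    validation: ItemTable,
    config: ForestConfig,
    alpha: float = 0.05,
    optimal_k: Optional[int] = None,
    scores: Optional[dict[int, np.ndarray]] = None,
) -> SelectionResult:
    """Scan k upward for the smallest model statistically equal to the full one.

    Every family member is compared to the largest-k (full) model via
    McNemar on validation correctness; minimal_k is the smallest k with
    p > alpha. If no reduced model passes, minimal_k is the full model's k
    and ``minimal_is_full`` is set. Precomputed ``scores`` (from
    :func:`validation_scores`) may be passed to avoid retraining.
    """
    records = sorted(records, key=lambda r: r.k)
    if not records:
        raise ValueError("empty model family")
    full = records[-1]
    if scores is None:
        scores = validation_scores(records, train, validation, config)
    y = validation.labels.to_numpy(dtype=int)
    correct = {
        r.k: (scores[r.k] >= r.threshold) == (y == 1) for r in records
    }
    comparisons = [
        (r.k, mcnemar_test(correct[r.k], correct[full.k])) for r in records
    ]
    minimal_k = full.k
    minimal_is_full = True
    for k, res in comparisons:
        if k == full.k:
            continue
        if res.p > alpha:
            minimal_k = k
            minimal_is_full = False
            break
    return SelectionResult(
        optimal_k=optimal_k,
        minimal_k=minimal_k,
        comparisons=comparisons,
        alpha=alpha,
        minimal_is_full=minimal_is_full,
    )
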
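"""Shared statistical primitives: confusion metrics, ROC/AUC, summary-statistic t-tests.

These are the building blocks the rest of the pipeline reports with: the AUC
is the Mann-Whitney probability that a randomly chosen positive (ASD) subject
scores above a randomly chosen negative one; sensitivity always refers to
detection of the positive (ASD) class; "balanced accuracy" is the mean of
sensitivity and specificity, robust to the ~46/54 class split.

The two-sample t machinery works from published summary statistics
(n, mean, SD per group) so that printed cohort tables can be recomputed
without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a binary classifier's outcomes (positive class = ASD)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


@dataclass(frozen=True)
class SummaryGroup:
    """One group's published summary statistics: size, mean, SD."""

    n: int
    m: float
    s: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.s < 0:
            raise ValueError(f"SD must be non-negative, got {self.s}")


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test computed from summary statistics.

    Sign convention: t = (m2 - m1) / SE with group 1 listed first, so t is
    negative when group 1 (conventionally the ASD group) has the higher mean.
    Cohen's d is reported as a magnitude, |m1 - m2| / pooled SD.
    """

    t: float
    df: float
    p: float
    pooled_sd: float
    d: float


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(score_pos > score_neg) + 0.5 * P(tie); exact under ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    n1 = int(pos.sum())
    n0 = int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_metrics(predictions, labels) -> ConfusionCounts:
    """Tabulate predicted vs true binary labels (1 = positive/ASD)."""
    predictions = np.asarray(predictions).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum(predictions & labels))
    fn = int(np.sum(~predictions & labels))
    tn = int(np.sum(~predictions & ~labels))
    fp = int(np.sum(predictions & ~labels))
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def pooled_t_from_summary(
    g1: SummaryGroup, g2: SummaryGroup, welch: bool = False
) -> TTestResult:
    """Two-sample t-test and Cohen's d from (n, mean, SD) summaries.

    Default is the pooled-variance Student t with df = n1 + n2 - 2; set
    ``welch=True`` for the unequal-variance Welch t with Satterthwaite df.
    Cohen's d always uses the pooled SD, the conventional effect-size
    denominator for two-group comparisons.
    """
    n1, m1, s1 = g1.n, g1.m, g1.s
    n2, m2, s2 = g2.n, g2.m, g2.s
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    sp = float(np.sqrt(sp2))
    if welch:
        v1 = s1**2 / n1
        v2 = s2**2 / n2
        se = float(np.sqrt(v1 + v2))
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        se = sp * float(np.sqrt(1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    if se == 0:
        t = 0.0
    else:
        t = (m2 - m1) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = abs(m1 - m2) / sp if sp > 0 else 0.0
    return TTestResult(t=float(t), df=float(df), p=p, pooled_sd=sp, d=float(d))
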
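"""Classifier performance machinery.

Confusion counts, the six binary-classification statistics (sensitivity,
specificity, precision, accuracy, F1, Matthews correlation coefficient),
ROC analysis with trapezoidal AUC, a two-tailed Mann–Whitney U test (exact
by enumeration for small samples, normal approximation with tie and
continuity corrections otherwise), and the stratified split used to divide
a labeled dataset into equal training and testing halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateEvaluationError, ParameterError, SplitError
from .sequence_io import NEGATIVE, POSITIVE, LabeledDataset

# combined sample size up to which the Mann-Whitney p-value is computed by
# exhaustive enumeration of group assignments
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.total < 1:
            raise ParameterError("confusion counts must sum to at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six performance statistics.

    A metric whose defining formula has a zero denominator is reported as
    ``None`` (undefined) rather than 0 or an error.
    """

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None
    mcc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC points (FPR, TPR) and trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float


@dataclass(frozen=True)
class MWTestResult:
    u: float
    p_two_tailed: float
    method: str  # "exact" | "normal-approximation"


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Tabulate TP/FP/TN/FN; positive class = recruited to stress granules."""
    if len(truth) != len(predicted):
        raise ParameterError(
            f"truth has {len(truth)} entries, predicted has {len(predicted)}"
        )
    if len(truth) == 0:
        raise ParameterError("cannot tabulate an empty prediction set")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The six statistics from their standard defining formulas.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); accuracy = (TP+TN)/total;
    F1 = TP/(TP + (FP+FN)/2);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return MetricsReport(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, counts.total),
        f1=_ratio(tp, tp + 0.5 * (fp + fn)),
        mcc=None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
    )


def roc_curve(scores: Sequence[float], truth: Sequence[str]) -> ROCCurve:
    """ROC by sweeping the decision threshold over the unique scores.

    Thresholds are taken in descending order; a group of tied scores moves
    the curve in a single step. The curve starts at (0, 0) and ends at
    (1, 1); AUC is computed by trapezoidal integration.
    """
    if len(scores) != len(truth):
        raise ParameterError("scores and truth must have equal length")
    y = np.array([1 if t == POSITIVE else 0 for t in truth])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateEvaluationError("ROC requires both classes in the truth")

    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    step_ends = np.r_[np.nonzero(distinct)[0][1:] - 1, len(s_sorted) - 1]
    tp_cum = np.cumsum(y_sorted)[step_ends]
    fp_cum = np.cumsum(1 - y_sorted)[step_ends]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s_sorted[step_ends]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        fpr=tuple(fpr.tolist()),
        tpr=tuple(tpr.tolist()),
        thresholds=tuple(thresholds.tolist()),
        auc=auc,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midrank sums: U = R1 - n1(n1+1)/2."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_two_tailed(
    x: Sequence[float], y: Sequence[float]
) -> MWTestResult:
    """Two-tailed Mann–Whitney U test.

    For combined sample sizes up to 12 the p-value is exact: every
    assignment of the pooled observations into groups of sizes (n1, n2) is
    enumerated and the two-tailed p is the fraction of assignments whose U
    deviates from the null mean n1*n2/2 at least as much as the observed
    one (ties handled by midranks, so the enumeration is valid with ties).
    For larger samples the normal approximation with tie correction and a
    0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ParameterError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mean_u = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs_dev = abs(u - mean_u)
        count = 0
        total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if abs(u_perm - mean_u) >= obs_dev - 1e-12:
                count += 1
            total += 1
        return MWTestResult(u=u, p_two_tailed=count / total, method="exact")

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        # all observations identical: no evidence against the null
        return MWTestResult(u=u, p_two_tailed=1.0, method="normal-approximation")
    z = (abs(u - mean_u) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return MWTestResult(u=u, p_two_tailed=p, method="normal-approximation")


def stratified_split(
    dataset: LabeledDataset, fraction: float = 0.5, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random split into training and testing subsets.

    Each class contributes ``round_half_up(fraction * class_size)`` members
    to the training half; the remainder forms the testing half. The two
    halves are disjoint and their union is the dataset. Deterministic for a
    fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (POSITIVE, NEGATIVE):
        idx = [i for i, lab in enumerate(dataset.labels) if lab == cls]
        if not idx:
            raise SplitError(f"class {cls!r} has no members")
        n_train = int(math.floor(fraction * len(idx) + 0.5))
        if n_train == 0 or n_train == len(idx):
            raise SplitError(
                f"class {cls!r} with {len(idx)} members cannot be split at "
                f"fraction {fraction} into two non-empty halves"
            )
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[i] for i in perm[:n_train])
        test_idx.extend(idx[i] for i in perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return dataset.subset(train_idx), dataset.subset(test_idx)


def evaluate_predictor(
    bundle, test: LabeledDataset
) -> tuple[ConfusionCounts, MetricsReport, ROCCurve]:
    """Score a predictor bundle on a labeled test set.

    Classifies every record, tabulates the confusion counts and the six
    statistics, and builds the ROC from the raw network scores.
    """
    predicted: list[str] = []
    scores: list[float] = []
    for rec in test.records:
        _, label, score = bundle.predict_record(rec)
        predicted.append(label)
        scores.append(score)
    counts = confusion(test.labels, predicted)
    return counts, metrics(counts), roc_curve(scores, test.labels)
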
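"""Multilabel discrimination metrics and resampling procedures.

Implements the evaluation protocol used for multilabel ECG classifiers:
rank-based AUROC and step-integrated AUPRC per label, an overall
(micro / concatenated) AUROC across all (record, label) cells,
subsample bootstrap confidence intervals (70% of records, 1000
iterations by default), the DeLong test for comparing correlated AUROCs,
and per-label decision thresholds chosen to maximize the mean of
sensitivity and specificity on a training set and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PredictionSet",
    "MetricEstimate",
    "ConfusionRates",
    "auroc",
    "auprc",
    "overall_auroc",
    "bootstrap_metric",
    "delong_test",
    "select_thresholds",
    "apply_thresholds",
    "confusion_rates",
]


@dataclass
class PredictionSet:
    """Scores, binary ground truth and group attributes for n records × L labels.

    ``scores`` are probabilities in [0, 1]; ``labels`` are {0, 1}. ``age``
    (years) and ``sex`` (categorical) are optional per-record attributes
    used by the fairness audit.
    """

    scores: np.ndarray
    labels: np.ndarray
    record_ids: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)
    age: np.ndarray | None = None
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.labels = np.atleast_2d(np.asarray(self.labels))
        if self.scores.shape != self.labels.shape:
            raise ValueError(
                f"scores shape {self.scores.shape} != labels shape {self.labels.shape}"
            )
        if np.any((self.scores < 0) | (self.scores > 1)):
            r, c = np.argwhere((self.scores < 0) | (self.scores > 1))[0]
            raise ValueError(
                f"score outside [0, 1] at record {r}, label column {c}: "
                f"{self.scores[r, c]}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.labels = self.labels.astype(np.int8)
        n, L = self.scores.shape
        if not self.record_ids:
            self.record_ids = [f"rec{i}" for i in range(n)]
        if len(self.record_ids) != n:
            raise ValueError(f"{len(self.record_ids)} record ids for {n} records")
        if not self.label_names:
            self.label_names = [f"label{j}" for j in range(L)]
        if len(self.label_names) != L:
            raise ValueError(f"{len(self.label_names)} label names for {L} labels")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (n,):
                raise ValueError("age must have one entry per record")
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
            if self.sex.shape != (n,):
                raise ValueError("sex must have one entry per record")

    @property
    def n_records(self) -> int:
        return self.scores.shape[0]

    @property
    def n_labels(self) -> int:
        return self.scores.shape[1]

    def subset(self, idx: np.ndarray) -> "PredictionSet":
        """Row (record-level) subset; keeps label structure intact."""
        idx = np.asarray(idx)
        return PredictionSet(
            scores=self.scores[idx],
            labels=self.labels[idx],
            record_ids=[self.record_ids[i] for i in idx],
            label_names=list(self.label_names),
            age=None if self.age is None else self.age[idx],
            sex=None if self.sex is None else self.sex[idx],
        )


@dataclass
class MetricEstimate:
    """Point estimate with a percentile bootstrap 95% CI."""

    point: float
    ci_low: float
    ci_high: float
    n_iterations: int
    sample_fraction: float
    seed: int
    n_redrawn: int = 0


class ConfusionRates(NamedTuple):
    tpr: float  # sensitivity; NaN when no positives
    fpr: float  # NaN when no negatives
    specificity: float


def _check_binary(labels: np.ndarray, name: str = "labels") -> np.ndarray:
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    if uniq.size < 2:
        raise ValueError(
            f"degenerate {name}: only class {uniq[0]} present; AUROC undefined"
        )
    return labels.astype(np.int8)


def auroc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney); ties receive 0.5 credit.

    Equals the probability that a random positive outranks a random
    negative, counting exact ties as half.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.shape != labels.shape:
        raise ValueError("labels and scores must have equal length")
    ranks = stats.rankdata(scores)  # average ranks -> tie credit 0.5
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Area under the precision-recall curve by step integration.

    Sum over descending-score thresholds of precision × recall increment
    (the average-precision estimator, no interpolation).
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at distinct-threshold boundaries
    last_of_run = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last_of_run], fp[last_of_run]
    precision = tp / (tp + fp)
    recall = tp / tp[-1]
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def overall_auroc(predset: PredictionSet) -> float:
    """Micro AUROC over all (record, label) cells concatenated into one vector."""
    labels = predset.labels.ravel()
    if labels.min() == labels.max():
        raise ValueError("all label columns degenerate; overall AUROC undefined")
    return auroc(labels, predset.scores.ravel())


def bootstrap_metric(
    predset: PredictionSet,
    metric: Callable[[PredictionSet], float],
    fraction: float = 0.7,
    iterations: int = 1000,
    seed: int = 0,
    replace: bool = False,
    max_retries: int = 10,
) -> MetricEstimate:
    """Record-level resampling CI for an arbitrary metric of a PredictionSet.

    Each iteration draws ``floor(fraction * n)`` records — without
    replacement by default (subsampling), with replacement when
    ``replace=True`` — and recomputes ``metric``. The CI is the empirical
    2.5/97.5 percentile band. Iterations on which the metric is undefined
    (e.g. a degenerate label column) are redrawn up to ``max_retries``
    times so the iteration count stays exact.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = predset.n_records
    m = max(1, int(np.floor(fraction * n)))
    rng = np.random.default_rng(seed)
    point = metric(predset)
    values = np.empty(iterations)
    n_redrawn = 0
    for i in range(iterations):
        for attempt in range(max_retries + 1):
            idx = rng.choice(n, size=m, replace=replace)
            try:
                values[i] = metric(predset.subset(idx))
                break
            except ValueError:
                n_redrawn += 1
                if attempt == max_retries:
                    raise ValueError(
                        f"bootstrap iteration {i} degenerate after "
                        f"{max_retries} redraws"
                    )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return MetricEstimate(
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=iterations,
        sample_fraction=fraction,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _delong_structural_components(labels: np.ndarray, scores: np.ndarray):
    """Midrank structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_s = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_s)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    a = float((rank_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return a, v10, v01


def delong_test(
    labels: Sequence[int] | np.ndarray,
    scores_a: Sequence[float] | np.ndarray,
    scores_b: Sequence[float] | np.ndarray,
) -> tuple[float, float, float]:
    """DeLong test for two correlated AUROCs on the same records.

    Returns ``(auroc_a, auroc_b, p)`` with a two-sided p-value from the
    normal approximation using the DeLong covariance of the paired AUROC
    estimates. When the two score vectors give a zero-variance AUROC
    difference (e.g. identical scores), p = 1.0 is returned.
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float).ravel()
    scores_b = np.asarray(scores_b, dtype=float).ravel()
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores must be paired with labels (equal length)")
    auc_a, v10_a, v01_a = _delong_structural_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_structural_components(labels, scores_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= np.finfo(float).eps:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(p)


def _balanced_accuracy_curve(labels: np.ndarray, scores: np.ndarray):
    """(sens + spec)/2 at every candidate threshold = each unique score.

    Decision rule: predict positive when score >= threshold. Returns the
    sorted unique scores and the balanced accuracy of thresholding at each.
    """
    uniq = np.unique(scores)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # counts of positives/negatives at each unique score
    idx = np.searchsorted(uniq, scores)
    pos_at = np.bincount(idx, weights=labels, minlength=uniq.size)
    neg_at = np.bincount(idx, weights=1 - labels, minlength=uniq.size)
    # predicting >= uniq[k]: TP = positives with score >= uniq[k]
    tp = n_pos - np.cumsum(pos_at) + pos_at
    fp = n_neg - np.cumsum(neg_at) + neg_at
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    return uniq, (sens + spec) / 2


def select_thresholds(train_predset: PredictionSet) -> dict[str, float]:
    """Per-label threshold maximizing (sensitivity + specificity) / 2.

    Candidate thresholds are the sorted unique scores of the label column;
    when several candidates tie, the lowest optimal candidate is taken and
    the returned threshold is the midpoint of the half-open interval
    (previous unique score, optimal candidate] — deterministic and
    symmetric. Labels with a single class get no threshold (reported as
    NaN). Thresholds are meant to be frozen and reapplied to other sets.
    """
    out: dict[str, float] = {}
    for j, name in enumerate(train_predset.label_names):
        y = train_predset.labels[:, j].astype(float)
        s = train_predset.scores[:, j]
        if y.min() == y.max():
            out[name] = float("nan")
            continue
        uniq, bacc = _balanced_accuracy_curve(y, s)
        k = int(np.argmax(bacc))  # argmax returns the lowest optimal index
        if k == 0:
            out[name] = float(uniq[0])
        else:
            out[name] = float((uniq[k - 1] + uniq[k]) / 2)
    return out


def apply_thresholds(
    predset: PredictionSet, thresholds: dict[str, float] | Sequence[float]
) -> np.ndarray:
    """Binarize scores with frozen per-label thresholds (score >= t)."""
    if isinstance(thresholds, dict):
        try:
            thr = np.array([thresholds[n] for n in predset.label_names], float)
        except KeyError as e:
            raise ValueError(f"no threshold for label {e.args[0]!r}") from e
    else:
        thr = np.asarray(thresholds, dtype=float)
        if thr.shape != (predset.n_labels,):
            raise ValueError("one threshold per label required")
    if np.isnan(thr).any():
        missing = [n for n, t in zip(predset.label_names, thr) if np.isnan(t)]
        raise ValueError(f"undefined thresholds for labels: {missing}")
    return (predset.scores >= thr[None, :]).astype(np.int8)


def confusion_rates(
    labels: Sequence[int] | np.ndarray, binary_preds: Sequence[int] | np.ndarray
) -> ConfusionRates:
    """TPR (sensitivity), FPR and specificity from binary predictions.

    Zero-denominator rates come back as NaN rather than raising.
    """
    y = np.asarray(labels).ravel()
    p = np.asarray(binary_preds).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(np.unique(y), (0, 1)).all() and np.isin(np.unique(p), (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tpr = tp / n_pos if n_pos else float("nan")
    fpr = fp / n_neg if n_neg else float("nan")
    spec = 1.0 - fpr if n_neg else float("nan")
    return ConfusionRates(tpr=tpr, fpr=fpr, specificity=spec)
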
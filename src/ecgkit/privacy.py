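"""Membership-inference auditing of model output logits.

A membership-inference attack (MIA) asks whether an adversary who sees a
model's per-record outputs can tell training records from held-out
records. The audit merges the two logit sets with membership labels,
trains a 50-tree random forest on an 80/20 stratified split, and scores
the attack by AUROC on the held-out 20%; an AUROC near 0.5 means the
model's outputs leak no membership signal. The protocol is repeated over
a predefined seed list to get a CI and averaged impurity-based feature
importances, and a t-SNE embedding (perplexity 30, up to 10,000 samples
per set) visualizes how separable the two output distributions are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import train_test_split

__all__ = ["AttackReport", "mia_single", "mia_repeated", "tsne_separation"]

DEFAULT_SEEDS = tuple(range(10))


@dataclass
class AttackReport:
    """Repeated-MIA result: per-seed AUROCs, their mean/CI, importances."""

    per_repeat_auroc: list[float]
    mean_auroc: float
    ci_low: float
    ci_high: float
    feature_importances: np.ndarray
    split_fraction: float
    n_trees: int
    seeds: list[int] = field(default_factory=list)


def _validate_sets(train_logits, heldout_logits):
    a = np.atleast_2d(np.asarray(train_logits, dtype=float))
    b = np.atleast_2d(np.asarray(heldout_logits, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    if a.shape[0] < 10 or b.shape[0] < 10:
        raise ValueError("each logit set needs at least 10 rows")
    return a, b


def mia_single(
    train_logits: np.ndarray,
    heldout_logits: np.ndarray,
    n_trees: int = 50,
    split: float = 0.8,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """One membership-inference attack run: (attack AUROC, importances).

    The larger set is subsampled to the smaller so membership classes
    are balanced and AUROC 0.5 is the exact null. Rows are labeled by
    membership, merged, split ``split``/(1-split) stratified, and a
    random forest with ``n_trees`` trees is fit on the training part and
    scored on the rest. Importances are the forest's impurity-based
    importances (non-negative, summing to 1).
    """
    a, b = _validate_sets(train_logits, heldout_logits)
    rng = np.random.default_rng(seed)
    m = min(a.shape[0], b.shape[0])
    if a.shape[0] > m:
        a = a[rng.choice(a.shape[0], size=m, replace=False)]
    if b.shape[0] > m:
        b = b[rng.choice(b.shape[0], size=m, replace=False)]
    X = np.vstack([a, b])
    y = np.r_[np.ones(m, dtype=int), np.zeros(m, dtype=int)]
    X_fit, X_eval, y_fit, y_eval = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed % (2**32)
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed % (2**32), n_jobs=1
    )
    forest.fit(X_fit, y_fit)
    scores = forest.predict_proba(X_eval)[:, 1]
    return float(roc_auc_score(y_eval, scores)), forest.feature_importances_


def mia_repeated(
    train_logits: np.ndarray,
    heldout_logits: np.ndarray,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    n_trees: int = 50,
    split: float = 0.8,
) -> AttackReport:
    """Repeat the attack over a predefined seed list and aggregate.

    Reports the mean attack AUROC with a percentile 95% CI over repeats
    and the elementwise average of the per-repeat feature importances.
    """
    if len(seeds) < 2:
        raise ValueError("at least two seeds required for a CI")
    aurocs: list[float] = []
    importances: list[np.ndarray] = []
    for s in seeds:
        auc, imp = mia_single(
            train_logits, heldout_logits, n_trees=n_trees, split=split, seed=s
        )
        aurocs.append(auc)
        importances.append(imp)
    lo, hi = np.percentile(aurocs, [2.5, 97.5])
    return AttackReport(
        per_repeat_auroc=aurocs,
        mean_auroc=float(np.mean(aurocs)),
        ci_low=float(lo),
        ci_high=float(hi),
        feature_importances=np.mean(importances, axis=0),
        split_fraction=split,
        n_trees=n_trees,
        seeds=list(seeds),
    )


def tsne_separation(
    train_logits: np.ndarray,
    heldout_logits: np.ndarray,
    sample_per_set: int = 10000,
    perplexity: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint 2-D t-SNE embedding of the two logit sets + separation score.

    Returns ``(coords, membership, score)``: the embedded coordinates of
    up to ``sample_per_set`` rows per set, a 0/1 membership tag per row,
    and the silhouette of the membership tags on the 2-D coordinates —
    a diagnostic score near 0 for overlapping distributions and
    approaching 1 for cleanly separated clusters. (The silhouette score
    is this package's quantification; the embedding itself is the
    standard visualization.)
    """
    a, b = _validate_sets(train_logits, heldout_logits)
    rng = np.random.default_rng(seed)
    if a.shape[0] > sample_per_set:
        a = a[rng.choice(a.shape[0], size=sample_per_set, replace=False)]
    if b.shape[0] > sample_per_set:
        b = b[rng.choice(b.shape[0], size=sample_per_set, replace=False)]
    X = np.vstack([a, b])
    membership = np.r_[np.ones(a.shape[0], dtype=int), np.zeros(b.shape[0], dtype=int)]
    if perplexity >= X.shape[0]:
        raise ValueError(
            f"perplexity {perplexity} must be below the combined sample "
            f"size {X.shape[0]}"
        )
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed % (2**32),
    ).fit_transform(X)
    score = float(silhouette_score(coords, membership))
    return coords, membership, score
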
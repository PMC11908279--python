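"""Equalized-odds disparity auditing across age and sex groups.

Under equalized odds a classifier is fair when its true-positive rate
(TPR) and false-positive rate (FPR) are equal across protected groups.
The audit bins age into under-55 / 55-75 / over-75 (or groups records by
sex), pools all (record, label) decisions within each group
(micro-averaging) at frozen per-label thresholds, and reports the mean
absolute pairwise disparity in TPR and FPR with a subsampling bootstrap
CI: 1000 iterations, each on a random 70% of records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import PredictionSet, apply_thresholds

__all__ = [
    "FairnessReport",
    "AGE_GROUPS",
    "assign_age_group",
    "group_rates",
    "disparity_bootstrap",
]

AGE_GROUPS = ("under_55", "55_75", "over_75")


@dataclass
class FairnessReport:
    """Equalized-odds audit result: mean |TPR/FPR| disparity with 95% CIs."""

    grouping: str
    groups: list[str]
    mean_abs_tpr_disparity: float
    tpr_ci: tuple[float, float]
    mean_abs_fpr_disparity: float
    fpr_ci: tuple[float, float]
    iterations: int
    fraction: float
    seed: int
    n_redrawn: int = 0


def assign_age_group(age: float) -> str:
    """Map an age in years onto the three audit bins.

    Boundaries are inclusive for the middle bin: 55.0 and 75.0 both fall
    in "55_75"; anything strictly below 55 is "under_55", strictly above
    75 is "over_75".
    """
    if not np.isfinite(age) or age < 0:
        raise ValueError(f"age must be a non-negative number, got {age}")
    if age < 55:
        return AGE_GROUPS[0]
    if age <= 75:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def _group_assignment(predset: PredictionSet, grouping: str) -> np.ndarray:
    if grouping == "age":
        if predset.age is None:
            raise ValueError("prediction set has no age attribute")
        return np.array([assign_age_group(a) for a in predset.age], dtype=object)
    if grouping == "sex":
        if predset.sex is None:
            raise ValueError("prediction set has no sex attribute")
        return np.asarray(predset.sex, dtype=object)
    raise ValueError(f"grouping must be 'age' or 'sex', got {grouping!r}")


def _per_record_counts(predset: PredictionSet, thresholds):
    """Per-record TP / positive / FP / negative cell counts at frozen thresholds."""
    preds = apply_thresholds(predset, thresholds)
    y = predset.labels
    tp = ((y == 1) & (preds == 1)).sum(axis=1).astype(float)
    pos = (y == 1).sum(axis=1).astype(float)
    fp = ((y == 0) & (preds == 1)).sum(axis=1).astype(float)
    neg = (y == 0).sum(axis=1).astype(float)
    return tp, pos, fp, neg


def group_rates(
    predset: PredictionSet, thresholds, grouping: str = "sex"
) -> dict[str, tuple[float, float]]:
    """Micro-averaged (TPR, FPR) per demographic group.

    All (record, label) cells of a group are pooled before the rates are
    computed. Groups with no positive (or no negative) cells get NaN for
    the affected rate. Empty groups cannot occur (only observed group
    values are reported).
    """
    assignment = _group_assignment(predset, grouping)
    tp, pos, fp, neg = _per_record_counts(predset, thresholds)
    out: dict[str, tuple[float, float]] = {}
    for g in sorted(set(assignment), key=str):
        mask = assignment == g
        gpos, gneg = pos[mask].sum(), neg[mask].sum()
        tpr = tp[mask].sum() / gpos if gpos else float("nan")
        fpr = fp[mask].sum() / gneg if gneg else float("nan")
        out[str(g)] = (tpr, fpr)
    return out


def _mean_abs_pairwise(rates: np.ndarray) -> float:
    """Mean |difference| over all unordered group pairs (2 groups: |a - b|)."""
    k = rates.size
    diffs = [abs(rates[i] - rates[j]) for i in range(k) for j in range(i + 1, k)]
    return float(np.mean(diffs))


def disparity_bootstrap(
    predset: PredictionSet,
    thresholds,
    grouping: str = "sex",
    fraction: float = 0.7,
    iterations: int = 1000,
    seed: int = 0,
    max_retries: int = 10,
) -> FairnessReport:
    """Bootstrap the mean absolute TPR/FPR disparity between groups.

    Each iteration subsamples ``fraction`` of the records without
    replacement, recomputes the pooled per-group rates and takes the mean
    absolute pairwise disparity; the report carries the mean and the
    percentile 95% CI over iterations. Iterations in which a group loses
    all its members (or all positives/negatives) are redrawn so the
    iteration count stays exact.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    assignment = _group_assignment(predset, grouping)
    groups = sorted(set(assignment), key=str)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    tp, pos, fp, neg = _per_record_counts(predset, thresholds)
    group_id = np.searchsorted(np.array(groups, dtype=object), assignment)
    n = predset.n_records
    m = max(1, int(np.floor(fraction * n)))
    k = len(groups)

    rng = np.random.default_rng(seed)
    tpr_disp = np.empty(iterations)
    fpr_disp = np.empty(iterations)
    n_redrawn = 0
    for i in range(iterations):
        for attempt in range(max_retries + 1):
            idx = rng.choice(n, size=m, replace=False)
            gid = group_id[idx]
            gpos = np.bincount(gid, weights=pos[idx], minlength=k)
            gneg = np.bincount(gid, weights=neg[idx], minlength=k)
            if np.any(gpos == 0) or np.any(gneg == 0):
                n_redrawn += 1
                if attempt == max_retries:
                    raise ValueError(
                        f"iteration {i}: a group kept losing all its "
                        f"positives/negatives after {max_retries} redraws"
                    )
                continue
            gtpr = np.bincount(gid, weights=tp[idx], minlength=k) / gpos
            gfpr = np.bincount(gid, weights=fp[idx], minlength=k) / gneg
            tpr_disp[i] = _mean_abs_pairwise(gtpr)
            fpr_disp[i] = _mean_abs_pairwise(gfpr)
            break
    t_lo, t_hi = np.percentile(tpr_disp, [2.5, 97.5])
    f_lo, f_hi = np.percentile(fpr_disp, [2.5, 97.5])
    return FairnessReport(
        grouping=grouping,
        groups=[str(g) for g in groups],
        mean_abs_tpr_disparity=float(tpr_disp.mean()),
        tpr_ci=(float(t_lo), float(t_hi)),
        mean_abs_fpr_disparity=float(fpr_disp.mean()),
        fpr_ci=(float(f_lo), float(f_hi)),
        iterations=iterations,
        fraction=fraction,
        seed=seed,
        n_redrawn=n_redrawn,
    )
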
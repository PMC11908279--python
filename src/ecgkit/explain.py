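"""Perturbation-based (LIME-style) attribution for multichannel signals.

The signal is tiled into equal-width segments per lead; random binary
masks switch segments off (replacing them with a baseline), the
black-box model scores each perturbed record, and a weighted ridge
surrogate regresses the scores on the masks. The surrogate's
coefficients attribute the prediction to signal regions: a positive
weight marks a segment whose presence raises the score for the label
under analysis. Each label is analyzed independently — attributions for
one label never depend on the model's outputs for other labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np

from .records import ECGRecord

__all__ = ["Segment", "Attribution", "segment_signal", "lime_attribute"]


class Segment(NamedTuple):
    """A half-open sample interval [start, stop) on one lead."""

    lead: int
    start: int
    stop: int


@dataclass
class Attribution:
    """Per-segment attribution of one label's prediction.

    ``weights[i]`` is the surrogate coefficient of ``segments[i]``;
    ``r_squared`` is the weighted fit quality of the linear surrogate
    (None when the model output was constant over perturbations, which
    leaves the fit quality undefined).
    """

    label_name: str
    segments: list[Segment]
    weights: np.ndarray
    intercept: float
    r_squared: float | None
    n_perturbations: int
    seed: int


def segment_signal(record: ECGRecord, n_segments_per_lead: int) -> list[Segment]:
    """Tile each lead into equal-width, contiguous, half-open segments.

    The last segment of each lead absorbs the division remainder, so the
    segments exactly tile the signal without overlap.
    """
    if n_segments_per_lead <= 0:
        raise ValueError("n_segments_per_lead must be positive")
    n = record.n_samples
    if n_segments_per_lead > n:
        raise ValueError(
            f"cannot cut {n} samples into {n_segments_per_lead} segments"
        )
    width = n // n_segments_per_lead
    segments = []
    for lead in range(record.n_leads):
        for k in range(n_segments_per_lead):
            start = k * width
            stop = (k + 1) * width if k < n_segments_per_lead - 1 else n
            segments.append(Segment(lead=lead, start=start, stop=stop))
    return segments


def _perturb(
    record: ECGRecord,
    segments: list[Segment],
    mask: np.ndarray,
    baseline: str,
) -> ECGRecord:
    wf = record.waveform.copy()
    if baseline == "mean":
        lead_means = record.waveform.mean(axis=1)
    for seg, keep in zip(segments, mask):
        if not keep:
            fill = 0.0 if baseline == "zero" else lead_means[seg.lead]
            wf[seg.lead, seg.start:seg.stop] = fill
    return record.copy(waveform=wf)


def lime_attribute(
    score_fn: Callable[[ECGRecord], Mapping[str, float] | Sequence[float]],
    record: ECGRecord,
    label: str | int,
    n_segments: int = 10,
    n_perturbations: int = 500,
    kernel_width: float | None = None,
    seed: int = 0,
    baseline: str = "zero",
    ridge_penalty: float = 1e-4,
) -> Attribution:
    """Fit a local linear surrogate to a black-box scorer around one record.

    Parameters
    ----------
    score_fn:
        Maps an :class:`ECGRecord` to per-label scores (a sequence
        indexed by position, or a mapping by label name).
    label:
        Which output to explain (name for mapping outputs, index for
        sequences).
    n_segments:
        Segments per lead (default 10: 1 s windows on a 10 s record,
        roughly one beat each at resting heart rate).
    kernel_width:
        Width of the exponential proximity kernel on mask Hamming
        distance, ``exp(-h / width²)``; default 0.25 × sqrt(total
        number of segments).
    baseline:
        What masked-off segments are replaced with: ``"zero"`` (flat
        zero signal) or ``"mean"`` (the lead's mean voltage).
    """
    if baseline not in ("zero", "mean"):
        raise ValueError("baseline must be 'zero' or 'mean'")
    if n_perturbations < 2:
        raise ValueError("need at least 2 perturbations")
    segments = segment_signal(record, n_segments)
    n_feat = len(segments)
    if kernel_width is None:
        kernel_width = 0.25 * np.sqrt(n_feat)

    rng = np.random.default_rng(seed)
    masks = np.ones((n_perturbations, n_feat), dtype=np.int8)
    masks[1:] = rng.integers(0, 2, size=(n_perturbations - 1, n_feat))

    def get_score(rec: ECGRecord) -> float:
        out = score_fn(rec)
        try:
            return float(out[label])
        except (KeyError, IndexError, TypeError) as e:
            raise ValueError(f"score_fn output has no entry for label {label!r}") from e

    y = np.empty(n_perturbations)
    for i in range(n_perturbations):
        if masks[i].all():
            rec_i = record
        else:
            rec_i = _perturb(record, segments, masks[i], baseline)
        y[i] = get_score(rec_i)

    hamming = n_feat - masks.sum(axis=1)
    w = np.exp(-hamming / kernel_width**2)

    # ridge-penalized weighted least squares; intercept unpenalized
    X = np.column_stack([np.ones(n_perturbations), masks.astype(float)])
    XtW = X.T * w
    A = XtW @ X
    A[1:, 1:] += ridge_penalty * np.eye(n_feat)
    beta = np.linalg.solve(A, XtW @ y)

    resid = y - X @ beta
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    # constant model output: variance is float dust, fit quality undefined
    degenerate = ss_tot <= 1e-15 * float(np.sum(w * y**2)) + 1e-30
    r2 = None if degenerate else 1.0 - ss_res / ss_tot

    return Attribution(
        label_name=str(label),
        segments=segments,
        weights=beta[1:],
        intercept=float(beta[0]),
        r_squared=r2,
        n_perturbations=n_perturbations,
        seed=seed,
    )
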
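"""Detection and segmentation metrics: ROC curve with Riemann-sum area, accuracy.

The ROC curve is built with a sliding threshold on the gray-scale filter
response: a pixel is predicted "vessel" when its score is at or above the
threshold, and the true-positive fraction is plotted against the
false-positive fraction as the threshold slides from above the maximum score
down to below the minimum.  The area under the curve, Az, is approximated by
a trapezoidal Riemann sum and is the fitness maximized during filter-bank
training.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "RocCurve",
    "roc_curve",
    "accuracy",
    "confusion_fractions",
    "concatenated_az",
    "grid_search",
]


@dataclasses.dataclass
class RocCurve:
    """ROC curve points and trapezoidal area.

    ``thresholds`` is descending (from +inf to -inf), so ``fpf`` and ``tpf``
    are nondecreasing and the curve runs from (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray
    az: float

    def to_csv(self, path) -> None:
        rows = np.column_stack([self.thresholds, self.fpf, self.tpf])
        np.savetxt(path, rows, delimiter=",", header="threshold,fpf,tpf", comments="")


def _flatten_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels must have the same length, got {scores.size} and {labels.size}"
        )
    return scores, labels


def roc_curve(scores, labels, *, thresholds: int | str = 256) -> RocCurve:
    """ROC curve of continuous scores against binary labels.

    Parameters
    ----------
    scores : array-like
        Per-pixel detector response; higher means more vessel-like.
    labels : array-like of bool
        Ground truth (True = vessel).  Both classes must be present.
    thresholds : int or "unique", default 256
        Number of evenly spaced threshold levels spanning
        [min(scores), max(scores)], or ``"unique"`` to slide over every
        distinct score value (exact, used against the pairwise-concordance
        oracle).  +inf / -inf endpoints are always appended so the curve
        starts at (0, 0) and ends at (1, 1).
    """
    scores, labels = _flatten_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes to build a ROC curve")

    lo, hi = float(scores.min()), float(scores.max())
    if thresholds == "unique":
        levels = np.unique(scores)[::-1]
    elif isinstance(thresholds, int):
        if thresholds < 1:
            raise ValueError("thresholds must be >= 1")
        levels = np.linspace(lo, hi, thresholds)[::-1] if hi > lo else np.array([lo])
    else:
        raise ValueError(f"thresholds must be an int or 'unique', got {thresholds!r}")
    t = np.concatenate([[np.inf], levels, [-np.inf]])

    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    # count of scores >= threshold, vectorized over the (descending) levels
    tp = n_pos - np.searchsorted(pos_sorted, t, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, t, side="left")
    tpf = tp / n_pos
    fpf = fp / n_neg
    az = float(np.trapezoid(tpf, fpf))
    return RocCurve(thresholds=t, fpf=fpf, tpf=tpf, az=az)


def confusion_fractions(predicted_mask, truth_mask) -> tuple[float, float, float, float]:
    """Return (tp, tn, fp, fn) as fractions of the total pixel count."""
    pred = np.asarray(predicted_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    n = pred.size
    tp = np.count_nonzero(pred & truth) / n
    tn = np.count_nonzero(~pred & ~truth) / n
    fp = np.count_nonzero(pred & ~truth) / n
    fn = np.count_nonzero(~pred & truth) / n
    return tp, tn, fp, fn


def accuracy(predicted_mask, truth_mask) -> float:
    """Fraction of correctly classified pixels, (TP+TN)/(TP+FP+TN+FN).

    1 when the masks are identical, 0 when they are complementary.
    """
    tp, tn, fp, fn = confusion_fractions(predicted_mask, truth_mask)
    return (tp + tn) / (tp + tn + fp + fn)


def concatenated_az(
    responses: Sequence, masks: Sequence, *, thresholds: int | str = 256
) -> float:
    """Az of the responses of a whole image set, concatenated into one sample.

    Each response (a ``FilterResponse`` or a bare 2-D array) is flattened and
    concatenated with the others to form one large gray-scale sample; the
    result is independent of image order.
    """
    if len(responses) != len(masks):
        raise ValueError(
            f"{len(responses)} responses but {len(masks)} masks"
        )
    if len(responses) == 0:
        raise ValueError("empty image set")
    flat_scores = []
    flat_labels = []
    for i, (resp, mask) in enumerate(zip(responses, masks)):
        arr = np.asarray(getattr(resp, "response", resp), dtype=float)
        m = np.asarray(mask)
        if arr.shape != m.shape:
            raise ValueError(
                f"response/mask shape mismatch at index {i}: {arr.shape} vs {m.shape}"
            )
        flat_scores.append(arr.ravel())
        flat_labels.append(m.ravel().astype(bool))
    scores = np.concatenate(flat_scores)
    labels = np.concatenate(flat_labels)
    return roc_curve(scores, labels, thresholds=thresholds).az


def grid_search(
    tau_values: Iterable[int],
    ell_values: Iterable[float],
    fitness: Callable[[int, float], float],
) -> tuple[tuple[int, float], int]:
    """Exhaustive search over the (tau, ell) grid.

    Evaluates ``fitness`` at every pair and returns ``((tau, ell),
    n_evaluations)`` where the argmax breaks ties by smaller tau, then
    smaller ell.
    """
    tau_values = list(tau_values)
    ell_values = list(ell_values)
    if not tau_values or not ell_values:
        raise ValueError("tau_values and ell_values must be nonempty")
    results = []
    n_eval = 0
    for tau in tau_values:
        for ell in ell_values:
            results.append((float(fitness(tau, ell)), tau, ell))
            n_eval += 1
    _, tau, ell = max(results, key=lambda r: (r[0], -r[1], -r[2]))
    return (tau, ell), n_eval
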
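"""Region-overlap metrics: Jaccard, Dice and the false ratios.

With ``S1`` the ground-truth foreground, ``S2`` the predicted foreground and
``O = S1 ∩ S2`` their overlap (all as pixel counts ``N(.)``):

    JS  = N(S1 ∩ S2) / N(S1 ∪ S2)
    DSC = 2 N(S1 ∩ S2) / (N(S1) + N(S2))
    RFP = N(S1 \\ O) / N(S1)
    RFN = N(S2 \\ O) / N(S2)

RFP/RFN are implemented exactly as defined above even though the naming is
reversed relative to common usage (``S1 \\ O`` is the *missed-truth* set,
conventionally the false-negative set); the defining formulas are treated as
authoritative.  JS and DSC are related by ``DSC = 2 JS / (1 + JS)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, InvalidInputError

__all__ = ["OverlapReport", "overlap", "per_label_overlap", "misclassified_pixels"]


@dataclass(frozen=True)
class OverlapReport:
    """The four overlap ratios plus the raw pixel counts behind them."""

    js: float
    dice: float
    rfp: float
    rfn: float
    n_truth: int
    n_pred: int
    n_overlap: int


def _report_from_counts(n_truth: int, n_pred: int, n_overlap: int) -> OverlapReport:
    union = n_truth + n_pred - n_overlap
    js = n_overlap / union if union else 0.0
    dice = 2.0 * n_overlap / (n_truth + n_pred) if (n_truth + n_pred) else 0.0
    rfp = (n_truth - n_overlap) / n_truth if n_truth else 1.0
    rfn = (n_pred - n_overlap) / n_pred if n_pred else 1.0
    return OverlapReport(
        js=float(js),
        dice=float(dice),
        rfp=float(rfp),
        rfn=float(rfn),
        n_truth=int(n_truth),
        n_pred=int(n_pred),
        n_overlap=int(n_overlap),
    )


def overlap(truth_mask: np.ndarray, pred_mask: np.ndarray) -> OverlapReport:
    """Overlap report for one predicted mask against one ground-truth mask."""
    truth = np.asarray(truth_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if truth.shape != pred.shape:
        raise InvalidInputError("truth and prediction masks must share a shape")
    n_truth = int(truth.sum())
    n_pred = int(pred.sum())
    if n_truth == 0 or n_pred == 0:
        raise EmptyMaskError("overlap metrics need nonempty truth and prediction")
    n_overlap = int((truth & pred).sum())
    return _report_from_counts(n_truth, n_pred, n_overlap)


def _contingency(truth_labels: np.ndarray, pred_labels: np.ndarray):
    t_vals, t_inv = np.unique(truth_labels, return_inverse=True)
    p_vals, p_inv = np.unique(pred_labels, return_inverse=True)
    table = np.zeros((t_vals.size, p_vals.size), dtype=np.int64)
    np.add.at(table, (t_inv.ravel(), p_inv.ravel()), 1)
    return t_vals, p_vals, table


def match_labels(truth_labels: np.ndarray, pred_labels: np.ndarray) -> dict:
    """Greedy maximal-overlap pairing of predicted labels to truth labels.

    Repeatedly matches the (truth, pred) pair with the largest contingency
    count, ties broken by the smaller label ids; each label is used at most
    once.  Returns ``{truth_label: pred_label}`` for matched pairs.
    """
    t_vals, p_vals, table = _contingency(truth_labels, pred_labels)
    work = table.astype(float).copy()
    matches: dict = {}
    for _ in range(min(len(t_vals), len(p_vals))):
        best = np.unravel_index(np.argmax(work), work.shape)
        if work[best] <= 0:
            break
        ti, pi = best
        matches[int(t_vals[ti])] = int(p_vals[pi])
        work[ti, :] = -1.0
        work[:, pi] = -1.0
    return matches


def per_label_overlap(
    truth_labels: np.ndarray, pred_labels: np.ndarray
) -> list:
    """One overlap report per ground-truth label, after label matching.

    Labelings may use arbitrary integer ids; predicted labels are paired to
    truth labels by maximal overlap so that a pure relabeling scores
    perfectly.  Unmatched truth labels get a zero-overlap report.  Returns a
    list of ``(truth_label, matched_pred_label_or_None, OverlapReport)``
    sorted by truth label.
    """
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    if truth_labels.shape != pred_labels.shape:
        raise InvalidInputError("labelings must share a shape")
    matches = match_labels(truth_labels, pred_labels)
    out = []
    for t in np.unique(truth_labels):
        t = int(t)
        t_mask = truth_labels == t
        n_truth = int(t_mask.sum())
        if t in matches:
            p_mask = pred_labels == matches[t]
            n_pred = int(p_mask.sum())
            n_overlap = int((t_mask & p_mask).sum())
            out.append((t, matches[t], _report_from_counts(n_truth, n_pred, n_overlap)))
        else:
            out.append((t, None, _report_from_counts(n_truth, 0, 0)))
    return out


def misclassified_pixels(truth_labels: np.ndarray, pred_labels: np.ndarray) -> int:
    """Pixels not explained by the maximal-overlap label matching.

    Total pixel count minus the summed overlaps of all matched label pairs;
    0 iff the prediction is a relabeling of the truth.
    """
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    if truth_labels.shape != pred_labels.shape:
        raise InvalidInputError("labelings must share a shape")
    matches = match_labels(truth_labels, pred_labels)
    good = 0
    for t, p in matches.items():
        good += int(((truth_labels == t) & (pred_labels == p)).sum())
    return int(truth_labels.size - good)
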
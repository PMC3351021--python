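"""Classification metrics, including carry-over-adjusted precision/recall.

A two-stage classifier's second stage inherits the first stage's mistakes:
instances routed to the wrong main class will be mis-sub-classified no
matter how good the sub-class model is. The adjusted ("new") metrics charge
those inherited errors to the sub-classes, allocating each main class's
false positives/negatives across its sub-classes proportionally to their
test sizes:

    new_precision = 100 * TP / (TP + FP + carry_over_FP)
    new_recall    = 100 * TP / (TP + FN + carry_over_FN)

Undefined rates (zero denominators) are reported as ``None`` ("not
available"), never as 0 or 100. Overall rows aggregate raw counts before
computing rates (micro-averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class ConfusionSummary:
    """Per-label TP/FP/FN counts pooled over a test set."""

    tp: Dict[str, int]
    fp: Dict[str, int]
    fn: Dict[str, int]
    total: int
    roc_area: Dict[str, Optional[float]] = field(default_factory=dict)

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "ConfusionSummary":
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred length mismatch")
        labels = sorted(set(y_true) | set(y_pred))
        tp = {lab: 0 for lab in labels}
        fp = {lab: 0 for lab in labels}
        fn = {lab: 0 for lab in labels}
        for t, p in zip(y_true, y_pred):
            if t == p:
                tp[t] += 1
            else:
                fn[t] += 1
                fp[p] += 1
        return cls(tp=tp, fp=fp, fn=fn, total=len(y_true))

    @property
    def labels(self) -> List[str]:
        return sorted(self.tp)

    def validate(self) -> "ConfusionSummary":
        if any(v < 0 for d in (self.tp, self.fp, self.fn) for v in d.values()):
            raise ValueError("negative confusion counts")
        if sum(self.tp.values()) + sum(self.fn.values()) != self.total:
            raise ValueError("sum(TP) + sum(FN) must equal the instance total")
        return self


def _rate(num: int, denom: int) -> Optional[float]:
    return None if denom == 0 else 100.0 * num / denom


def class_metrics(confusion: ConfusionSummary) -> pd.DataFrame:
    """Per-label precision/recall (percent) and overall accuracy.

    Returns a frame indexed by label with a trailing ``overall`` row whose
    accuracy is ``100 * sum(TP) / total``. Undefined rates are NaN.
    """
    if confusion.total <= 0:
        raise ValueError("empty confusion summary")
    confusion.validate()
    rows = {}
    for lab in confusion.labels:
        tp, fp, fn = confusion.tp[lab], confusion.fp[lab], confusion.fn[lab]
        rows[lab] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": _rate(tp, tp + fp),
            "recall": _rate(tp, tp + fn),
            "accuracy": None,
        }
    correct = sum(confusion.tp.values())
    rows["overall"] = {
        "tp": correct,
        "fp": sum(confusion.fp.values()),
        "fn": sum(confusion.fn.values()),
        "precision": None,
        "recall": None,
        "accuracy": 100.0 * correct / confusion.total,
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "label"
    return frame


def overall_accuracy(correct: int, total: int) -> float:
    """Accuracy in percent from raw counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * correct / total


def allocate_carryover(
    total_carry: int, subclass_sizes: Mapping[str, int]
) -> Dict[str, int]:
    """Allocate a main class's carried-over error count across its
    sub-classes proportionally to their test sizes (largest-remainder
    method; ties broken by sub-class label order). Sums exactly to
    ``total_carry``; every entry is within 1 of its exact proportional
    share."""
    if total_carry < 0:
        raise ValueError("total_carry must be non-negative")
    if not subclass_sizes:
        raise ValueError("subclass_sizes must be nonempty")
    if any(v <= 0 for v in subclass_sizes.values()):
        raise ValueError("subclass sizes must be positive")
    size_total = sum(subclass_sizes.values())
    labels = sorted(subclass_sizes)
    shares = {lab: total_carry * subclass_sizes[lab] / size_total for lab in labels}
    alloc = {lab: math.floor(shares[lab]) for lab in labels}
    remaining = total_carry - sum(alloc.values())
    by_remainder = sorted(labels, key=lambda lab: (-(shares[lab] - alloc[lab]), lab))
    for lab in by_remainder[:remaining]:
        alloc[lab] += 1
    return alloc


def adjusted_precision(tp: int, fp: int, carry_fp: int) -> Optional[float]:
    """Percent precision charging carried-over false positives:
    ``100 * tp / (tp + fp + carry_fp)``; None when undefined."""
    for name, v in (("tp", tp), ("fp", fp), ("carry_fp", carry_fp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return _rate(tp, tp + fp + carry_fp)


def adjusted_recall(tp: int, fn: int, carry_fn: int) -> Optional[float]:
    """Percent recall charging carried-over false negatives:
    ``100 * tp / (tp + fn + carry_fn)``; None when undefined."""
    for name, v in (("tp", tp), ("fn", fn), ("carry_fn", carry_fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return _rate(tp, tp + fn + carry_fn)


def roc_area(
    scores: Sequence[float], is_positive: Sequence[bool]
) -> Optional[float]:
    """One-vs-rest area under the ROC curve by the rank statistic: the
    probability that a positive outranks a negative, ties counted half.
    Returns None when either class is empty."""
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(is_positive, dtype=bool)
    if scores.shape != mask.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(mask.sum())
    n_neg = int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    rank = 1.0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (rank + rank + (j - i))
        rank += j - i + 1
        i = j + 1
    rank_sum = ranks[mask].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def per_class_roc_areas(
    vote_fractions: pd.DataFrame, y_true: Sequence[str]
) -> Dict[str, Optional[float]]:
    """One-vs-rest ROC area per class from a (rows x classes) vote table."""
    y_true = list(y_true)
    if len(y_true) != len(vote_fractions):
        raise ValueError("votes and labels length mismatch")
    return {
        lab: roc_area(vote_fractions[lab].to_numpy(), [t == lab for t in y_true])
        for lab in vote_fractions.columns
    }


def evaluate_cascade(
    predictions,
    true_labels: Mapping[str, object],
    level2_confusion: ConfusionSummary,
) -> pd.DataFrame:
    """Sub-class metrics with level-2 error carry-over (adjusted metrics).

    ``predictions`` is a sequence of cascade predictions (see
    :mod:`ecforest.cascade`); ``true_labels`` maps record id to its true
    :class:`~ecforest.records.ECLabel`. Level-3 TP/FP/FN are counted among
    correctly routed rows (predicted main class equals true main class);
    each main class's level-2 FP and FN totals are then allocated across its
    sub-classes proportionally to sub-class size and folded into the
    adjusted rates. The trailing ``overall`` row micro-averages raw counts.
    """
    from .records import ECLabel  # local import to avoid cycle at module load

    routed: Dict[int, List[Tuple[str, str]]] = {}
    for pred in predictions:
        if not pred.is_enzyme:
            continue
        truth = true_labels.get(pred.id)
        if not isinstance(truth, ECLabel) or truth.sub_class is None:
            raise ValueError(f"prediction {pred.id!r} lacks a true sub-class label")
        if pred.main_class != truth.main_class:
            continue  # a level-2 error; accounted via carry-over totals
        routed.setdefault(pred.main_class, []).append(
            (truth.sub_class, pred.sub_class)
        )

    rows = {}
    totals = {"size": 0, "tp": 0, "fp": 0, "fn": 0, "carry_fp": 0, "carry_fn": 0}
    for k in sorted(routed):
        pairs = routed[k]
        sub_true = [t for t, _ in pairs]
        sub_pred = [p for _, p in pairs]
        conf = ConfusionSummary.from_predictions(sub_true, sub_pred)
        sizes = {lab: sub_true.count(lab) for lab in set(sub_true)}
        lvl2_fp = level2_confusion.fp.get(str(k), 0)
        lvl2_fn = level2_confusion.fn.get(str(k), 0)
        carry_fp = allocate_carryover(lvl2_fp, sizes)
        carry_fn = allocate_carryover(lvl2_fn, sizes)
        for lab in sorted(sizes):
            tp = conf.tp.get(lab, 0)
            fp = conf.fp.get(lab, 0)
            fn = conf.fn.get(lab, 0)
            rows[lab] = {
                "size": sizes[lab],
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "carry_fp": carry_fp[lab],
                "carry_fn": carry_fn[lab],
                "precision": _rate(tp, tp + fp),
                "new_precision": adjusted_precision(tp, fp, carry_fp[lab]),
                "recall": _rate(tp, tp + fn),
                "new_recall": adjusted_recall(tp, fn, carry_fn[lab]),
            }
            for key in totals:
                totals[key] += rows[lab][key]

    rows["overall"] = {
        **totals,
        "precision": _rate(totals["tp"], totals["tp"] + totals["fp"]),
        "new_precision": adjusted_precision(
            totals["tp"], totals["fp"], totals["carry_fp"]
        ),
        "recall": _rate(totals["tp"], totals["tp"] + totals["fn"]),
        "new_recall": adjusted_recall(
            totals["tp"], totals["fn"], totals["carry_fn"]
        ),
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sub_class"
    return frame


def write_metrics(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.4f")
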
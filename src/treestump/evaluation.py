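"""Detection and classification scoring: matching, metrics, confusion.

Two evaluation modes are supported.  Per-tree mode matches detection
boxes to ground-truth boxes greedily in descending score order at an
IoU threshold and reports precision, recall and false acceptance over
the matched counts.  Per-patch mode scores window/patch label
predictions directly and additionally reports a row-normalised 2x2
confusion matrix (rows = true class).

False acceptance is the fraction of positive detections that are wrong,
i.e. the complement of precision: FA = FP / (TP + FP) = 1 - precision.
Note that under heavy class imbalance (suburban scenes contain far more
non-trunk regions than trunks) a small non-tree false-positive *rate*
in the confusion matrix coexists with a large false acceptance, because
the two statistics normalise by different totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from treestump.boxes import Box, box_iou
from treestump.detector import Detection

CLASSES = ("tree", "non-tree")


@dataclass
class MatchResult:
    """Greedy detection-to-truth assignment counts."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp != len(self.matched_pairs):
            raise ValueError("tp must equal the number of matched pairs")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    """Precision/recall/false-acceptance plus optional confusion matrix.

    Undefined metrics (zero denominators) carry ``nan`` with the
    corresponding ``*_defined`` flag cleared -- they are never silently
    propagated into downstream arithmetic.
    """

    precision: float
    recall: float
    false_acceptance: float
    precision_defined: bool = True
    recall_defined: bool = True
    confusion: np.ndarray | None = None
    confusion_support: np.ndarray | None = None
    counts: dict = field(default_factory=dict)


def match_detections(
    detections: Sequence[Detection],
    truth_boxes: Sequence[Box],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Match detections to ground-truth boxes greedily by score.

    Detections are visited in descending score order (ties by input
    index); each claims the unmatched truth box of highest IoU provided
    that IoU reaches the threshold.  Each truth box and each detection
    matches at most once.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    unmatched_truth = set(range(len(truth_boxes)))
    pairs: list[tuple[int, int, float]] = []
    for di in order:
        best_iou, best_t = 0.0, None
        for ti in sorted(unmatched_truth):
            iou = box_iou(detections[di].box, truth_boxes[ti])
            if iou > best_iou:
                best_iou, best_t = iou, ti
        if best_t is not None and best_iou >= iou_threshold:
            pairs.append((di, best_t, best_iou))
            unmatched_truth.discard(best_t)
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(detections) - tp,
                       fn=len(truth_boxes) - tp, matched_pairs=pairs)


def compute_metrics(match: MatchResult) -> MetricsReport:
    """Precision, recall and false acceptance from match counts."""
    tp, fp, fn = match.tp, match.fp, match.fn
    p_def = tp + fp > 0
    r_def = tp + fn > 0
    precision = tp / (tp + fp) if p_def else float("nan")
    recall = tp / (tp + fn) if r_def else float("nan")
    fa = fp / (tp + fp) if p_def else float("nan")
    return MetricsReport(
        precision=precision, recall=recall, false_acceptance=fa,
        precision_defined=p_def, recall_defined=r_def,
        counts={"tp": tp, "fp": fp, "fn": fn},
    )


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: tuple[str, str] = CLASSES,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised 2x2 confusion matrix (rows = true class).

    Returns ``(matrix, support)`` where ``support[i]`` counts true
    examples of class i; rows with zero support are filled with ``nan``
    rather than dividing by zero.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in classes:
            raise ValueError(f"unknown label {lab!r}; expected one of {classes}")
    counts = np.zeros((2, 2))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1)
    matrix = np.full((2, 2), np.nan)
    for i in range(2):
        if support[i] > 0:
            matrix[i] = counts[i] / support[i]
    return matrix, support.astype(int)


def evaluate_patch_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Per-patch metrics: 1 = trunk, 0 = non-trunk integer labels."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must share shape")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    report = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn,
                                         matched_pairs=[(0, 0, 0.0)] * tp))
    names = np.where(y_true == 1, CLASSES[0], CLASSES[1])
    pred_names = np.where(y_pred == 1, CLASSES[0], CLASSES[1])
    report.confusion, report.confusion_support = confusion_matrix(
        list(names), list(pred_names)
    )
    return report
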
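"""Instance-segmentation evaluation: SEG score and average precision.

Two complementary measures, both on pairs of label images:

* **SEG** (segmentation accuracy): for each ground-truth cell, find the
  predicted cell covering more than half of it (at most one can exist) and
  average the Jaccard indices; unmatched ground-truth cells score 0.
* **AP** (segmentation quality): one-to-one matching of predicted and
  ground-truth cells at IoU >= a threshold (0.7 by default);
  AP = TP / (TP + FP + FN), where FP counts over-segmentation surplus and
  FN counts missed cells.

Label 0 (watershed line / background) belongs to no cell in either image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["iou", "seg_score", "average_precision", "MatchReport"]


@dataclass
class MatchReport:
    """Per-image evaluation record."""

    seg: float
    tp: int
    fp: int
    fn: int
    ap: float
    iou_threshold: float
    per_cell: list[tuple[int, int | None, float]] = field(default_factory=list)
    degenerate: bool = False  # both images empty of cells

    def to_dict(self) -> dict:
        return {
            "seg": self.seg,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ap": self.ap,
            "iou_threshold": self.iou_threshold,
            "degenerate": self.degenerate,
            "per_cell": [
                {"gt_label": g, "pred_label": p, "iou": v} for g, p, v in self.per_cell
            ],
        }


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two pixel sets (boolean masks)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("IoU of two empty sets is undefined")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Sparse contingency table of positive-label overlaps plus areas."""
    gt = np.asarray(gt).astype(np.int64)
    pred = np.asarray(pred).astype(np.int64)
    if gt.shape != pred.shape:
        raise ValueError("label images must share a shape")
    mask = (gt > 0) & (pred > 0)
    table = sparse.coo_matrix(
        (np.ones(int(mask.sum()), dtype=np.int64), (gt[mask], pred[mask])),
    ).tocsr() if mask.any() else None
    gt_labels, gt_areas = np.unique(gt[gt > 0], return_counts=True)
    pred_labels, pred_areas = np.unique(pred[pred > 0], return_counts=True)
    return table, dict(zip(gt_labels, gt_areas)), dict(zip(pred_labels, pred_areas))


def seg_score(gt: np.ndarray, pred: np.ndarray) -> float:
    """Mean over ground-truth cells of the IoU with their majority match.

    A predicted cell S matches ground-truth cell R iff |R ∩ S| > 0.5 |R|;
    cells with no such S contribute 0.
    """
    table, gt_areas, pred_areas = _overlap_table(gt, pred)
    if not gt_areas:
        raise ValueError("ground truth contains no cells")
    total = 0.0
    for g, area_g in gt_areas.items():
        best = 0.0
        if table is not None and g < table.shape[0]:
            row = table.getrow(g)
            for p, inter in zip(row.indices, row.data):
                if inter > 0.5 * area_g:
                    best = inter / (area_g + pred_areas[p] - inter)
                    break  # at most one cell can cover > half of R
        total += best
    return total / len(gt_areas)


def average_precision(
    gt: np.ndarray, pred: np.ndarray, iou_thr: float = 0.7
) -> MatchReport:
    """One-to-one IoU matching and AP = TP / (TP + FP + FN).

    Candidate (gt, pred) pairs with IoU >= ``iou_thr`` are matched greedily
    in descending IoU (ties broken by gt label then pred label). At
    thresholds >= 0.5 each cell can exceed the threshold with at most one
    partner, so the greedy matching is the optimal one.
    """
    table, gt_areas, pred_areas = _overlap_table(gt, pred)
    n_gt, n_pred = len(gt_areas), len(pred_areas)
    if n_gt == 0 and n_pred == 0:
        return MatchReport(
            seg=1.0, tp=0, fp=0, fn=0, ap=1.0,
            iou_threshold=iou_thr, degenerate=True,
        )
    candidates: list[tuple[float, int, int]] = []
    pair_iou: dict[int, tuple[int, float]] = {}
    if table is not None:
        coo = table.tocoo()
        for g, p, inter in zip(coo.row, coo.col, coo.data):
            v = inter / (gt_areas[g] + pred_areas[p] - inter)
            if v >= iou_thr:
                candidates.append((v, int(g), int(p)))
            prev = pair_iou.get(int(g))
            if prev is None or v > prev[1]:
                pair_iou[int(g)] = (int(p), v)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_gt: dict[int, tuple[int, float]] = {}
    matched_pred: set[int] = set()
    for v, g, p in candidates:
        if g in matched_gt or p in matched_pred:
            continue
        matched_gt[g] = (p, v)
        matched_pred.add(p)
    tp = len(matched_gt)
    fp = n_pred - tp
    fn = n_gt - tp
    ap = tp / (tp + fp + fn) if (tp + fp + fn) > 0 else 1.0
    per_cell = []
    for g in sorted(gt_areas):
        if g in matched_gt:
            p, v = matched_gt[g]
            per_cell.append((int(g), int(p), float(v)))
        else:
            best = pair_iou.get(int(g))
            per_cell.append((int(g), None, float(best[1]) if best else 0.0))
    seg = seg_score(gt, pred) if n_gt else 1.0
    return MatchReport(
        seg=seg, tp=tp, fp=fp, fn=fn, ap=ap,
        iou_threshold=iou_thr, per_cell=per_cell,
    )
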
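"""Point-level, object-level and count-agreement evaluation.

Predicted and ground-truth labelings are integer arrays over the same cloud
(−1 = unlabeled).  Predicted groups are matched one-to-one to ground-truth
groups greedily by descending IoU; with the matching fixed,

* point level: TP = |S_pred ∩ S_gt| summed over matched pairs,
  FP = |S_pred| − TP, FN = |S_gt| − TP, then precision/recall/F1;
* object level: mIoU = mean IoU over ground-truth groups (unmatched → 0), and
  AP@IoU from the precision–recall curve over predictions ranked by group
  mean confidence;
* counts: R², MAPE (%) and RMSE between predicted and true per-sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "match_instances",
    "point_metrics",
    "miou",
    "average_precision",
    "count_agreement",
    "evaluate",
]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    miou: float
    ap: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "miou": self.miou,
            "ap": {f"{k:g}": v for k, v in self.ap.items()},
        }


def _groups(labels: np.ndarray) -> dict[int, np.ndarray]:
    labels = np.asarray(labels)
    return {int(k): np.nonzero(labels == k)[0] for k in np.unique(labels) if k >= 0}


def match_instances(
    pred: np.ndarray, gt: np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of predicted to ground-truth groups.

    Returns ``(pred_label, gt_label, iou)`` triples in descending IoU order;
    each group appears at most once.  Ties break on the smaller labels for
    determinism.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must have equal length")
    pg, gg = _groups(pred), _groups(gt)
    cand = []
    for pl, pidx in pg.items():
        gl_at_p = gt[pidx]
        for gl in np.unique(gl_at_p[gl_at_p >= 0]):
            inter = int((gl_at_p == gl).sum())
            union = len(pidx) + len(gg[int(gl)]) - inter
            cand.append((inter / union, pl, int(gl)))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    out = []
    for iou, pl, gl in cand:
        if pl in used_p or gl in used_g:
            continue
        out.append((pl, gl, iou))
        used_p.add(pl)
        used_g.add(gl)
    return out


def point_metrics(
    pred: np.ndarray,
    gt: np.ndarray,
    matching: list[tuple[int, int, float]] | None = None,
):
    """Point-level TP/FP/FN and precision/recall/F1 under an instance matching."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if matching is None:
        matching = match_instances(pred, gt)
    tp = sum(int(((pred == pl) & (gt == gl)).sum()) for pl, gl, _ in matching)
    n_pred = int((pred >= 0).sum())
    n_gt = int((gt >= 0).sum())
    fp = n_pred - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return tp, fp, fn, precision, recall, f1


def miou(
    pred: np.ndarray,
    gt: np.ndarray,
    matching: list[tuple[int, int, float]] | None = None,
) -> float:
    """Mean IoU over ground-truth groups; unmatched ground truth counts 0."""
    gt = np.asarray(gt)
    if matching is None:
        matching = match_instances(pred, gt)
    gg = _groups(gt)
    if not gg:
        raise ValueError("no ground-truth groups")
    by_gt = {gl: iou for _, gl, iou in matching}
    return float(np.mean([by_gt.get(gl, 0.0) for gl in gg]))


def average_precision(
    pred: np.ndarray,
    gt: np.ndarray,
    scores: dict[int, float],
    iou_threshold: float = 0.5,
) -> float:
    """AP from the PR curve over predictions ranked by group mean confidence.

    Walking the ranked predictions, each one is a true positive iff its best
    IoU against a still-unclaimed ground-truth group reaches the threshold;
    AP = Σ P(i)·(R(i) − R(i−1)).
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must be in (0, 1)")
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    pg, gg = _groups(pred), _groups(gt)
    if not gg:
        raise ValueError("no ground-truth groups")
    ranked = sorted(pg, key=lambda pl: (-scores.get(pl, 0.0), pl))
    claimed: set[int] = set()
    tp_flags = []
    for pl in ranked:
        gl_at_p = gt[pg[pl]]
        best_iou, best_gl = 0.0, None
        for gl in np.unique(gl_at_p[gl_at_p >= 0]):
            gl = int(gl)
            if gl in claimed:
                continue
            inter = int((gl_at_p == gl).sum())
            union = len(pg[pl]) + len(gg[gl]) - inter
            iou = inter / union
            if iou > best_iou:
                best_iou, best_gl = iou, gl
        if best_gl is not None and best_iou >= iou_threshold:
            claimed.add(best_gl)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    ap = 0.0
    tp_cum = 0
    prev_recall = 0.0
    n_gt = len(gg)
    for i, flag in enumerate(tp_flags, start=1):
        tp_cum += flag
        precision = tp_cum / i
        recall = tp_cum / n_gt
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return float(ap)


def count_agreement(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    """R², MAPE (%) and RMSE between true and predicted per-sample counts."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length non-empty arrays")
    if np.any(y == 0):
        raise ValueError("MAPE is undefined when a true count is zero")
    resid = y - y_hat
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    mape = float(np.mean(np.abs(resid / y))) * 100.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r2, mape, rmse


def evaluate(
    pred: np.ndarray,
    gt: np.ndarray,
    conf: np.ndarray | None = None,
    iou_thresholds: tuple[float, ...] = (0.5, 0.75),
    mask: np.ndarray | None = None,
) -> MetricsReport:
    """Full report: point level, mIoU and AP at the given IoU thresholds.

    ``conf`` supplies per-point confidences used to rank predicted groups for
    AP (group mean); without it all groups rank equally.  ``mask`` restricts
    the evaluation to a point subset (e.g. points visible in at least one
    view).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if mask is not None:
        pred, gt = pred[mask], gt[mask]
        conf = None if conf is None else np.asarray(conf)[mask]
    matching = match_instances(pred, gt)
    tp, fp, fn, precision, recall, f1 = point_metrics(pred, gt, matching)
    m = miou(pred, gt, matching)
    if conf is None:
        scores = {pl: 0.0 for pl in _groups(pred)}
    else:
        conf = np.asarray(conf, dtype=np.float64)
        scores = {pl: float(conf[idx].mean()) for pl, idx in _groups(pred).items()}
    ap = {thr: average_precision(pred, gt, scores, thr) for thr in iou_thresholds}
    return MetricsReport(tp, fp, fn, precision, recall, f1, m, ap)
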
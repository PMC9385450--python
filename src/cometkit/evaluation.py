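"""Multi-object Jaccard-index evaluation of instance segmentations.

Predicted instance masks are scored against expert (or synthetic) ground
truth per object: each ground-truth object is paired with the predicted
object covering the largest fraction of its pixels; if that best coverage
is below 50% the object scores 0 (missed), otherwise it scores the Jaccard
index |A∩B| / |A∪B| of the pair. The reported score is the mean over
ground-truth objects.

The 50% gate's denominator is the ground-truth object's area by default
(configurable to the pair union). Pairing is per-GT greedy, so one
predicted object may serve several ground-truth objects; an optional
Hungarian mode enforces one-to-one matching instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LabelMask

__all__ = ["ObjectMatch", "JIResult", "pairwise_ji", "multi_object_ji"]


@dataclass
class ObjectMatch:
    """Evaluation outcome for one ground-truth object."""

    gt_id: int
    pred_id: int | None
    overlap_fraction: float
    ji: float


@dataclass
class JIResult:
    per_gt_object: list[ObjectMatch]
    mean_ji: float

    def to_rows(self) -> list[dict]:
        rows = [{"gt_id": m.gt_id,
                 "pred_id": "" if m.pred_id is None else m.pred_id,
                 "overlap_fraction": m.overlap_fraction, "ji": m.ji}
                for m in self.per_gt_object]
        rows.append({"gt_id": "mean", "pred_id": "", "overlap_fraction": "",
                     "ji": self.mean_ji})
        return rows


def pairwise_ji(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two binary masks; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - inter
    return inter / union if union else 0.0


def _contingency(gt: np.ndarray, pred: np.ndarray):
    """Sparse overlap counts between positive GT and pred labels."""
    sel = gt > 0
    g = gt[sel].astype(np.int64)
    p = pred[sel].astype(np.int64)
    width = int(pred.max()) + 1
    keys = g * width + p
    uniq, counts = np.unique(keys, return_counts=True)
    return uniq // width, uniq % width, counts


def multi_object_ji(gt: LabelMask | np.ndarray, pred: LabelMask | np.ndarray,
                    min_overlap: float = 0.5,
                    overlap_denominator: str = "gt",
                    matching: str = "greedy") -> JIResult:
    """Score a predicted label mask against ground truth, per GT object.

    Parameters
    ----------
    min_overlap:
        Coverage gate below which a GT object scores 0 (default 0.5).
    overlap_denominator:
        ``"gt"`` (default) measures coverage as |GT∩pred| / |GT|;
        ``"union"`` uses |GT∩pred| / |GT∪pred|.
    matching:
        ``"greedy"`` pairs each GT object independently with its
        maximum-overlap predicted object (a predicted object may be reused);
        ``"hungarian"`` enforces a one-to-one assignment maximising total JI.
    """
    gt_arr = gt.labels if isinstance(gt, LabelMask) else np.asarray(gt)
    pred_arr = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    if gt_arr.shape != pred_arr.shape:
        raise ValueError(f"mask shapes differ: {gt_arr.shape} vs {pred_arr.shape}")
    if overlap_denominator not in ("gt", "union"):
        raise ValueError("overlap_denominator must be 'gt' or 'union'")

    gt_ids = np.unique(gt_arr)
    gt_ids = gt_ids[gt_ids > 0]
    if gt_ids.size == 0:
        raise ValueError("ground truth contains no objects; mean JI undefined")

    gt_areas = {int(i): int(np.count_nonzero(gt_arr == i)) for i in gt_ids}
    pred_ids = np.unique(pred_arr)
    pred_ids = pred_ids[pred_ids > 0]
    pred_areas = {int(i): int(np.count_nonzero(pred_arr == i)) for i in pred_ids}

    gi, pi, counts = _contingency(gt_arr, pred_arr)
    overlaps: dict[int, dict[int, int]] = {int(i): {} for i in gt_ids}
    for g, p, k in zip(gi, pi, counts):
        if p > 0:
            overlaps[int(g)][int(p)] = int(k)

    def _metrics(g: int, p: int) -> tuple[float, float]:
        inter = overlaps[g].get(p, 0)
        union = gt_areas[g] + pred_areas[p] - inter
        frac = (inter / gt_areas[g] if overlap_denominator == "gt"
                else inter / union if union else 0.0)
        return frac, (inter / union if union else 0.0)

    assignment: dict[int, int | None]
    if matching == "greedy":
        assignment = {}
        for g in map(int, gt_ids):
            cands = overlaps[g]
            if not cands:
                assignment[g] = None
                continue
            # maximum overlap; ties to the lower predicted ID
            best = max(sorted(cands), key=lambda p: cands[p])
            assignment[g] = best
    elif matching == "hungarian":
        from scipy.optimize import linear_sum_assignment
        g_list = [int(i) for i in gt_ids]
        p_list = [int(i) for i in pred_ids]
        cost = np.zeros((len(g_list), len(p_list)))
        for a, g in enumerate(g_list):
            for b, p in enumerate(p_list):
                cost[a, b] = -_metrics(g, p)[1]
        assignment = {g: None for g in g_list}
        if p_list:
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < 0:
                    assignment[g_list[a]] = p_list[b]
    else:
        raise ValueError("matching must be 'greedy' or 'hungarian'")

    matches: list[ObjectMatch] = []
    for g in map(int, gt_ids):
        p = assignment[g]
        if p is None:
            matches.append(ObjectMatch(g, None, 0.0, 0.0))
            continue
        frac, ji = _metrics(g, p)
        if frac < min_overlap:
            matches.append(ObjectMatch(g, None, frac, 0.0))
        else:
            matches.append(ObjectMatch(g, p, frac, ji))
    mean = float(np.mean([m.ji for m in matches]))
    return JIResult(per_gt_object=matches, mean_ji=mean)
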
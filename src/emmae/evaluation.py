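"""Detection metrics for particle picking.

A prediction and an annotation are compared as axis-aligned square boxes of
side equal to the particle diameter, centered on the respective
coordinates.  Predictions are matched to ground truth one-to-one, greedily
in descending IoU; a matched pair counts as a true positive only if its
IoU is at least 0.6.  Per-micrograph metrics are the mean IoU over matched
pairs, precision, recall and F1; test-set metrics are unweighted means
across micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError
from .io_formats import ParticleSet

__all__ = ["MatchResult", "Metrics", "box_iou", "match_and_score", "aggregate"]


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (pred_index, gt_index, iou)
    tp: int
    fp: int
    fn: int


@dataclass
class Metrics:
    iou: float
    precision: float
    recall: float
    f1: float


def box_iou(c1, c2, diameter_px: float) -> float:
    """IoU of two axis-aligned squares of side ``diameter_px`` centered at
    ``c1`` and ``c2``."""
    if diameter_px <= 0:
        raise ContractViolationError("diameter must be positive")
    dx = diameter_px - abs(c1[0] - c2[0])
    dy = diameter_px - abs(c1[1] - c2[1])
    if dx <= 0 or dy <= 0:
        return 0.0
    inter = dx * dy
    union = 2.0 * diameter_px**2 - inter
    return float(inter / union)


def _pairwise_iou(pred: np.ndarray, gt: np.ndarray, diameter_px: float) -> np.ndarray:
    if pred.size == 0 or gt.size == 0:
        return np.zeros((pred.shape[0], gt.shape[0]))
    dx = np.maximum(diameter_px - np.abs(pred[:, None, 0] - gt[None, :, 0]), 0.0)
    dy = np.maximum(diameter_px - np.abs(pred[:, None, 1] - gt[None, :, 1]), 0.0)
    inter = dx * dy
    return inter / (2.0 * diameter_px**2 - inter)


def match_and_score(
    pred: ParticleSet,
    gt: ParticleSet,
    diameter_px: float,
    tp_iou: float = 0.6,
) -> tuple[MatchResult, Metrics]:
    """Greedy unique matching and the four detection metrics.

    Pairs are accepted in descending IoU (ties broken by lower prediction
    index, then lower ground-truth index); each prediction and each
    annotation matches at most once, and only pairs with IoU >= ``tp_iou``
    count.  Precision is tp / n_pred (0 when there are no predictions) and
    recall tp / n_gt (0 when there are no annotations).
    """
    if pred.frame != gt.frame:
        raise ContractViolationError("prediction and ground truth frames differ")
    P = pred.centers
    G = gt.centers
    iou = _pairwise_iou(P, G, diameter_px)

    candidates = [
        (iou[i, j], i, j)
        for i in range(P.shape[0])
        for j in range(G.shape[0])
        if iou[i, j] >= tp_iou
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for v, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((i, j, float(v)))

    tp = len(pairs)
    n_pred, n_gt = P.shape[0], G.shape[0]
    result = MatchResult(pairs=pairs, tp=tp, fp=n_pred - tp, fn=n_gt - tp)
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_gt if n_gt else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    mean_iou = float(np.mean([p[2] for p in pairs])) if pairs else 0.0
    return result, Metrics(iou=mean_iou, precision=precision, recall=recall, f1=f1)


def aggregate(per_micrograph: list[Metrics]) -> Metrics:
    """Unweighted mean of each metric across micrographs."""
    if not per_micrograph:
        raise ContractViolationError("cannot aggregate an empty metric list")
    return Metrics(
        iou=float(np.mean([m.iou for m in per_micrograph])),
        precision=float(np.mean([m.precision for m in per_micrograph])),
        recall=float(np.mean([m.recall for m in per_micrograph])),
        f1=float(np.mean([m.f1 for m in per_micrograph])),
    )
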
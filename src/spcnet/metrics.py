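"""Pixel and object evaluation: Dice, pixel TP/FP rates, object FN rate, AP.

Pixel metrics are computed on binarized (foreground vs background) maps;
object metrics come from a greedy one-to-one instance matching at mask-IoU
threshold tau (default 0.7), with ``AP = TP / (TP + FP + FN)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "PixelConfusion",
    "pixel_confusion",
    "dice",
    "match_instances",
    "average_precision",
    "object_fn_rate",
    "evaluate_pair",
    "evaluate_batch",
]


@dataclass
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tpp_rate: float  # TP / gt foreground  (pixel recall)
    fpp_rate: float  # FP / gt background


@dataclass
class Matching:
    pairs: list[tuple[int, int, float]]  # (pred id, gt id, IoU)
    unmatched_pred: list[int]  # false positives
    unmatched_gt: list[int]  # false negatives
    tau: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


@dataclass
class MetricsReport:
    dc: float
    tpp: float
    fpp: float
    fn: float
    ap: float
    tau: float = 0.7

    def as_percent(self) -> dict[str, float]:
        return {
            "DC": round(100.0 * self.dc, 2),
            "TPp": round(100.0 * self.tpp, 2),
            "FPp": round(100.0 * self.fpp, 2),
            "FN": round(100.0 * self.fn, 2),
            "AP": round(100.0 * self.ap, 2),
            "tau": self.tau,
        }


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> PixelConfusion:
    """Binary foreground confusion counts plus the paper's rate conventions."""
    pred, gt = _check_shapes(pred, gt)
    p, g = pred > 0, gt > 0
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    n_fg = tp + fn
    n_bg = int(np.count_nonzero(~g))
    return PixelConfusion(
        tp=tp,
        fp=fp,
        fn=fn,
        tpp_rate=tp / n_fg if n_fg else 0.0,
        fpp_rate=fp / n_bg if n_bg else 0.0,
    )


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """``2*TP / (2*TP + FN + FP)`` on binarized maps; 1.0 when both are empty."""
    c = pixel_confusion(pred, gt)
    denom = 2 * c.tp + c.fn + c.fp
    return 2 * c.tp / denom if denom else 1.0


def _instance_iou_table(pred: np.ndarray, gt: np.ndarray):
    """Sparse pairwise mask IoU between pred and gt instances via id-pair counts."""
    pred_ids, pred_inv = np.unique(pred[pred > 0], return_inverse=True)
    gt_ids, gt_inv = np.unique(gt[gt > 0], return_inverse=True)
    pred_areas = np.bincount(pred[pred > 0].ravel(), minlength=1)
    gt_areas = np.bincount(gt[gt > 0].ravel(), minlength=1)
    both = (pred > 0) & (gt > 0)
    if both.any():
        pair_keys = pred[both].astype(np.int64) * (int(gt.max()) + 1) + gt[both].astype(np.int64)
        keys, counts = np.unique(pair_keys, return_counts=True)
        pid = keys // (int(gt.max()) + 1)
        gid = keys % (int(gt.max()) + 1)
        inter = counts
    else:
        pid = gid = inter = np.zeros(0, dtype=np.int64)
    union = pred_areas[pid] + gt_areas[gid] - inter
    iou = inter / union
    return pred_ids, gt_ids, pid, gid, iou


def match_instances(pred: np.ndarray, gt: np.ndarray, tau: float = 0.7) -> Matching:
    """Greedy one-to-one matching of instances in descending IoU while IoU >= tau.

    Returns matched (pred, gt, IoU) triples plus the unmatched prediction ids
    (false positives) and unmatched ground-truth ids (false negatives).
    """
    pred, gt = _check_shapes(pred, gt)
    pred_ids, gt_ids, pid, gid, iou = _instance_iou_table(pred, gt)
    # descending IoU, deterministic tie-break on (pred id, gt id)
    order = np.lexsort((gid, pid, -iou))
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        if iou[k] < tau:
            break
        p, g = int(pid[k]), int(gid[k])
        if p in used_pred or g in used_gt:
            continue
        used_pred.add(p)
        used_gt.add(g)
        pairs.append((p, g, float(iou[k])))
    unmatched_pred = [int(p) for p in pred_ids if p not in used_pred]
    unmatched_gt = [int(g) for g in gt_ids if g not in used_gt]
    return Matching(pairs=pairs, unmatched_pred=unmatched_pred, unmatched_gt=unmatched_gt, tau=tau)


def average_precision(matching: Matching) -> float:
    """``TP / (TP + FP + FN)``; 1.0 when there are no instances at all."""
    denom = matching.tp + matching.fp + matching.fn
    return matching.tp / denom if denom else 1.0


def object_fn_rate(matching: Matching) -> float:
    """Unmatched ground-truth instances over total ground-truth instances."""
    n_gt = matching.tp + matching.fn
    return matching.fn / n_gt if n_gt else 0.0


def evaluate_pair(pred: np.ndarray, gt: np.ndarray, tau: float = 0.7) -> MetricsReport:
    """All five metrics for one prediction / ground-truth label-map pair."""
    conf = pixel_confusion(pred, gt)
    matching = match_instances(pred, gt, tau)
    return MetricsReport(
        dc=dice(pred, gt),
        tpp=conf.tpp_rate,
        fpp=conf.fpp_rate,
        fn=object_fn_rate(matching),
        ap=average_precision(matching),
        tau=tau,
    )


def evaluate_batch(pairs, tau: float = 0.7, aggregate: str = "per_image") -> MetricsReport:
    """Mean report over (pred, gt) pairs.

    ``per_image`` averages each metric across images (the default);
    ``pooled`` concatenates all pixels/instances before computing rates.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no prediction/ground-truth pairs to evaluate")
    if aggregate == "per_image":
        reports = [evaluate_pair(p, g, tau) for p, g in pairs]
        return MetricsReport(
            dc=float(np.mean([r.dc for r in reports])),
            tpp=float(np.mean([r.tpp for r in reports])),
            fpp=float(np.mean([r.fpp for r in reports])),
            fn=float(np.mean([r.fn for r in reports])),
            ap=float(np.mean([r.ap for r in reports])),
            tau=tau,
        )
    if aggregate != "pooled":
        raise ValueError(f"unknown aggregate mode: {aggregate!r}")
    tp = fp = fn_pix = n_fg = n_bg = 0
    otp = ofp = ofn = 0
    for p, g in pairs:
        c = pixel_confusion(p, g)
        tp, fp, fn_pix = tp + c.tp, fp + c.fp, fn_pix + c.fn
        n_fg += c.tp + c.fn
        n_bg += int(np.count_nonzero(np.asarray(g) == 0))
        m = match_instances(p, g, tau)
        otp, ofp, ofn = otp + m.tp, ofp + m.fp, ofn + m.fn
    denom = 2 * tp + fn_pix + fp
    obj_denom = otp + ofp + ofn
    return MetricsReport(
        dc=2 * tp / denom if denom else 1.0,
        tpp=tp / n_fg if n_fg else 0.0,
        fpp=fp / n_bg if n_bg else 0.0,
        fn=ofn / (otp + ofn) if (otp + ofn) else 0.0,
        ap=otp / obj_denom if obj_denom else 1.0,
        tau=tau,
    )


def write_report(report: MetricsReport, json_path=None, csv_path=None) -> None:
    data = report.as_percent()
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(data))
            writer.writerow([data[k] for k in data])
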
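"""Evaluation metrics: splat-level extraction quality, staged P-R sweeps,
and instance-segmentation AP/AR."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ExtractionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    miou: float
    undefined_precision: bool = False


def extraction_metrics(predicted: np.ndarray, gt_positive: np.ndarray,
                       n_total: int) -> ExtractionMetrics:
    """Target-plant-vs-all-else confusion over all scene splats.

    ``predicted`` and ``gt_positive`` are positional index sets; neighbor
    plants count as background.  mIoU averages the plant-class and
    background-class IoU.
    """
    pred = np.zeros(n_total, dtype=bool)
    pred[np.asarray(predicted, dtype=np.int64)] = True
    gt = np.zeros(n_total, dtype=bool)
    gt[np.asarray(gt_positive, dtype=np.int64)] = True
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    undefined = tp + fp == 0
    if undefined:
        log.warning("empty prediction: precision undefined, reported as 0")
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    iou_plant = 0.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
    iou_bg = 0.0 if tn + fp + fn == 0 else tn / (tn + fp + fn)
    return ExtractionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                             recall=recall, miou=0.5 * (iou_plant + iou_bg),
                             undefined_precision=undefined)


DEFAULT_SWEEP_PERCENTILES = tuple(np.round(np.arange(0.80, 0.981, 0.02), 2))


def pr_sweep(run_stage_chain, gt_positive: np.ndarray, n_total: int,
             percentiles=DEFAULT_SWEEP_PERCENTILES) -> np.ndarray:
    """P-R curve over foreground quantiles for one stage configuration.

    ``run_stage_chain(q)`` must return the predicted index set for
    threshold quantile q.  Returns an array of (q, precision, recall) rows.
    """
    rows = []
    for q in percentiles:
        pred = run_stage_chain(float(q))
        m = extraction_metrics(pred, gt_positive, n_total)
        rows.append((float(q), m.precision, m.recall))
    return np.asarray(rows)


def _point_set_iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = set(map(int, a)), set(map(int, b))
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def instance_ap(pred_instances, gt_instances, iou_thr: float = 0.5):
    """AP50/AR50-style instance matching over point-index sets.

    ``pred_instances``: list of (class, member_ids, confidence);
    ``gt_instances``: list of (class, member_ids).  Predictions are sorted
    by confidence and matched greedily one-to-one at IoU >= ``iou_thr``;
    AP is the all-point interpolated area under the precision-recall curve,
    AR the matched-gt fraction.  Returns ({class: (ap, ar)}, mean_ap, mean_ar).
    """
    classes = sorted({c for c, _ in gt_instances})
    per_class = {}
    for cls in classes:
        gts = [set(map(int, m)) for c, m in gt_instances if c == cls]
        preds = sorted([(conf, set(map(int, m))) for c, m, conf in pred_instances if c == cls],
                       key=lambda t: -t[0])
        matched = [False] * len(gts)
        tp_flags = []
        for conf, members in preds:
            best, best_iou = -1, iou_thr
            for gi, g in enumerate(gts):
                if matched[gi]:
                    continue
                u = len(members | g)
                iou = len(members & g) / u if u else 0.0
                if iou >= best_iou:
                    best, best_iou = gi, iou
            if best >= 0:
                matched[best] = True
                tp_flags.append(1)
            else:
                tp_flags.append(0)
        n_gt = len(gts)
        if n_gt == 0:
            log.info("no ground-truth instances of class %s; skipped", cls)
            continue
        tp_cum = np.cumsum(tp_flags) if tp_flags else np.zeros(0)
        if len(tp_cum):
            prec = tp_cum / np.arange(1, len(tp_cum) + 1)
            rec = tp_cum / n_gt
            # all-point interpolation: precision envelope from the right
            prec_env = np.maximum.accumulate(prec[::-1])[::-1]
            recall_grid = np.concatenate([[0.0], rec])
            ap = float(np.sum(np.diff(recall_grid) * prec_env))
        else:
            ap = 0.0
        ar = float(sum(matched) / n_gt)
        per_class[cls] = (ap, ar)
    if not per_class:
        return {}, 0.0, 0.0
    mean_ap = float(np.mean([v[0] for v in per_class.values()]))
    mean_ar = float(np.mean([v[1] for v in per_class.values()]))
    return per_class, mean_ap, mean_ar
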
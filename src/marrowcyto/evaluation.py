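"""Detection evaluation: 11-point AP, mAP, F1, log-average miss rate, kappa.

Conventions (applied identically everywhere):

* localization is correct at IoU >= 0.5;
* the operating point for precision/recall/F1 uses class probability > 0.75;
* AP uses the 11-point interpolated precision at recalls 0.0, 0.1, ..., 1.0,
  where the interpolated precision at r is the maximum precision achieved at
  any recall >= r (zero if r is never reached);
* the log-average miss rate is the geometric mean of miss rates sampled at
  9 FPPI reference points evenly spaced in log10 between 1e-2 and 1e0.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score
from sklearn.metrics import confusion_matrix as _sk_confusion

from .detection import Annotation, Detection, iou, match_detections
from .taxonomy import CLASS_NAMES, EVALUATED_CLASS_IDS

#: FPPI reference points: 10^(-2 + k/4), k = 0..8.
FPPI_POINTS: tuple[float, ...] = tuple(10.0 ** (-2 + k / 4) for k in range(9))


@dataclass
class PRCurve:
    """Ranked precision/recall trace for one class pooled over all tiles."""

    confidences: list[float]
    precisions: list[float]
    recalls: list[float]
    tp_flags: list[bool]
    n_gt: int

    def __post_init__(self) -> None:
        if self.n_gt < 1:
            raise ValueError("PR curve requires at least one ground-truth object")


@dataclass(frozen=True)
class APResult:
    class_id: int
    ap: float
    interp_precisions: tuple[float, ...]  # at r = 0.0, 0.1, ..., 1.0


@dataclass
class FPPICurve:
    fppi: list[float]
    miss_rate: list[float]
    n_images: int
    n_gt: int


def pr_curve(
    tile_pairs: Sequence[tuple[Sequence[Detection], Sequence[Annotation]]],
    class_id: int,
    iou_thr: float = 0.5,
) -> PRCurve:
    """Pool detections of one class over tiles, rank globally by confidence.

    Each detection, visited in descending confidence, is a TP if it localizes
    (IoU >= ``iou_thr``) an as-yet-unmatched same-class annotation in its own
    tile; otherwise an FP.  Cumulative precision/recall are recorded at every
    rank.  Raises if the class has no ground truth (AP undefined).
    """
    n_gt = sum(1 for _, anns in tile_pairs for a in anns if a.class_id == class_id)
    if n_gt == 0:
        raise ValueError(f"class {class_id} absent from ground truth; AP undefined")

    pool: list[tuple[float, int, int]] = []  # (confidence, tile index, det index)
    for t, (dets, _) in enumerate(tile_pairs):
        for i, d in enumerate(dets):
            if d.class_id == class_id:
                pool.append((d.confidence, t, i))
    pool.sort(key=lambda x: (-x[0], x[1], x[2]))

    matched: dict[int, list[bool]] = {}
    confs, precs, recs, flags = [], [], [], []
    tp = fp = 0
    for conf, t, i in pool:
        dets, anns = tile_pairs[t]
        used = matched.setdefault(t, [False] * len(anns))
        best, best_j = 0.0, -1
        for j, ann in enumerate(anns):
            if used[j] or ann.class_id != class_id:
                continue
            v = iou(dets[i].box, ann.box)
            if v >= iou_thr and v > best:
                best, best_j = v, j
        if best_j >= 0:
            used[best_j] = True
            tp += 1
            flags.append(True)
        else:
            fp += 1
            flags.append(False)
        confs.append(conf)
        precs.append(tp / (tp + fp))
        recs.append(tp / n_gt)
    return PRCurve(confs, precs, recs, flags, n_gt)


def ap_11point(curve: PRCurve, class_id: int = -1) -> APResult:
    """11-point interpolated average precision of a ranked PR curve."""
    recalls = np.asarray(curve.recalls)
    precisions = np.asarray(curve.precisions)
    interp = []
    for k in range(11):
        r = k / 10.0
        mask = recalls >= r - 1e-12
        interp.append(float(precisions[mask].max()) if mask.any() else 0.0)
    return APResult(class_id, float(sum(interp) / 11.0), tuple(interp))


def mean_ap(aps: Sequence[APResult | float]) -> float:
    """Arithmetic mean AP over the evaluated classes."""
    if not aps:
        raise ValueError("mean_ap of an empty list")
    vals = [a.ap if isinstance(a, APResult) else float(a) for a in aps]
    return float(sum(vals) / len(vals))


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall <= 0:
        raise ValueError("F1 undefined when precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def fppi_curve(curve: PRCurve, n_images: int) -> FPPICurve:
    """Miss rate vs false positives per image, swept over the confidence ranking."""
    if n_images < 1:
        raise ValueError("n_images must be positive")
    tp = fp = 0
    fppi, miss = [], []
    for flag in curve.tp_flags:
        if flag:
            tp += 1
        else:
            fp += 1
        fppi.append(fp / n_images)
        miss.append(1.0 - tp / curve.n_gt)
    return FPPICurve(fppi, miss, n_images, curve.n_gt)


def lamr(curve: FPPICurve, points: Sequence[float] = FPPI_POINTS) -> float:
    """Log-average miss rate: geometric mean of miss rates at the FPPI points.

    At each reference point the miss rate of the largest achieved FPPI <= the
    point is used (step function, no interpolation); if no achieved FPPI lies
    at or below the point, the miss rate is 1.  Rates are clamped to >= 1e-10
    before taking logs.
    """
    if not curve.fppi:
        return 1.0
    fppi = np.asarray(curve.fppi)
    miss = np.asarray(curve.miss_rate)
    samples = []
    for p in points:
        idx = np.nonzero(fppi <= p + 1e-12)[0]
        samples.append(float(miss[idx[-1]]) if idx.size else 1.0)
    logs = [math.log(max(a, 1e-10)) for a in samples]
    return float(math.exp(sum(logs) / len(logs)))


def confusion_matrix(
    tile_pairs: Sequence[tuple[Sequence[Detection], Sequence[Annotation]]],
    class_ids: Sequence[int] = EVALUATED_CLASS_IDS,
    iou_thr: float = 0.5,
    conf_thr: float = 0.75,
) -> np.ndarray:
    """Row-normalized percentage confusion matrix over localized objects.

    Detections are matched to annotations class-agnostically (localization
    only); each matched pair contributes (ground-truth class, predicted
    class).  Rows (ground truth) sum to 100 for classes with any matched
    object, 0 otherwise.
    """
    y_true, y_pred = [], []
    for dets, anns in tile_pairs:
        m = match_detections(dets, anns, iou_thr=iou_thr, conf_thr=conf_thr, class_aware=False)
        for det, ann in m.tp_pairs:
            y_true.append(ann.class_id)
            y_pred.append(det.class_id)
    n = len(class_ids)
    if not y_true:
        return np.zeros((n, n))
    raw = _sk_confusion(y_true, y_pred, labels=list(class_ids)).astype(float)
    sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(sums > 0, raw / sums * 100.0, 0.0)
    return pct


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists must have equal length")
    if list(labels_a) == list(labels_b):
        return 1.0  # sklearn returns nan for constant identical lists
    return float(cohen_kappa_score(list(labels_a), list(labels_b)))


@dataclass
class ClassEval:
    class_id: int
    name: str
    n_gt: int
    precision: float | None
    recall: float | None
    f1: float | None
    lamr: float
    ap: float


@dataclass
class EvalSummary:
    per_class: list[ClassEval]
    map: float
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None
    macro_lamr: float
    confusion_pct: np.ndarray = field(repr=False, default=None)

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "class": c.name,
                "precision": c.precision,
                "recall": c.recall,
                "f1": c.f1,
                "lamr": c.lamr,
                "ap_0.5": c.ap,
            }
            for c in self.per_class
        ]
        rows.append(
            {
                "class": "average",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "lamr": self.macro_lamr,
                "ap_0.5": self.map,
            }
        )
        return rows

    def write_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["class", "precision", "recall", "f1", "lamr", "ap_0.5"])
            w.writeheader()
            for row in self.to_rows():
                w.writerow(row)


def evaluate_detections(
    tile_pairs: Sequence[tuple[Sequence[Detection], Sequence[Annotation]]],
    class_ids: Sequence[int] = EVALUATED_CLASS_IDS,
    iou_thr: float = 0.5,
    conf_thr: float = 0.75,
) -> EvalSummary:
    """Full per-class and summary evaluation over a pooled tile set.

    Classes absent from the ground truth are excluded (AP is undefined for
    them), not scored zero.
    """
    per_class: list[ClassEval] = []
    n_images = len(tile_pairs)
    for cid in class_ids:
        n_gt = sum(1 for _, anns in tile_pairs for a in anns if a.class_id == cid)
        if n_gt == 0:
            continue
        curve = pr_curve(tile_pairs, cid, iou_thr=iou_thr)
        ap = ap_11point(curve, cid).ap
        cls_lamr = lamr(fppi_curve(curve, n_images))
        tp = fp = fn = 0
        for dets, anns in tile_pairs:
            d_c = [d for d in dets if d.class_id == cid]
            a_c = [a for a in anns if a.class_id == cid]
            m = match_detections(d_c, a_c, iou_thr=iou_thr, conf_thr=conf_thr)
            tp += m.n_tp
            fp += len(m.fp)
            fn += len(m.fn)
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        f1v = f1(prec, rec) if prec is not None and rec is not None and prec + rec > 0 else None
        per_class.append(ClassEval(cid, CLASS_NAMES[cid], n_gt, prec, rec, f1v, cls_lamr, ap))

    if not per_class:
        raise ValueError("no evaluated class present in ground truth")

    def _macro(vals: list[float | None]) -> float | None:
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    return EvalSummary(
        per_class=per_class,
        map=mean_ap([c.ap for c in per_class]),
        macro_precision=_macro([c.precision for c in per_class]),
        macro_recall=_macro([c.recall for c in per_class]),
        macro_f1=_macro([c.f1 for c in per_class]),
        macro_lamr=float(np.mean([c.lamr for c in per_class])),
        confusion_pct=confusion_matrix(tile_pairs, class_ids, iou_thr, conf_thr),
    )
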
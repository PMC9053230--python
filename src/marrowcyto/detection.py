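"""Detection data model, IoU, YOLO-format I/O, matching, and a reference detector.

Boxes are 0-based half-open pixel intervals ``[x0, x1) x [y0, y1)``.  YOLO
text files use the normalized center convention ``class cx cy w h``; the two
converters here are exact inverses up to floating-point rounding.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .taxonomy import (
    BACKGROUND_RGB,
    CLASS_NAMES,
    DEFAULT_PALETTE,
    N_CLASSES,
    ClassProfile,
)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open in both dimensions."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class Annotation:
    box: BoundingBox
    class_id: int

    def __post_init__(self) -> None:
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside 0..{N_CLASSES - 1}")


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    class_id: int
    confidence: float

    def __post_init__(self) -> None:
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside 0..{N_CLASSES - 1}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MatchResult:
    """Outcome of greedy one-to-one detection/ground-truth assignment."""

    tp_pairs: list[tuple[Detection, Annotation]] = field(default_factory=list)
    fp: list[Detection] = field(default_factory=list)
    fn: list[Annotation] = field(default_factory=list)
    ious: list[float] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff equal."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    dets: Sequence[Detection],
    anns: Sequence[Annotation],
    iou_thr: float = 0.5,
    conf_thr: float = 0.75,
    class_aware: bool = True,
) -> MatchResult:
    """Greedy Pascal-VOC-style matching.

    Detections below ``conf_thr`` are discarded.  The rest are visited in
    descending confidence (ties broken by input order) and each is assigned
    to the unmatched annotation — of the same class when ``class_aware`` —
    with the highest IoU >= ``iou_thr`` (IoU ties broken by lowest
    annotation index).  Unassigned detections are false positives; unmatched
    annotations are false negatives.
    """
    retained = [(i, d) for i, d in enumerate(dets) if d.confidence >= conf_thr]
    retained.sort(key=lambda t: (-t[1].confidence, t[0]))

    result = MatchResult()
    matched = [False] * len(anns)
    for _, det in retained:
        best_iou = 0.0
        best_j = -1
        for j, ann in enumerate(anns):
            if matched[j]:
                continue
            if class_aware and ann.class_id != det.class_id:
                continue
            v = iou(det.box, ann.box)
            if v >= iou_thr and v > best_iou:
                best_iou = v
                best_j = j
        if best_j >= 0:
            matched[best_j] = True
            result.tp_pairs.append((det, anns[best_j]))
            result.ious.append(best_iou)
        else:
            result.fp.append(det)
    result.fn = [ann for j, ann in enumerate(anns) if not matched[j]]
    return result


class YoloFormatError(ValueError):
    """Raised for malformed YOLO/LabelImg annotation lines."""


def read_yolo_txt(path: str | os.PathLike, image_width: int, image_height: int) -> list[Annotation]:
    """Parse a LabelImg/YOLO text file into pixel-space annotations.

    Each nonempty line is ``class_id cx cy w h`` with coordinates normalized
    to [0, 1] relative to the image.  Errors carry the 1-based line number.
    """
    anns: list[Annotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise YoloFormatError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise YoloFormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not 0 <= cid < N_CLASSES:
                raise YoloFormatError(f"{path}:{lineno}: class_id {cid} outside 0..{N_CLASSES - 1}")
            if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
                raise YoloFormatError(f"{path}:{lineno}: coordinate outside [0, 1]")
            box = BoundingBox(
                (cx - w / 2) * image_width,
                (cy - h / 2) * image_height,
                (cx + w / 2) * image_width,
                (cy + h / 2) * image_height,
            )
            anns.append(Annotation(box, cid))
    return anns


def write_yolo_txt(
    anns: Sequence[Annotation], path: str | os.PathLike, image_width: int, image_height: int
) -> None:
    """Write annotations in the normalized-center YOLO dialect (inverse of read)."""
    with open(path, "w") as fh:
        for ann in anns:
            b = ann.box
            cx = (b.x0 + b.x1) / 2 / image_width
            cy = (b.y0 + b.y1) / 2 / image_height
            w = (b.x1 - b.x0) / image_width
            h = (b.y1 - b.y0) / image_height
            fh.write(f"{ann.class_id} {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}\n")


def nms(dets: Sequence[Detection], iou_thr: float = 0.5) -> list[Detection]:
    """Greedy per-class non-maximum suppression by descending confidence."""
    survivors: list[Detection] = []
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    for i in order:
        d = dets[i]
        if any(s.class_id == d.class_id and iou(s.box, d.box) > iou_thr for s in survivors):
            continue
        survivors.append(d)
    return survivors


def write_detections_csv(
    dets_by_tile: dict[str, Sequence[Detection]], path: str | os.PathLike
) -> None:
    """Detections as CSV: tile, class_id, confidence, x0, y0, x1, y1."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tile", "class_id", "confidence", "x0", "y0", "x1", "y1"])
        for tile, dets in dets_by_tile.items():
            for d in dets:
                w.writerow([tile, d.class_id, f"{d.confidence:.6f}",
                            d.box.x0, d.box.y0, d.box.x1, d.box.y1])


def read_detections_csv(path: str | os.PathLike) -> dict[str, list[Detection]]:
    """Inverse of :func:`write_detections_csv`."""
    import csv

    out: dict[str, list[Detection]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                det = Detection(
                    BoundingBox(float(row["x0"]), float(row["y0"]),
                                float(row["x1"]), float(row["y1"])),
                    int(row["class_id"]),
                    float(row["confidence"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed detection row") from exc
            out.setdefault(row["tile"], []).append(det)
    return out


# ---------------------------------------------------------------------------
# Reference detector


def _foreground_mask(image: np.ndarray, dist_thr: float = 40.0) -> np.ndarray:
    bg = np.asarray(BACKGROUND_RGB, dtype=np.float64)
    dist = np.sqrt(((image.astype(np.float64) - bg) ** 2).sum(axis=-1))
    return dist > dist_thr


def reference_blob_detector(
    image: np.ndarray,
    palette: Sequence[ClassProfile] = DEFAULT_PALETTE,
    min_area: int = 9,
    conf_scale: float = 60.0,
) -> list[Detection]:
    """Threshold-and-classify detector over synthetic-contrast tiles.

    Foreground pixels (color far from the pale background) are grouped into
    connected components; each component yields a tight box, a class by
    nearest palette centroid in (equivalent radius, mean RGB) feature space,
    and a confidence that decays with that feature distance:
    ``conf = exp(-d / conf_scale)``, clipped to [0, 1].
    """
    mask = _foreground_mask(image)
    labels = measure.label(mask, connectivity=2)
    dets: list[Detection] = []
    if labels.max() == 0:
        return dets

    centroids = np.array(
        [[p.mean_radius_px, *p.fill_rgb] for p in palette], dtype=np.float64
    )
    # radius differences weighted up so size separates same-hue classes
    weights = np.array([3.0, 1.0, 1.0, 1.0])

    for region in measure.regionprops(labels, intensity_image=image):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        radius = math.sqrt(region.area / math.pi)
        mean_rgb = region.image_intensity[region.image].reshape(-1, 3).mean(axis=0)
        feat = np.array([radius, *mean_rgb])
        d = np.sqrt((((centroids - feat) * weights) ** 2).sum(axis=1))
        cid = int(np.argmin(d))
        conf = float(np.clip(math.exp(-d[cid] / conf_scale), 0.0, 1.0))
        dets.append(Detection(BoundingBox(x0, y0, x1, y1), cid, conf))
    return dets
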
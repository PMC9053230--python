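"""Tile-grid construction over a slide, ROI classification, and binary metrics.

Tiles are sampled from the center of each cell of a uniform grid (default 15
rows x 20 columns) so that the whole slide is covered evenly, then clamped —
never padded — to the slide bounds.  A pluggable ROI backend scores each tile
in [0, 1]; tiles at or above the decision threshold are "appropriate" for
cytology.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from skimage import measure
from sklearn.metrics import roc_auc_score

from .taxonomy import BACKGROUND_RGB


@dataclass(frozen=True)
class GridSpec:
    rows: int = 15
    cols: int = 20
    tile_size_px: int = 512

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.tile_size_px < 32:
            raise ValueError("tile_size_px must be >= 32")


@dataclass(frozen=True)
class TileRef:
    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int


@dataclass(frozen=True)
class ROIPrediction:
    tile: TileRef
    score: float
    label: str  # appropriate | inappropriate


class SlideSource(Protocol):
    """Reader contract: dimensions plus random-access region reads."""

    @property
    def width(self) -> int: ...

    @property
    def height(self) -> int: ...

    def read_region(self, x0: int, y0: int, width: int, height: int) -> np.ndarray: ...


def build_grid(slide_width: int, slide_height: int, grid: GridSpec = GridSpec()) -> list[TileRef]:
    """One tile per grid cell, centered on the cell center, clamped in-bounds.

    Returned in row-major order; cell (r, c) has center
    ``((c + 0.5) * W / cols, (r + 0.5) * H / rows)``.
    """
    ts = grid.tile_size_px
    if slide_width < ts or slide_height < ts:
        raise ValueError(
            f"slide {slide_width}x{slide_height} smaller than one {ts}px tile"
        )
    tiles = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            cx = (c + 0.5) * slide_width / grid.cols
            cy = (r + 0.5) * slide_height / grid.rows
            x0 = int(round(cx - ts / 2))
            y0 = int(round(cy - ts / 2))
            x0 = min(max(x0, 0), slide_width - ts)
            y0 = min(max(y0, 0), slide_height - ts)
            tiles.append(TileRef(r, c, x0, y0, ts, ts))
    return tiles


def classify_tiles(
    backend: Callable[[np.ndarray], float],
    slide: SlideSource,
    tiles: Sequence[TileRef],
    threshold: float = 0.5,
) -> list[ROIPrediction]:
    """Score every tile with ``backend``; label = appropriate iff score >= threshold."""
    preds = []
    for t in tiles:
        img = slide.read_region(t.x0, t.y0, t.width, t.height)
        score = float(backend(img))
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"backend score {score} outside [0, 1] for tile {t}")
        label = "appropriate" if score >= threshold else "inappropriate"
        preds.append(ROIPrediction(t, score, label))
    return preds


def reference_roi_backend(
    image: np.ndarray,
    fg_lo: float = 0.004,
    fg_hi: float = 0.15,
    tint_scale: float = 25.0,
    comp_area_band: tuple[int, int] = (20, 8000),
) -> float:
    """Heuristic ROI score for synthetic-contrast tiles, in [0, 1].

    The score is the product of three factors, each monotone in its feature:

    * foreground fraction must sit in ``[fg_lo, fg_hi]`` (too little = empty
      tile, too much = dense overlapping smear); the factor falls linearly
      to 0 outside the band;
    * background tint must sit near the reference background color; the
      factor decays exponentially with the mean background color deviation
      (over-stained tiles are heavily tinted);
    * at least one connected foreground component in a plausible single-cell
      area band must be present (a segmentable cell).
    """
    img = image.astype(np.float64)
    bg = np.asarray(BACKGROUND_RGB, dtype=np.float64)
    dist = np.sqrt(((img - bg) ** 2).sum(axis=-1))
    fg = dist > 40.0
    frac = float(fg.mean())

    if frac < fg_lo:
        s_frac = frac / fg_lo
    elif frac > fg_hi:
        s_frac = max(0.0, 1.0 - (frac - fg_hi) / fg_hi)
    else:
        s_frac = 1.0

    bg_pixels = img[~fg]
    if bg_pixels.size == 0:
        s_tint = 0.0
    else:
        dev = float(np.abs(bg_pixels.mean(axis=0) - bg).mean())
        s_tint = math.exp(-dev / tint_scale)

    labels = measure.label(fg, connectivity=2)
    n_band = 0
    if labels.max():
        areas = np.bincount(labels.ravel())[1:]
        n_band = int(((areas >= comp_area_band[0]) & (areas <= comp_area_band[1])).sum())
    s_comp = 1.0 if n_band >= 1 else 0.0

    return float(np.clip(s_frac * s_tint * s_comp, 0.0, 1.0))


@dataclass(frozen=True)
class BinaryEvalCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class BinaryMetrics:
    """Eqs. of the ROI evaluation; metrics with a zero denominator are None."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    npv: float | None


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def binary_metrics(counts: BinaryEvalCounts) -> BinaryMetrics:
    """Accuracy, precision, recall, specificity and NPV from confusion counts.

    A metric whose denominator is zero is reported as None (undefined),
    never silently coerced to 0 or 1.
    """
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return BinaryMetrics(
        accuracy=_safe_div(counts.tp + counts.tn, total),
        precision=_safe_div(counts.tp, counts.tp + counts.fp),
        recall=_safe_div(counts.tp, counts.tp + counts.fn),
        specificity=_safe_div(counts.tn, counts.tn + counts.fp),
        npv=_safe_div(counts.tn, counts.tn + counts.fn),
    )


def confusion_counts(
    predicted: Sequence[str], actual: Sequence[str], positive: str = "appropriate"
) -> BinaryEvalCounts:
    """Tally a label-pair list into TP/TN/FP/FN with the given positive class."""
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must have equal length")
    tp = sum(p == positive and a == positive for p, a in zip(predicted, actual))
    tn = sum(p != positive and a != positive for p, a in zip(predicted, actual))
    fp = sum(p == positive and a != positive for p, a in zip(predicted, actual))
    fn = sum(p != positive and a == positive for p, a in zip(predicted, actual))
    return BinaryEvalCounts(tp, tn, fp, fn)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic; ties averaged)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def grouped_kfold(slide_ids: Sequence[str], k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """Patient-level k-fold split: shuffle unique slide ids, deal into k folds.

    Returns (train_ids, test_ids) per fold; no id appears in both partitions
    of any fold.
    """
    unique = sorted(set(slide_ids))
    if k < 2 or k > len(unique):
        raise ValueError("k must be between 2 and the number of distinct slides")
    rng = np.random.default_rng(seed)
    perm = [unique[i] for i in rng.permutation(len(unique))]
    folds = [perm[i::k] for i in range(k)]
    out = []
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(x for j, f in enumerate(folds) if j != i for x in f)
        out.append((train, test))
    return out


def tile_stem(slide_id: str, tile: TileRef) -> str:
    return f"{slide_id}_r{tile.row}_c{tile.col}"


def write_predictions_csv(preds: Sequence[ROIPrediction], path: str | os.PathLike,
                          slide_id: str = "slide") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tile", "row", "col", "score", "label"])
        for p in preds:
            w.writerow([tile_stem(slide_id, p.tile), p.tile.row, p.tile.col,
                        f"{p.score:.6f}", p.label])
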
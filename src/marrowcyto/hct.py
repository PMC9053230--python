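"""Histogram of Cell Types, its accumulation, and convergence of the count.

Each appropriate (ROI) tile yields a Histogram of Cell Types (HCT): the
per-class count of detected objects.  Tile HCTs are accumulated into an
Integrated HCT (IHCT), a running cytological fingerprint of the slide.  After
each new tile the chi-square distance

    chi2(x, y) = 1/2 * sum_i (x_i - y_i)^2 / (x_i + y_i)

is computed between the convergence feature vectors of the IHCT before and
after the tile.  The feature vector holds the proportions of the 12 nucleated
differential count (NDC) classes plus, optionally, the myeloid-to-erythroid
ratio squashed to [0, 1).  Once at least ``min_tiles`` tiles have been
accumulated and the last ``patience`` distances all fall below ``tau``, the
IHCT is declared converged and represents the completed differential count.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .detection import Detection
from .taxonomy import (
    BM_ME_NUMERATOR_IDS,
    CLASS_IDS,
    CLASS_NAMES,
    N_CLASSES,
    NDC_CLASS_IDS,
    NDC_CLASSES,
)
from .tiling import GridSpec, SlideSource, TileRef, build_grid

_ERYTHROBLAST = CLASS_IDS["erythroblast"]

#: Chi-square distance between two NDC-proportion vectors is at most 1, so a
#: step against an empty histogram is recorded as this ceiling.
_MAX_DISTANCE = 1.0


@dataclass
class HCT:
    """Per-tile class-count vector."""

    counts: np.ndarray  # shape (19,), nonnegative ints
    tile: TileRef | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"counts must have shape ({N_CLASSES},)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())


def hct_from_detections(
    dets: Sequence[Detection], conf_thr: float = 0.75, tile: TileRef | None = None
) -> HCT:
    """Count detections with confidence >= ``conf_thr`` per class."""
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for d in dets:
        if d.confidence >= conf_thr:
            counts[d.class_id] += 1
    return HCT(counts, tile)


def chi_square_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Symmetric chi-square histogram distance; 0/0 terms contribute 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("chi-square distance requires nonnegative entries")
    s = x + y
    d = x - y
    mask = s > 0
    return float(0.5 * np.sum(d[mask] ** 2 / s[mask]))


def bm_me_ratio(counts: Sequence[float]) -> float | None:
    """Myeloid-to-erythroid ratio; None (undefined) when erythroblasts absent.

    Numerator: blast + promyelocyte + myelocyte + metamyelocyte + neutrophil
    + eosinophil.  Denominator: erythroblast.
    """
    counts = np.asarray(counts, dtype=np.float64)
    den = counts[_ERYTHROBLAST]
    if den == 0:
        return None
    return float(counts[list(BM_ME_NUMERATOR_IDS)].sum() / den)


@dataclass(frozen=True)
class NDCFeatureVector:
    """Convergence features: 12 NDC proportions plus the (optional) BM_ME ratio."""

    proportions: np.ndarray  # shape (12,); zeros when no NDC cell counted
    bm_me: float | None
    n_ndc_cells: int


def feature_vector(counts: Sequence[float]) -> NDCFeatureVector:
    """NDC proportions and BM_ME ratio of a 19-class count vector."""
    counts = np.asarray(counts, dtype=np.float64)
    ndc = counts[list(NDC_CLASS_IDS)]
    total = ndc.sum()
    props = ndc / total if total > 0 else np.zeros(len(NDC_CLASS_IDS))
    return NDCFeatureVector(props, bm_me_ratio(counts), int(total))


def _step_distance(
    prev: NDCFeatureVector, cur: NDCFeatureVector, bm_me_in_distance: bool = True
) -> float:
    """Chi-square distance between successive convergence feature vectors.

    The BM_ME ratio enters squashed to s = bm/(1+bm) so the unbounded ratio
    cannot dominate 12 bounded proportions; if it is undefined on either
    side, the component is omitted from both vectors.  A step against an
    empty (zero-cell) histogram is reported at the distance ceiling.
    """
    if prev.n_ndc_cells == 0 or cur.n_ndc_cells == 0:
        return _MAX_DISTANCE
    a = list(prev.proportions)
    b = list(cur.proportions)
    if bm_me_in_distance and prev.bm_me is not None and cur.bm_me is not None:
        a.append(prev.bm_me / (1.0 + prev.bm_me))
        b.append(cur.bm_me / (1.0 + cur.bm_me))
    return chi_square_distance(a, b)


def check_convergence(
    trace: Sequence[float],
    min_tiles: int = 80,
    tau: float = 1e-4,
    patience: int = 5,
    n_tiles: int | None = None,
) -> bool:
    """Converged iff >= ``min_tiles`` tiles and the last ``patience`` distances < tau.

    ``n_tiles`` defaults to ``len(trace) + 1`` (one distance per accumulated
    tile after the first).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if n_tiles is None:
        n_tiles = len(trace) + 1
    if n_tiles < min_tiles or len(trace) < patience:
        return False
    return all(d < tau for d in list(trace)[-patience:])


@dataclass
class IHCT:
    """Integrated HCT: accumulated counts plus the convergence trace."""

    min_tiles: int = 80
    tau: float = 1e-4
    patience: int = 5
    bm_me_in_distance: bool = True
    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))
    n_tiles: int = 0
    distance_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    def add(self, hct: HCT | np.ndarray) -> float | None:
        """Accumulate one tile; returns the chi-square step distance (None first tile)."""
        counts = hct.counts if isinstance(hct, HCT) else np.asarray(hct, dtype=np.int64)
        prev_fv = feature_vector(self.counts) if self.n_tiles > 0 else None
        self.counts = self.counts + counts
        self.n_tiles += 1
        if prev_fv is None:
            return None
        d = _step_distance(prev_fv, feature_vector(self.counts), self.bm_me_in_distance)
        self.distance_trace.append(d)
        self.converged = check_convergence(
            self.distance_trace, self.min_tiles, self.tau, self.patience, n_tiles=self.n_tiles
        )
        return d


def accumulate_stream(
    tile_counts: np.ndarray,
    min_tiles: int = 80,
    tau: float = 1e-4,
    patience: int = 5,
    bm_me_in_distance: bool = True,
    stop_at_convergence: bool = True,
) -> tuple[IHCT, int | None]:
    """Feed a (n_tiles, 19) count matrix into an IHCT.

    Returns the IHCT and the 1-based tile index at which convergence was
    declared (None if never).
    """
    ihct = IHCT(min_tiles, tau, patience, bm_me_in_distance)
    converged_at = None
    for i, row in enumerate(np.asarray(tile_counts, dtype=np.int64), start=1):
        ihct.add(HCT(row))
        if ihct.converged and converged_at is None:
            converged_at = i
            if stop_at_convergence:
                break
    return ihct, converged_at


@dataclass
class NDCReport:
    """Converged (or exhausted) nucleated differential cell count."""

    slide_id: str
    counts: dict[str, int]
    percentages: dict[str, float]          # of all counted objects
    ndc_percentages: dict[str, float]      # of NDC cells only
    bm_me: float | None
    final_distance: float | None
    n_tiles_visited: int                   # grid tiles examined
    n_roi_tiles: int                       # appropriate tiles accumulated
    n_cells: int
    converged: bool
    distance_trace: list[float] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "count", "percent_of_objects", "percent_of_ndc"])
            for name in CLASS_NAMES:
                w.writerow([
                    name,
                    self.counts[name],
                    f"{self.percentages[name]:.4f}",
                    f"{self.ndc_percentages.get(name, float('nan')):.4f}" if name in NDC_CLASSES else "",
                ])
            w.writerow([])
            w.writerow(["bm_me", self.bm_me if self.bm_me is not None else "undefined"])
            w.writerow(["final_chi_square", self.final_distance])
            w.writerow(["n_tiles_visited", self.n_tiles_visited])
            w.writerow(["n_roi_tiles", self.n_roi_tiles])
            w.writerow(["n_cells", self.n_cells])
            w.writerow(["converged", self.converged])

    def write_trace_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["roi_tile_index", "chi_square_distance"])
            for i, d in enumerate(self.distance_trace, start=2):
                w.writerow([i, d])


def _report_from_ihct(
    ihct: IHCT, slide_id: str, n_visited: int
) -> NDCReport:
    counts = {name: int(ihct.counts[i]) for i, name in enumerate(CLASS_NAMES)}
    total = ihct.n_cells
    percentages = {
        name: (100.0 * c / total if total else 0.0) for name, c in counts.items()
    }
    fv = feature_vector(ihct.counts)
    ndc_pct = {
        name: 100.0 * float(fv.proportions[i]) for i, name in enumerate(NDC_CLASSES)
    }
    return NDCReport(
        slide_id=slide_id,
        counts=counts,
        percentages=percentages,
        ndc_percentages=ndc_pct,
        bm_me=fv.bm_me,
        final_distance=ihct.distance_trace[-1] if ihct.distance_trace else None,
        n_tiles_visited=n_visited,
        n_roi_tiles=ihct.n_tiles,
        n_cells=total,
        converged=ihct.converged,
        distance_trace=list(ihct.distance_trace),
    )


def run_ndc(
    slide: SlideSource,
    roi_backend: Callable[[np.ndarray], float],
    detector_backend: Callable[[np.ndarray], Sequence[Detection]],
    grid: GridSpec = GridSpec(),
    roi_threshold: float = 0.5,
    conf_thr: float = 0.75,
    min_tiles: int = 80,
    tau: float = 1e-4,
    patience: int = 5,
    bm_me_in_distance: bool = True,
    shuffle_seed: int | None = None,
    max_tiles: int | None = None,
    slide_id: str = "slide",
) -> NDCReport:
    """End-to-end differential count over one slide.

    Grid tiles are visited in row-major order (or a seeded shuffle); each is
    scored by the ROI backend, and appropriate tiles are run through the
    detector, counted into an HCT, and accumulated until the IHCT converges
    or the grid is exhausted (which yields a non-converged report).  Raises
    if no tile is judged appropriate.
    """
    tiles = build_grid(slide.width, slide.height, grid)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        tiles = [tiles[i] for i in rng.permutation(len(tiles))]
    if max_tiles is not None:
        tiles = tiles[:max_tiles]

    ihct = IHCT(min_tiles, tau, patience, bm_me_in_distance)
    n_visited = 0
    for tref in tiles:
        img = slide.read_region(tref.x0, tref.y0, tref.width, tref.height)
        n_visited += 1
        score = float(roi_backend(img))
        if score < roi_threshold:
            continue
        dets = detector_backend(img)
        ihct.add(hct_from_detections(dets, conf_thr, tref))
        if ihct.converged:
            break

    if ihct.n_tiles == 0:
        raise ValueError("no appropriate tile found on the slide")
    return _report_from_ihct(ihct, slide_id, n_visited)
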
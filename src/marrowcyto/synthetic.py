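"""Synthetic bone marrow aspirate slides with exact ground truth.

Real aspirate whole-slide images cannot be redistributed, so the pipeline is
exercised on synthetic slides that reproduce the *statistical* structure the
method assumes: a grid of 512x512 tiles, a minority of tiles suitable for
cytology ("appropriate"), and within those a stationary per-class mixture of
cellular and non-cellular objects.  Cells are rendered as colored ellipses
with class-specific size and hue — crude morphology, exact annotations.

Inappropriate tiles are produced in three documented failure modes mirroring
the criteria an ROI tile must satisfy (thin, well spread, not overstained,
containing segmentable cells):

* ``overlap``   — a dense, mutually overlapping smear;
* ``overstain`` — a global stain-like color cast;
* ``empty``     — near-empty background with at most a couple of debris blobs.

All randomness flows from explicit integer seeds; equal seeds give
bit-identical rasters and annotation lists.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import draw as skdraw

from .detection import Annotation, BoundingBox, write_yolo_txt
from .taxonomy import (
    BACKGROUND_RGB,
    CLASS_IDS,
    CLASS_NAMES,
    DEFAULT_PALETTE,
    N_CLASSES,
    ClassProfile,
)

TILE_SIZE = 512

FAILURE_MODES = ("overlap", "overstain", "empty")


@dataclass(frozen=True)
class DiagnosticProfile:
    """Mixture of object classes emulating one diagnostic regime.

    ``mixture`` gives the probability that a sampled object belongs to each
    of the 19 classes; ``cells_per_roi_tile_mean`` is the Poisson mean number
    of objects per appropriate tile; ``roi_fraction`` is the probability that
    a grid tile is appropriate for cytology.
    """

    name: str
    mixture: tuple[float, ...]
    cells_per_roi_tile_mean: float = 10.0
    roi_fraction: float = 0.15

    def __post_init__(self) -> None:
        if len(self.mixture) != N_CLASSES:
            raise ValueError(f"mixture must have {N_CLASSES} entries")
        if any(p < 0 for p in self.mixture):
            raise ValueError("mixture probabilities must be nonnegative")
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError(f"mixture sums to {sum(self.mixture)}, not 1")
        if self.cells_per_roi_tile_mean <= 0:
            raise ValueError("cells_per_roi_tile_mean must be positive")
        if not 0 < self.roi_fraction <= 1:
            raise ValueError("roi_fraction must lie in (0, 1]")


def _mixture(**kwargs: float) -> tuple[float, ...]:
    mix = [0.0] * N_CLASSES
    for name, p in kwargs.items():
        mix[CLASS_IDS[name]] = p
    total = sum(mix)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"preset mixture sums to {total}")
    return tuple(mix)


# Preset mixtures are package-defined placeholders capturing the qualitative
# regimes (blast fraction, erythroid fraction) of the three diagnostic
# groups; they are NOT clinically calibrated frequencies.
_PRESETS: dict[str, DiagnosticProfile] = {
    "normal": DiagnosticProfile(
        "normal",
        _mixture(
            neutrophil=0.21, metamyelocyte=0.06, myelocyte=0.06, promyelocyte=0.03,
            blast=0.02, erythroblast=0.22, megakaryocyte_nucleus=0.002,
            lymphocyte=0.12, monocyte=0.04, plasma_cell=0.02, eosinophil=0.03,
            basophil=0.005, megakaryocyte=0.003, debris=0.03, histiocyte=0.01,
            mast_cell=0.002, platelet=0.09, platelet_clump=0.02, other=0.028,
        ),
        roi_fraction=0.15,
    ),
    "mds_like": DiagnosticProfile(
        "mds_like",
        _mixture(
            neutrophil=0.14, metamyelocyte=0.05, myelocyte=0.05, promyelocyte=0.03,
            blast=0.08, erythroblast=0.28, megakaryocyte_nucleus=0.004,
            lymphocyte=0.10, monocyte=0.04, plasma_cell=0.02, eosinophil=0.02,
            basophil=0.005, megakaryocyte=0.004, debris=0.05, histiocyte=0.012,
            mast_cell=0.003, platelet=0.07, platelet_clump=0.012, other=0.03,
        ),
        roi_fraction=0.12,
    ),
    "aml_like": DiagnosticProfile(
        "aml_like",
        _mixture(
            neutrophil=0.08, metamyelocyte=0.03, myelocyte=0.03, promyelocyte=0.03,
            blast=0.38, erythroblast=0.14, megakaryocyte_nucleus=0.002,
            lymphocyte=0.08, monocyte=0.03, plasma_cell=0.01, eosinophil=0.01,
            basophil=0.004, megakaryocyte=0.002, debris=0.05, histiocyte=0.01,
            mast_cell=0.002, platelet=0.07, platelet_clump=0.01, other=0.03,
        ),
        roi_fraction=0.10,
    ),
}


def make_diagnostic_profile(name: str) -> DiagnosticProfile:
    """Return one of the fixed diagnostic presets: normal, mds_like, aml_like."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Tile rendering


def _ellipse_axes(radius: float, ecc: float) -> tuple[float, float]:
    # area-preserving: a*b = radius^2 with b/a = sqrt(1 - ecc^2)
    k = (1.0 - ecc * ecc) ** 0.25
    return radius / k, radius * k


def _aabb_halfextents(a: float, b: float, theta: float) -> tuple[float, float]:
    ex = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ey = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    return ex, ey


def _box_iou_xyxy(p: tuple[float, float, float, float], q: tuple[float, float, float, float]) -> float:
    ix = min(p[2], q[2]) - max(p[0], q[0])
    iy = min(p[3], q[3]) - max(p[1], q[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    pa = (p[2] - p[0]) * (p[3] - p[1])
    qa = (q[2] - q[0]) * (q[3] - q[1])
    return inter / (pa + qa - inter)


def _background(rng: np.random.Generator, size: int = TILE_SIZE) -> np.ndarray:
    base = np.asarray(BACKGROUND_RGB, dtype=np.float64)
    noise = rng.normal(0.0, 2.5, size=(size, size, 3))
    return np.clip(base + noise, 0, 255).astype(np.uint8)


def _draw_cells(
    image: np.ndarray,
    rng: np.random.Generator,
    n_cells: int,
    mixture: Sequence[float],
    palette: Sequence[ClassProfile],
    max_overlap_iou: float = 0.1,
    max_rejections: int = 100,
) -> list[Annotation]:
    """Place ``n_cells`` ellipses; rejection-sample centers to cap box overlap."""
    size = image.shape[0]
    placed_boxes: list[tuple[float, float, float, float]] = []
    anns: list[Annotation] = []
    for _ in range(n_cells):
        cid = int(rng.choice(N_CLASSES, p=np.asarray(mixture)))
        prof = palette[cid]
        radius = max(2.5, rng.normal(prof.mean_radius_px, prof.radius_sd_px))
        theta = rng.uniform(0, math.pi)
        a, b = _ellipse_axes(radius, prof.eccentricity)
        ex, ey = _aabb_halfextents(a, b, theta)
        ex, ey = min(ex, size / 2 - 1), min(ey, size / 2 - 1)

        cand = None
        for _ in range(max_rejections):
            cx = rng.uniform(ex + 1, size - ex - 1)
            cy = rng.uniform(ey + 1, size - ey - 1)
            box = (cx - ex, cy - ey, cx + ex, cy + ey)
            if max_overlap_iou >= 1.0 or all(
                _box_iou_xyxy(box, pb) <= max_overlap_iou for pb in placed_boxes
            ):
                cand = (cx, cy, box)
                break
        if cand is None:  # give up on separation, accept the last draw
            cand = (cx, cy, box)
        cx, cy, box = cand
        placed_boxes.append(box)

        rr, cc = skdraw.ellipse(cy, cx, b, a, shape=(size, size), rotation=theta)
        if rr.size == 0:
            continue
        color = np.asarray(prof.fill_rgb, dtype=np.float64)
        jitter = rng.normal(0.0, 4.0, size=3)
        image[rr, cc] = np.clip(color + jitter, 0, 255).astype(np.uint8)
        tight = BoundingBox(
            float(cc.min()), float(rr.min()), float(cc.max() + 1), float(rr.max() + 1)
        )
        anns.append(Annotation(tight, cid))
    return anns


@dataclass(frozen=True)
class RenderedTile:
    image: np.ndarray
    annotations: list[Annotation]
    appropriate: bool
    failure_mode: str | None  # set only for inappropriate tiles


def render_tile_full(
    profile: DiagnosticProfile,
    appropriate: bool,
    seed: int,
    palette: Sequence[ClassProfile] = DEFAULT_PALETTE,
    size: int = TILE_SIZE,
) -> RenderedTile:
    """Render one tile and report the inappropriate-tile failure mode used."""
    rng = np.random.default_rng(seed)
    image = _background(rng, size)
    if appropriate:
        n = int(rng.poisson(profile.cells_per_roi_tile_mean))
        anns = _draw_cells(image, rng, n, profile.mixture, palette)
        return RenderedTile(image, anns, True, None)

    mode = FAILURE_MODES[int(rng.integers(len(FAILURE_MODES)))]
    if mode == "overlap":
        n = int(rng.poisson(40 * profile.cells_per_roi_tile_mean))
        anns = _draw_cells(image, rng, n, profile.mixture, palette, max_overlap_iou=1.0)
    elif mode == "overstain":
        n = int(rng.poisson(profile.cells_per_roi_tile_mean))
        anns = _draw_cells(image, rng, n, profile.mixture, palette)
        tint = np.array([140.0, 70.0, 160.0])
        image = np.clip(0.45 * image + 0.55 * tint, 0, 255).astype(np.uint8)
    else:  # empty: background with at most a couple of debris specks
        n = int(rng.integers(0, 3))
        debris_only = [0.0] * N_CLASSES
        debris_only[CLASS_IDS["debris"]] = 1.0
        anns = _draw_cells(image, rng, n, debris_only, palette)
    return RenderedTile(image, anns, False, mode)


def render_tile(
    profile: DiagnosticProfile,
    appropriate: bool,
    seed: int,
    palette: Sequence[ClassProfile] = DEFAULT_PALETTE,
    size: int = TILE_SIZE,
) -> tuple[np.ndarray, list[Annotation]]:
    """Render a single tile (default 512x512); returns (image, annotations)."""
    t = render_tile_full(profile, appropriate, seed, palette, size)
    return t.image, t.annotations


def tile_seed(slide_seed: int, row: int, col: int) -> int:
    """Deterministic per-tile seed so lazy and eager rendering agree."""
    return int(np.random.SeedSequence([slide_seed, row, col]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# Slide rendering


@dataclass
class SyntheticSlide:
    """A fully rendered synthetic slide with ground truth."""

    image: np.ndarray
    annotations: list[Annotation]
    roi_labels: dict[tuple[int, int], str]  # (row, col) -> appropriate|inappropriate
    seed: int
    profile_name: str
    rows: int
    cols: int
    tile_size: int = TILE_SIZE
    failure_modes: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def read_region(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        return self.image[y0 : y0 + height, x0 : x0 + width]


def sample_roi_labels(
    profile: DiagnosticProfile, rows: int, cols: int, seed: int
) -> dict[tuple[int, int], str]:
    """Each grid tile is independently appropriate with prob ``roi_fraction``."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    labels = {}
    for r in range(rows):
        for c in range(cols):
            ok = rng.uniform() < profile.roi_fraction
            labels[(r, c)] = "appropriate" if ok else "inappropriate"
    return labels


def render_slide(
    profile: DiagnosticProfile,
    rows: int = 15,
    cols: int = 20,
    seed: int = 0,
    palette: Sequence[ClassProfile] = DEFAULT_PALETTE,
) -> SyntheticSlide:
    """Render a full slide raster covering a rows x cols grid of 512px tiles."""
    labels = sample_roi_labels(profile, rows, cols, seed)
    image = np.empty((rows * TILE_SIZE, cols * TILE_SIZE, 3), dtype=np.uint8)
    annotations: list[Annotation] = []
    modes: dict[tuple[int, int], str] = {}
    for r in range(rows):
        for c in range(cols):
            t = render_tile_full(
                profile, labels[(r, c)] == "appropriate", tile_seed(seed, r, c), palette
            )
            y0, x0 = r * TILE_SIZE, c * TILE_SIZE
            image[y0 : y0 + TILE_SIZE, x0 : x0 + TILE_SIZE] = t.image
            if t.failure_mode is not None:
                modes[(r, c)] = t.failure_mode
            for ann in t.annotations:
                b = ann.box
                annotations.append(
                    Annotation(BoundingBox(b.x0 + x0, b.y0 + y0, b.x1 + x0, b.y1 + y0), ann.class_id)
                )
    return SyntheticSlide(image, annotations, labels, seed, profile.name, rows, cols,
                          failure_modes=modes)


class SyntheticSlideReader:
    """Lazy slide source: renders grid tiles on demand, never the full raster.

    Implements the same reader contract as :class:`SyntheticSlide`
    (``width``, ``height``, ``read_region``) and produces pixel-identical
    regions, so memory stays bounded for large grids.
    """

    def __init__(
        self,
        profile: DiagnosticProfile,
        rows: int = 15,
        cols: int = 20,
        seed: int = 0,
        palette: Sequence[ClassProfile] = DEFAULT_PALETTE,
    ) -> None:
        self.profile = profile
        self.rows, self.cols, self.seed = rows, cols, seed
        self.palette = palette
        self.roi_labels = sample_roi_labels(profile, rows, cols, seed)
        self._cache: dict[tuple[int, int], RenderedTile] = {}

    @property
    def width(self) -> int:
        return self.cols * TILE_SIZE

    @property
    def height(self) -> int:
        return self.rows * TILE_SIZE

    def tile(self, row: int, col: int) -> RenderedTile:
        key = (row, col)
        if key not in self._cache:
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = render_tile_full(
                self.profile,
                self.roi_labels[key] == "appropriate",
                tile_seed(self.seed, row, col),
                self.palette,
            )
        return self._cache[key]

    def read_region(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        out = np.empty((height, width, 3), dtype=np.uint8)
        r0, r1 = y0 // TILE_SIZE, (y0 + height - 1) // TILE_SIZE
        c0, c1 = x0 // TILE_SIZE, (x0 + width - 1) // TILE_SIZE
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                timg = self.tile(r, c).image
                ty0, tx0 = r * TILE_SIZE, c * TILE_SIZE
                ys = slice(max(y0, ty0), min(y0 + height, ty0 + TILE_SIZE))
                xs = slice(max(x0, tx0), min(x0 + width, tx0 + TILE_SIZE))
                out[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0] = timg[
                    ys.start - ty0 : ys.stop - ty0, xs.start - tx0 : xs.stop - tx0
                ]
        return out


# ---------------------------------------------------------------------------
# Augmentation


def augment_tile(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    op: str,
    amount: float | None = None,
) -> tuple[np.ndarray, list[Annotation]]:
    """Apply one augmentation; geometric ops move boxes with the pixels.

    ``hflip``/``vflip``/``rot90`` are exact involutions/rotations on both
    pixels and boxes; ``brightness`` (additive, amount in [-128, 128]) and
    ``contrast`` (multiplicative about the mean, amount in (0, 4]) leave
    boxes untouched.
    """
    h, w = image.shape[:2]
    if op == "hflip":
        out = image[:, ::-1].copy()
        boxes = [Annotation(BoundingBox(w - a.box.x1, a.box.y0, w - a.box.x0, a.box.y1), a.class_id)
                 for a in annotations]
    elif op == "vflip":
        out = image[::-1, :].copy()
        boxes = [Annotation(BoundingBox(a.box.x0, h - a.box.y1, a.box.x1, h - a.box.y0), a.class_id)
                 for a in annotations]
    elif op == "rot90":  # counterclockwise, numpy convention
        out = np.rot90(image).copy()
        boxes = [Annotation(BoundingBox(a.box.y0, w - a.box.x1, a.box.y1, w - a.box.x0), a.class_id)
                 for a in annotations]
    elif op == "brightness":
        if amount is None or not -128 <= amount <= 128:
            raise ValueError("brightness amount must lie in [-128, 128]")
        out = np.clip(image.astype(np.float64) + amount, 0, 255).astype(np.uint8)
        boxes = list(annotations)
    elif op == "contrast":
        if amount is None or not 0 < amount <= 4:
            raise ValueError("contrast amount must lie in (0, 4]")
        mean = image.astype(np.float64).mean()
        out = np.clip(mean + amount * (image.astype(np.float64) - mean), 0, 255).astype(np.uint8)
        boxes = list(annotations)
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return out, boxes


# ---------------------------------------------------------------------------
# Disk output (PNG tiles + YOLO txt + slide manifest)


def save_tile(
    directory: str | os.PathLike,
    stem: str,
    image: np.ndarray,
    annotations: Sequence[Annotation],
) -> tuple[str, str]:
    """Write ``{stem}.png`` and the matching YOLO ``{stem}.txt``."""
    os.makedirs(directory, exist_ok=True)
    png = os.path.join(directory, f"{stem}.png")
    txt = os.path.join(directory, f"{stem}.txt")
    Image.fromarray(image).save(png)
    write_yolo_txt(annotations, txt, image.shape[1], image.shape[0])
    return png, txt


def write_slide_manifest(slide: SyntheticSlide, path: str | os.PathLike) -> None:
    manifest = {
        "seed": slide.seed,
        "profile": slide.profile_name,
        "grid": {"rows": slide.rows, "cols": slide.cols, "tile_size": slide.tile_size},
        "roi_labels": {f"{r},{c}": lab for (r, c), lab in sorted(slide.roi_labels.items())},
        "failure_modes": {f"{r},{c}": m for (r, c), m in sorted(slide.failure_modes.items())},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# Count-level stream simulation (no rendering), for convergence studies


def simulate_hct_stream(
    profile: DiagnosticProfile,
    n_tiles: int,
    seed: int,
    drift_to: DiagnosticProfile | None = None,
    drift_mode: str = "linear",
) -> np.ndarray:
    """Per-tile class-count vectors drawn straight from the mixture.

    With ``drift_to`` the stream is nonstationary: the mixture either
    interpolates linearly from ``profile`` to the target across the stream
    (``drift_mode="linear"``) or switches abruptly to the target at the
    midpoint (``drift_mode="switch"``, a regime change).  Returns an
    ``(n_tiles, 19)`` integer array.
    """
    if drift_mode not in ("linear", "switch"):
        raise ValueError("drift_mode must be 'linear' or 'switch'")
    rng = np.random.default_rng(seed)
    base = np.asarray(profile.mixture)
    target = np.asarray(drift_to.mixture) if drift_to is not None else base
    counts = np.zeros((n_tiles, N_CLASSES), dtype=np.int64)
    for t in range(n_tiles):
        if drift_mode == "switch":
            mix = target if t >= n_tiles // 2 else base
        else:
            frac = t / max(n_tiles - 1, 1)
            mix = (1 - frac) * base + frac * target
        n = rng.poisson(profile.cells_per_roi_tile_mean)
        counts[t] = rng.multinomial(n, mix / mix.sum())
    return counts
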
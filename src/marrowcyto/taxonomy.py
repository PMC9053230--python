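"""The 19-class bone marrow object taxonomy and its rendering palette.

Bone marrow aspirate cytology distinguishes nucleated hematopoietic cells
(the classes entering the nucleated differential cell count, NDC) from
cellular and non-cellular objects that are counted but not part of the
traditional differential (platelets, debris, megakaryocyte nuclei, ...).
Every stage of the pipeline — synthesis, detection, histogram accumulation,
evaluation — indexes objects by the integer ``class_id`` defined here.
"""

from __future__ import annotations

from dataclasses import dataclass


CLASS_NAMES: tuple[str, ...] = (
    "neutrophil",            # 0
    "metamyelocyte",         # 1
    "myelocyte",             # 2
    "promyelocyte",          # 3
    "blast",                 # 4
    "erythroblast",          # 5
    "megakaryocyte_nucleus", # 6
    "lymphocyte",            # 7
    "monocyte",              # 8
    "plasma_cell",           # 9
    "eosinophil",            # 10
    "basophil",              # 11
    "megakaryocyte",         # 12
    "debris",                # 13
    "histiocyte",            # 14
    "mast_cell",             # 15
    "platelet",              # 16
    "platelet_clump",        # 17
    "other",                 # 18
)

N_CLASSES = len(CLASS_NAMES)

CLASS_IDS: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Classes entering the nucleated differential cell count and the
#: convergence feature vector (12 classes).
NDC_CLASSES: tuple[str, ...] = (
    "neutrophil",
    "metamyelocyte",
    "myelocyte",
    "promyelocyte",
    "blast",
    "erythroblast",
    "lymphocyte",
    "monocyte",
    "plasma_cell",
    "eosinophil",
    "basophil",
    "megakaryocyte",
)
NDC_CLASS_IDS: tuple[int, ...] = tuple(CLASS_IDS[n] for n in NDC_CLASSES)

#: Numerator classes of the myeloid-to-erythroid (BM_ME) ratio.
BM_ME_NUMERATOR: tuple[str, ...] = (
    "blast",
    "promyelocyte",
    "myelocyte",
    "metamyelocyte",
    "neutrophil",
    "eosinophil",
)
BM_ME_NUMERATOR_IDS: tuple[int, ...] = tuple(CLASS_IDS[n] for n in BM_ME_NUMERATOR)

#: The 16 classes routinely evaluated in detection benchmarks.  Basophil and
#: mast cell are annotatable and countable but are too rare for stable
#: per-class AP; "other" is a catch-all excluded from class-aware scoring.
EVALUATED_CLASSES: tuple[str, ...] = tuple(
    n for n in CLASS_NAMES if n not in ("basophil", "mast_cell", "other")
)
EVALUATED_CLASS_IDS: tuple[int, ...] = tuple(CLASS_IDS[n] for n in EVALUATED_CLASSES)

#: Low-support classes: evaluable on request, flagged as unstable.
LOW_SUPPORT_CLASSES: tuple[str, ...] = ("basophil", "mast_cell")


@dataclass(frozen=True)
class ClassProfile:
    """Rendering morphology of one object class.

    The synthetic generator draws each object as an ellipse with a
    class-specific size and fill color; the reference detector inverts the
    same feature space (radius, RGB) to classify connected components.
    """

    class_id: int
    name: str
    mean_radius_px: float
    radius_sd_px: float
    fill_rgb: tuple[int, int, int]
    eccentricity: float

    def __post_init__(self) -> None:
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside 0..{N_CLASSES - 1}")
        if CLASS_NAMES[self.class_id] != self.name:
            raise ValueError(f"name {self.name!r} does not match id {self.class_id}")
        if self.mean_radius_px <= 2:
            raise ValueError("mean_radius_px must exceed 2")
        if self.radius_sd_px < 0:
            raise ValueError("radius_sd_px must be nonnegative")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")
        if not all(0 <= c <= 255 for c in self.fill_rgb):
            raise ValueError("fill_rgb components must lie in 0..255")


def _p(cid: int, r: float, sd: float, rgb: tuple[int, int, int], ecc: float) -> ClassProfile:
    return ClassProfile(cid, CLASS_NAMES[cid], r, sd, rgb, ecc)


#: Default palette.  Radii follow the rough size ordering of real marrow
#: objects (platelets tiny, megakaryocytes huge); fill colors are mutually
#: well separated so a nearest-centroid classifier is exercised, not a
#: simulation of Wright-Giemsa staining.
DEFAULT_PALETTE: tuple[ClassProfile, ...] = (
    _p(0, 13.0, 1.2, (150, 80, 170), 0.45),
    _p(1, 14.0, 1.2, (190, 110, 200), 0.40),
    _p(2, 15.0, 1.3, (170, 60, 120), 0.35),
    _p(3, 17.0, 1.4, (120, 40, 140), 0.30),
    _p(4, 16.0, 1.3, (90, 60, 200), 0.30),
    _p(5, 10.0, 0.9, (60, 30, 90), 0.20),
    _p(6, 28.0, 2.5, (100, 20, 60), 0.50),
    _p(7, 9.0, 0.8, (70, 90, 200), 0.15),
    _p(8, 16.0, 1.4, (140, 140, 220), 0.50),
    _p(9, 12.0, 1.0, (40, 80, 160), 0.45),
    _p(10, 13.0, 1.1, (230, 110, 90), 0.35),
    _p(11, 12.0, 1.0, (60, 40, 220), 0.30),
    _p(12, 40.0, 3.5, (160, 90, 130), 0.55),
    _p(13, 8.0, 2.0, (120, 120, 100), 0.70),
    _p(14, 20.0, 1.8, (180, 160, 120), 0.50),
    _p(15, 12.0, 1.0, (110, 30, 190), 0.25),
    _p(16, 4.0, 0.5, (200, 170, 220), 0.30),
    _p(17, 18.0, 2.0, (210, 150, 210), 0.60),
    _p(18, 11.0, 1.5, (130, 170, 170), 0.40),
)

#: Background color of synthetic tiles (pale smear background).
BACKGROUND_RGB: tuple[int, int, int] = (235, 228, 232)
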
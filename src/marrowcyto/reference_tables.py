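"""Published reference tables from the original clinical deployment.

The end-to-end system this package re-implements was originally trained and
evaluated on a private clinical slide archive.  Those slides and model
weights are not redistributable, but the printed benchmark tables are, and
they serve here as *input data* for arithmetic-parity checks: feeding the
printed per-class values through this package's metric and bookkeeping code
must reproduce the printed summary rows.

``TABLE1``  — per-diagnosis slide counts used to train/validate the ROI model.
``TABLE3``  — per-class detection metrics (precision, recall, F1, log-average
              miss rate, AP@0.5) for the 16 evaluated classes.
``TABLE4``  — active-learning bookkeeping: cumulative annotated-object count
              and AP per class over 8 iterations.
"""

from __future__ import annotations

# (diagnostic tag, slides used in training, slides used in test-validation)
TABLE1: tuple[tuple[str, int, int], ...] = (
    ("Normal", 80, 18),
    ("Myelodysplastic syndrome (MDS)", 15, 3),
    ("Acute leukemia", 23, 5),
    ("Lymphoproliferative disorder", 28, 7),
    ("Plasma cell neoplasm", 19, 4),
    ("Hypercellular", 5, 1),
    ("Erythroid hyperplasia", 3, 0),
    ("Myeloproliferative neoplasm (MPN)", 4, 1),
    ("Inadequate", 11, 3),
    ("Hypocellular", 6, 2),
    ("MPN/MDS", 2, 0),
    ("MPN", 3, 1),
    ("Necrosis", 2, 1),
    ("Carcinoma", 3, 0),
)
TABLE1_TOTALS = (204, 46, 250)  # printed: training, test-validation, patients

#: ROI training-set composition (tiles, after augmentation).
ROI_INAPPROPRIATE_TILES = 70_250
ROI_APPROPRIATE_TILES = 28_500
ROI_TOTAL_TILES = 98_750

# (class, precision, recall, F1, log-average miss rate, AP@0.5)
TABLE3: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("Neutrophil", 0.84, 0.91, 0.87, 0.21, 0.90),
    ("Metamyelocyte", 0.68, 0.79, 0.73, 0.37, 0.77),
    ("Myelocyte", 0.80, 0.82, 0.81, 0.34, 0.80),
    ("Promyelocyte", 0.60, 0.67, 0.64, 0.53, 0.62),
    ("Blast", 0.87, 0.90, 0.88, 0.34, 0.84),
    ("Erythroblast", 0.86, 0.92, 0.89, 0.17, 0.92),
    ("Megakaryocyte nucleus", 0.80, 0.57, 0.67, 0.18, 0.60),
    ("Lymphocyte", 0.73, 0.65, 0.69, 0.49, 0.66),
    ("Monocyte", 0.84, 0.71, 0.77, 0.36, 0.72),
    ("Plasma cell", 0.75, 0.69, 0.72, 0.33, 0.72),
    ("Eosinophil", 0.93, 0.94, 0.93, 0.06, 0.97),
    ("Megakaryocyte", 1.00, 0.79, 0.88, 0.19, 0.82),
    ("Debris", 0.85, 0.80, 0.82, 0.34, 0.79),
    ("Histiocyte", 0.90, 0.53, 0.67, 0.50, 0.54),
    ("Platelet", 0.84, 0.64, 0.73, 0.33, 0.64),
    ("Platelet clump", 0.93, 0.61, 0.73, 0.41, 0.62),
)
#: Printed summary row: precision, recall, F1, LAMR averages and mAP@0.5.
TABLE3_AVERAGES = (0.83, 0.75, 0.78, 0.32, 0.75)

# class -> 8 (cumulative count, AP) pairs, iterations 1..8
TABLE4: dict[str, tuple[tuple[int, float], ...]] = {
    "Neutrophil": ((680, 0.75), (1256, 0.82), (1568, 0.83), (1756, 0.85),
                   (1895, 0.86), (2050, 0.89), (2398, 0.91), (2714, 0.90)),
    "Metamyelocyte": ((480, 0.60), (605, 0.66), (752, 0.69), (785, 0.72),
                      (856, 0.76), (925, 0.75), (986, 0.76), (1017, 0.77)),
    "Myelocyte": ((390, 0.53), (589, 0.55), (665, 0.59), (720, 0.62),
                  (869, 0.70), (950, 0.78), (1015, 0.79), (1199, 0.80)),
    "Promyelocyte": ((65, 0.44), (102, 0.46), (256, 0.52), (285, 0.54),
                     (320, 0.59), (326, 0.62), (360, 0.64), (409, 0.62)),
    "Blast": ((1050, 0.69), (1785, 0.76), (2029, 0.78), (2590, 0.81),
              (2896, 0.80), (3268, 0.83), (3526, 0.84), (3950, 0.84)),
    "Erythroblast": ((620, 0.72), (1150, 0.78), (1390, 0.80), (1580, 0.82),
                     (2028, 0.89), (2295, 0.90), (2480, 0.92), (2668, 0.92)),
    "Megakaryocyte nucleus": ((5, 0.32), (7, 0.35), (18, 0.52), (19, 0.55),
                              (19, 0.55), (23, 0.60), (23, 0.59), (23, 0.60)),
    "Lymphocyte": ((390, 0.47), (530, 0.48), (689, 0.50), (706, 0.51),
                   (780, 0.52), (1015, 0.59), (1150, 0.62), (1305, 0.66)),
    "Monocyte": ((62, 0.47), (98, 0.51), (295, 0.57), (368, 0.61),
                 (423, 0.62), (485, 0.65), (520, 0.68), (569, 0.72)),
    "Plasma cell": ((29, 0.57), (45, 0.59), (50, 0.61), (82, 0.63),
                    (105, 0.67), (135, 0.68), (158, 0.71), (176, 0.72)),
    "Eosinophil": ((31, 0.59), (38, 0.63), (135, 0.83), (172, 0.86),
                   (185, 0.88), (221, 0.95), (228, 0.95), (249, 0.97)),
    "Megakaryocyte": ((25, 0.49), (30, 0.52), (90, 0.77), (90, 0.77),
                      (92, 0.78), (95, 0.80), (100, 0.81), (106, 0.82)),
    "Debris": ((1380, 0.58), (2680, 0.62), (3450, 0.65), (3920, 0.68),
               (4490, 0.73), (4901, 0.77), (5260, 0.77), (5603, 0.79)),
    "Histiocyte": ((38, 0.34), (72, 0.42), (147, 0.48), (163, 0.48),
                   (168, 0.51), (174, 0.52), (182, 0.54), (191, 0.54)),
    "Platelet": ((790, 0.41), (1680, 0.46), (2150, 0.48), (2560, 0.52),
                 (2890, 0.58), (3250, 0.65), (3680, 0.65), (3971, 0.64)),
    "Platelet clump": ((93, 0.37), (146, 0.41), (320, 0.54), (409, 0.56),
                       (475, 0.57), (536, 0.58), (563, 0.61), (585, 0.62)),
}
#: Printed per-iteration totals row of the active-learning table.
TABLE4_COUNT_TOTALS = (6128, 10813, 14004, 16205, 18491, 20649, 22629, 24735)
TABLE4_AP_MEANS = (0.52, 0.56, 0.64, 0.66, 0.69, 0.72, 0.74, 0.75)


def table4_counts(iteration: int) -> list[int]:
    """Per-class cumulative counts at a 1-based iteration."""
    return [pairs[iteration - 1][0] for pairs in TABLE4.values()]


def table4_aps(iteration: int) -> list[float]:
    """Per-class AP values at a 1-based iteration."""
    return [pairs[iteration - 1][1] for pairs in TABLE4.values()]
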
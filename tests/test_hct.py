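"""HCT/IHCT accumulation, chi-square convergence, BM_ME and run_ndc."""

import numpy as np
import pytest

from marrowcyto.detection import BoundingBox, Detection
from marrowcyto.hct import (
    HCT,
    IHCT,
    accumulate_stream,
    bm_me_ratio,
    check_convergence,
    chi_square_distance,
    feature_vector,
    hct_from_detections,
    run_ndc,
)
from marrowcyto.synthetic import (
    SyntheticSlideReader,
    make_diagnostic_profile,
    simulate_hct_stream,
)
from marrowcyto.taxonomy import CLASS_IDS, N_CLASSES, NDC_CLASSES
from marrowcyto.tiling import GridSpec


def _counts(**kw):
    c = np.zeros(N_CLASSES, dtype=np.int64)
    for name, v in kw.items():
        c[CLASS_IDS[name]] = v
    return c


# ---------------------------------------------------------------------------
# chi-square distance


def test_chi_square_hand_values():
    assert chi_square_distance([1, 0], [0, 1]) == pytest.approx(1.0)
    assert chi_square_distance([2, 2], [2, 2]) == 0.0
    assert chi_square_distance([0, 0], [0, 0]) == 0.0  # all 0/0 terms
    # 0.5 * ((4-1)^2/5) = 0.9
    assert chi_square_distance([4], [1]) == pytest.approx(0.9)


def test_chi_square_properties():
    rng = np.random.default_rng(0)
    for _ in range(100):
        x = rng.uniform(0, 5, size=8)
        y = rng.uniform(0, 5, size=8)
        d = chi_square_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(chi_square_distance(y, x))
        assert chi_square_distance(x, x) == 0.0
    with pytest.raises(ValueError):
        chi_square_distance([1, 2], [1])
    with pytest.raises(ValueError):
        chi_square_distance([-1], [1])


def test_chi_square_bounded_by_one_for_proportions():
    # for probability vectors the distance is at most 1
    rng = np.random.default_rng(1)
    for _ in range(200):
        x = rng.dirichlet(np.ones(12))
        y = rng.dirichlet(np.ones(12))
        assert chi_square_distance(x, y) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# BM_ME and feature vector


def test_bm_me_hand_case():
    c = _counts(blast=2, promyelocyte=1, myelocyte=3, metamyelocyte=4,
                neutrophil=10, eosinophil=2, erythroblast=11)
    assert bm_me_ratio(c) == pytest.approx(22 / 11)


def test_bm_me_excludes_non_numerator_classes():
    c = _counts(neutrophil=5, erythroblast=5, lymphocyte=100, basophil=7,
                monocyte=3, platelet=50)
    assert bm_me_ratio(c) == pytest.approx(1.0)


def test_bm_me_undefined_without_erythroblasts():
    assert bm_me_ratio(_counts(neutrophil=5)) is None


def test_feature_vector():
    c = _counts(neutrophil=3, erythroblast=1, platelet=100, debris=7)
    fv = feature_vector(c)
    assert fv.n_ndc_cells == 4  # platelets and debris excluded
    assert fv.proportions.sum() == pytest.approx(1.0)
    assert fv.proportions[NDC_CLASSES.index("neutrophil")] == pytest.approx(0.75)
    assert fv.bm_me == pytest.approx(3.0)
    fv0 = feature_vector(np.zeros(N_CLASSES))
    assert fv0.n_ndc_cells == 0 and not fv0.proportions.any()


def test_hct_from_detections_conf_threshold():
    box = BoundingBox(0, 0, 5, 5)
    dets = [Detection(box, 0, 0.9), Detection(box, 0, 0.74), Detection(box, 5, 0.75)]
    h = hct_from_detections(dets, conf_thr=0.75)
    assert h.counts[0] == 1 and h.counts[5] == 1
    assert h.n_cells == 2


def test_hct_validation():
    with pytest.raises(ValueError):
        HCT(np.zeros(5))
    with pytest.raises(ValueError):
        HCT(-np.ones(N_CLASSES))


# ---------------------------------------------------------------------------
# convergence


def test_check_convergence_rules():
    flat = [1e-6] * 10
    assert not check_convergence(flat, min_tiles=80, n_tiles=79)
    assert check_convergence(flat, min_tiles=80, n_tiles=80)
    assert not check_convergence([1e-6] * 4 + [1e-3], min_tiles=5, n_tiles=100)
    assert not check_convergence([1e-6] * 3, min_tiles=1, patience=5, n_tiles=100)
    # default n_tiles = len(trace) + 1
    assert check_convergence([1e-6] * 79, min_tiles=80)
    assert not check_convergence([1e-6] * 78, min_tiles=80)
    with pytest.raises(ValueError):
        check_convergence(flat, tau=0)
    with pytest.raises(ValueError):
        check_convergence(flat, patience=0)


def test_ihct_accumulation_conserves_counts():
    ihct = IHCT()
    rows = [_counts(neutrophil=3, erythroblast=2), _counts(blast=1, platelet=4)]
    assert ihct.add(HCT(rows[0])) is None  # first tile: no distance
    d = ihct.add(HCT(rows[1]))
    assert d is not None and d > 0
    assert np.array_equal(ihct.counts, rows[0] + rows[1])
    assert ihct.n_tiles == 2
    assert len(ihct.distance_trace) == 1


def test_ihct_distance_against_zero_histogram_is_ceiling():
    ihct = IHCT()
    ihct.add(HCT(np.zeros(N_CLASSES, dtype=np.int64)))
    d = ihct.add(HCT(_counts(neutrophil=5)))
    assert d == 1.0


def test_ihct_identical_tiles_distances_shrink():
    ihct = IHCT(min_tiles=10, bm_me_in_distance=True)
    row = _counts(neutrophil=6, erythroblast=3, lymphocyte=1)
    for _ in range(30):
        ihct.add(HCT(row))
    # identical proportions each step: distance is exactly 0 after tile 2
    assert all(d == 0.0 for d in ihct.distance_trace)
    assert ihct.converged


def test_accumulate_stream_stationary_converges(normal_profile):
    counts = simulate_hct_stream(normal_profile, 200, seed=3)
    ihct, at = accumulate_stream(counts)
    assert at is not None and at >= 80
    assert ihct.converged
    assert ihct.n_tiles == at  # stopped at convergence
    ihct2, at2 = accumulate_stream(counts, stop_at_convergence=False)
    assert at2 == at and ihct2.n_tiles == 200


def test_accumulate_stream_monotone_in_tau(normal_profile):
    counts = simulate_hct_stream(normal_profile, 300, seed=4)
    _, loose = accumulate_stream(counts, tau=1e-3)
    _, tight = accumulate_stream(counts, tau=1e-5)
    assert loose is not None
    assert tight is None or tight >= loose


# ---------------------------------------------------------------------------
# run_ndc


def _const_detector(dets):
    return lambda img: dets


def test_run_ndc_non_converged_on_exhaustion(normal_profile):
    reader = SyntheticSlideReader(normal_profile, rows=2, cols=3, seed=8)
    box = BoundingBox(0, 0, 8, 8)
    dets = [Detection(box, CLASS_IDS["neutrophil"], 0.9),
            Detection(box, CLASS_IDS["erythroblast"], 0.9)]
    report = run_ndc(reader, lambda img: 1.0, _const_detector(dets),
                     grid=GridSpec(2, 3, 512), slide_id="s")
    assert not report.converged  # only 6 tiles < min_tiles=80
    assert report.n_tiles_visited == 6 and report.n_roi_tiles == 6
    assert report.counts["neutrophil"] == 6
    assert report.bm_me == pytest.approx(1.0)
    assert report.n_cells == 12
    assert report.percentages["neutrophil"] == pytest.approx(50.0)
    assert report.ndc_percentages["neutrophil"] == pytest.approx(50.0)


def test_run_ndc_raises_without_roi_tiles(normal_profile):
    reader = SyntheticSlideReader(normal_profile, rows=1, cols=2, seed=8)
    with pytest.raises(ValueError, match="no appropriate tile"):
        run_ndc(reader, lambda img: 0.0, _const_detector([]), grid=GridSpec(1, 2, 512))


def test_run_ndc_respects_conf_thr(normal_profile):
    reader = SyntheticSlideReader(normal_profile, rows=1, cols=2, seed=8)
    box = BoundingBox(0, 0, 8, 8)
    dets = [Detection(box, 0, 0.74)]
    report = run_ndc(reader, lambda img: 1.0, _const_detector(dets),
                     grid=GridSpec(1, 2, 512), conf_thr=0.75)
    assert report.n_cells == 0
    report = run_ndc(reader, lambda img: 1.0, _const_detector(dets),
                     grid=GridSpec(1, 2, 512), conf_thr=0.5)
    assert report.n_cells == 2


def test_run_ndc_max_tiles_and_shuffle(normal_profile):
    reader = SyntheticSlideReader(normal_profile, rows=2, cols=3, seed=8)
    box = BoundingBox(0, 0, 8, 8)
    det = _const_detector([Detection(box, 0, 0.9)])
    r1 = run_ndc(reader, lambda img: 1.0, det, grid=GridSpec(2, 3, 512), max_tiles=4)
    assert r1.n_tiles_visited == 4
    # shuffle is deterministic under a fixed seed
    r2 = run_ndc(reader, lambda img: 1.0, det, grid=GridSpec(2, 3, 512),
                 shuffle_seed=1, max_tiles=4)
    r3 = run_ndc(reader, lambda img: 1.0, det, grid=GridSpec(2, 3, 512),
                 shuffle_seed=1, max_tiles=4)
    assert r2.to_json() == r3.to_json()


def test_report_serialization(tmp_path, normal_profile):
    import csv
    import json

    reader = SyntheticSlideReader(normal_profile, rows=2, cols=3, seed=8)
    box = BoundingBox(0, 0, 8, 8)
    dets = [Detection(box, CLASS_IDS["neutrophil"], 0.9)]
    report = run_ndc(reader, lambda img: 1.0, _const_detector(dets),
                     grid=GridSpec(2, 3, 512), slide_id="slideX")
    payload = json.loads(report.to_json(tmp_path / "r.json"))
    assert payload["slide_id"] == "slideX"
    assert payload["counts"]["neutrophil"] == 6
    report.write_csv(tmp_path / "r.csv")
    rows = list(csv.reader(open(tmp_path / "r.csv")))
    assert rows[0] == ["class", "count", "percent_of_objects", "percent_of_ndc"]
    report.write_trace_csv(tmp_path / "t.csv")
    rows = list(csv.reader(open(tmp_path / "t.csv")))
    assert len(rows) == 1 + len(report.distance_trace)
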
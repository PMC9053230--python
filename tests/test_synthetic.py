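"""Generator tests: determinism, ground-truth fidelity, mixture GOF, readers."""

import numpy as np
import pytest
from scipy import stats

from marrowcyto.detection import iou
from marrowcyto.synthetic import (
    TILE_SIZE,
    DiagnosticProfile,
    SyntheticSlideReader,
    augment_tile,
    make_diagnostic_profile,
    render_slide,
    render_tile,
    render_tile_full,
    sample_roi_labels,
    simulate_hct_stream,
    tile_seed,
)
from marrowcyto.taxonomy import CLASS_IDS, N_CLASSES


def test_presets_valid():
    for name in ("normal", "mds_like", "aml_like"):
        p = make_diagnostic_profile(name)
        assert sum(p.mixture) == pytest.approx(1.0, abs=1e-9)
        assert p.mixture[CLASS_IDS["blast"]] > 0
    with pytest.raises(ValueError, match="unknown preset"):
        make_diagnostic_profile("nope")
    # aml has far more blasts than normal
    assert (make_diagnostic_profile("aml_like").mixture[CLASS_IDS["blast"]]
            > 5 * make_diagnostic_profile("normal").mixture[CLASS_IDS["blast"]])


def test_profile_validation():
    good = make_diagnostic_profile("normal")
    with pytest.raises(ValueError):
        DiagnosticProfile("x", good.mixture[:-1])
    with pytest.raises(ValueError):
        DiagnosticProfile("x", good.mixture, cells_per_roi_tile_mean=0)
    with pytest.raises(ValueError):
        DiagnosticProfile("x", good.mixture, roi_fraction=0.0)
    bad = list(good.mixture)
    bad[0] += 0.1
    with pytest.raises(ValueError):
        DiagnosticProfile("x", tuple(bad))


def test_render_tile_deterministic(normal_profile):
    a_img, a_anns = render_tile(normal_profile, True, 77)
    b_img, b_anns = render_tile(normal_profile, True, 77)
    assert np.array_equal(a_img, b_img)
    assert a_anns == b_anns
    c_img, _ = render_tile(normal_profile, True, 78)
    assert not np.array_equal(a_img, c_img)


def test_render_tile_shape_and_boxes(rendered_tiles):
    for img, anns in rendered_tiles:
        assert img.shape == (TILE_SIZE, TILE_SIZE, 3) and img.dtype == np.uint8
        for a in anns:
            assert 0 <= a.box.x0 < a.box.x1 <= TILE_SIZE
            assert 0 <= a.box.y0 < a.box.y1 <= TILE_SIZE
            assert 0 <= a.class_id < N_CLASSES


def test_boxes_are_tight(rendered_tiles):
    """Each annotation box tightly hugs non-background pixels."""
    from marrowcyto.detection import _foreground_mask

    img, anns = rendered_tiles[0]
    mask = _foreground_mask(img)
    for a in anns[:5]:
        x0, y0, x1, y1 = (int(a.box.x0), int(a.box.y0), int(a.box.x1), int(a.box.y1))
        sub = mask[y0:y1, x0:x1]
        # foreground present on every edge row/column of the tight box
        assert sub[0].any() and sub[-1].any() and sub[:, 0].any() and sub[:, -1].any()


def test_appropriate_tiles_control_overlap(rendered_tiles):
    """Rejection sampling keeps pairwise box IoU low on appropriate tiles."""
    high = total = 0
    for _, anns in rendered_tiles:
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                total += 1
                if iou(anns[i].box, anns[j].box) > 0.1 + 1e-9:
                    high += 1
    # a handful of giveup placements are allowed, not a systematic failure
    assert total > 100
    assert high / total < 0.05


def test_failure_modes(normal_profile):
    seen = set()
    for seed in range(40):
        t = render_tile_full(normal_profile, False, seed)
        assert not t.appropriate
        seen.add(t.failure_mode)
        if t.failure_mode == "empty":
            assert len(t.annotations) <= 2
            assert all(a.class_id == CLASS_IDS["debris"] for a in t.annotations)
        elif t.failure_mode == "overlap":
            assert len(t.annotations) > 10 * normal_profile.cells_per_roi_tile_mean
    assert seen == {"overlap", "overstain", "empty"}
    t = render_tile_full(normal_profile, True, 0)
    assert t.appropriate and t.failure_mode is None


def test_mixture_goodness_of_fit(normal_profile):
    """Pooled class counts over >=1000 simulated tiles match the mixture."""
    counts = simulate_hct_stream(normal_profile, 1000, seed=5).sum(axis=0)
    expected = np.asarray(normal_profile.mixture) * counts.sum()
    keep = expected >= 5  # standard chi-square validity rule
    chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    # lump the small-expectation classes into one cell
    if (~keep).any():
        o, e = counts[~keep].sum(), expected[~keep].sum()
        chi2 += (o - e) ** 2 / e
        dof = keep.sum()  # lumped cell adds one
    else:
        dof = keep.sum() - 1
    p = stats.chi2.sf(chi2, dof)
    assert p > 1e-4, f"mixture GOF rejected: chi2={chi2:.1f}, p={p:.2e}"


def test_rendered_class_counts_match_mixture(normal_profile):
    """Classes drawn by the renderer itself follow the mixture (pooled GOF)."""
    counts = np.zeros(N_CLASSES)
    for seed in range(150):
        _, anns = render_tile(normal_profile, True, 9_000 + seed, size=256)
        for a in anns:
            counts[a.class_id] += 1
    expected = np.asarray(normal_profile.mixture) * counts.sum()
    keep = expected >= 5
    chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    o, e = counts[~keep].sum(), expected[~keep].sum()
    chi2 += (o - e) ** 2 / e if e > 0 else 0.0
    p = stats.chi2.sf(chi2, keep.sum())
    assert p > 1e-4


def test_roi_label_fraction(normal_profile):
    labels = sample_roi_labels(normal_profile, 30, 40, seed=2)
    assert len(labels) == 1200
    k = sum(v == "appropriate" for v in labels.values())
    lo, hi = stats.binom.interval(0.9999, 1200, normal_profile.roi_fraction)
    assert lo <= k <= hi
    assert labels == sample_roi_labels(normal_profile, 30, 40, seed=2)


def test_lazy_reader_matches_eager(normal_profile):
    slide = render_slide(normal_profile, rows=2, cols=3, seed=4)
    reader = SyntheticSlideReader(normal_profile, rows=2, cols=3, seed=4)
    assert (reader.width, reader.height) == (slide.width, slide.height)
    assert reader.roi_labels == slide.roi_labels
    # unaligned region spanning tile borders
    got = reader.read_region(400, 300, 700, 500)
    assert np.array_equal(got, slide.read_region(400, 300, 700, 500))
    assert np.array_equal(reader.read_region(0, 0, 512, 512),
                          slide.read_region(0, 0, 512, 512))


def test_slide_annotations_in_global_frame(normal_profile):
    slide = render_slide(normal_profile, rows=2, cols=2, seed=6)
    assert all(
        0 <= a.box.x0 < a.box.x1 <= slide.width
        and 0 <= a.box.y0 < a.box.y1 <= slide.height
        for a in slide.annotations
    )
    # appropriate tiles hold ~10 cells each; totals must reflect that
    n_app = sum(v == "appropriate" for v in slide.roi_labels.values())
    assert len(slide.annotations) >= 5 * n_app


def test_tile_seed_distinct():
    seeds = {tile_seed(0, r, c) for r in range(15) for c in range(20)}
    assert len(seeds) == 300
    assert tile_seed(0, 1, 2) != tile_seed(1, 1, 2)


# ---------------------------------------------------------------------------
# Augmentation


@pytest.mark.parametrize("op", ["hflip", "vflip"])
def test_flip_involution(rendered_tiles, op):
    img, anns = rendered_tiles[1]
    out, boxes = augment_tile(img, anns, op)
    back_img, back_boxes = augment_tile(out, boxes, op)
    assert np.array_equal(back_img, img)
    assert back_boxes == list(anns)


def test_rot90_four_times_identity(rendered_tiles):
    img, anns = rendered_tiles[2]
    out, boxes = img, list(anns)
    for _ in range(4):
        out, boxes = augment_tile(out, boxes, "rot90")
    assert np.array_equal(out, img)
    assert boxes == list(anns)


def test_geometric_ops_move_boxes_with_pixels(rendered_tiles):
    """After any geometric op, each box still tightly covers foreground."""
    from marrowcyto.detection import _foreground_mask

    img, anns = rendered_tiles[3]
    for op in ("hflip", "vflip", "rot90"):
        out, boxes = augment_tile(img, anns, op)
        mask = _foreground_mask(out)
        for a in boxes[:5]:
            sub = mask[int(a.box.y0):int(a.box.y1), int(a.box.x0):int(a.box.x1)]
            assert sub.any()
            assert sub[0].any() and sub[-1].any() and sub[:, 0].any() and sub[:, -1].any()


def test_photometric_ops_leave_boxes(rendered_tiles):
    img, anns = rendered_tiles[4]
    out, boxes = augment_tile(img, anns, "brightness", amount=30)
    assert boxes == list(anns)
    assert out.mean() > img.mean()
    out, boxes = augment_tile(img, anns, "contrast", amount=0.5)
    assert boxes == list(anns)
    assert out.std() < img.std()


def test_augment_rejects_bad_args(rendered_tiles):
    img, anns = rendered_tiles[0]
    with pytest.raises(ValueError):
        augment_tile(img, anns, "shear")
    with pytest.raises(ValueError):
        augment_tile(img, anns, "brightness", amount=300)
    with pytest.raises(ValueError):
        augment_tile(img, anns, "contrast", amount=0)


# ---------------------------------------------------------------------------
# Count streams


def test_simulate_hct_stream_shape_and_determinism(normal_profile):
    a = simulate_hct_stream(normal_profile, 50, seed=9)
    assert a.shape == (50, N_CLASSES)
    assert (a >= 0).all()
    assert np.array_equal(a, simulate_hct_stream(normal_profile, 50, seed=9))
    with pytest.raises(ValueError):
        simulate_hct_stream(normal_profile, 10, 0, drift_mode="bogus")


def test_simulate_hct_stream_switch_changes_mixture(normal_profile):
    aml = make_diagnostic_profile("aml_like")
    c = simulate_hct_stream(normal_profile, 400, seed=1, drift_to=aml,
                            drift_mode="switch")
    blast = CLASS_IDS["blast"]
    first = c[:200, blast].sum() / max(c[:200].sum(), 1)
    second = c[200:, blast].sum() / max(c[200:].sum(), 1)
    assert second > 3 * first
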
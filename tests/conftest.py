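import numpy as np
import pytest

from marrowcyto.detection import reference_blob_detector
from marrowcyto.synthetic import make_diagnostic_profile, render_tile


@pytest.fixture(scope="session")
def normal_profile():
    return make_diagnostic_profile("normal")


@pytest.fixture(scope="session")
def rendered_tiles(normal_profile):
    """A batch of appropriate tiles with ground truth, shared across tests."""
    return [render_tile(normal_profile, True, 5000 + s) for s in range(30)]


@pytest.fixture(scope="session")
def detection_pairs(rendered_tiles):
    """(detections, annotations) per tile from the reference detector."""
    return [(reference_blob_detector(img), anns) for img, anns in rendered_tiles]


def random_boxes(rng, n, lo=0, hi=100, max_side=30):
    """Random valid boxes as (x0, y0, x1, y1) tuples."""
    out = []
    for _ in range(n):
        x0 = rng.uniform(lo, hi - 1)
        y0 = rng.uniform(lo, hi - 1)
        out.append((x0, y0, x0 + rng.uniform(1, max_side), y0 + rng.uniform(1, max_side)))
    return out
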
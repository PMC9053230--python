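"""Slide readers implementing the region-access contract.

The pipeline only requires ``width``, ``height`` and
``read_region(x0, y0, width, height) -> RGB uint8 array``; any object with
that surface (a proprietary whole-slide-image adapter, the lazy synthetic
reader, ...) can be plugged in.  Shipped here: an in-memory array slide and a
raster-file slide for PNG/TIFF.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

Image.MAX_IMAGE_PIXELS = None  # slides legitimately exceed PIL's decompression guard


class ArraySlide:
    """Wrap an in-memory (H, W, 3) uint8 array as a slide."""

    def __init__(self, image: np.ndarray) -> None:
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB array")
        self.image = image

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def read_region(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        if x0 < 0 or y0 < 0 or x0 + width > self.width or y0 + height > self.height:
            raise ValueError("region outside slide bounds")
        return self.image[y0 : y0 + height, x0 : x0 + width]


class RasterSlide(ArraySlide):
    """Slide backed by a raster file (PNG, TIFF, ...); loaded fully into memory."""

    def __init__(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            image = tifffile.imread(path)
            if image.ndim == 2:
                image = np.stack([image] * 3, axis=-1)
            image = image[..., :3]
        else:
            image = np.asarray(Image.open(path).convert("RGB"))
        super().__init__(image.astype(np.uint8))
        self.path = path
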
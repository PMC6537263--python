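"""Raster I/O: PNG / TIFF / JPEG readers and writers for pipeline images.

Integer files are normalized by their max code value (255 or 65535) on
read; grayscale files are replicated to three channels; alpha is
dropped.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from cvdenhance.colorspace import EncodedImage

__all__ = ["read_image", "write_image", "write_gray_map"]


def read_image(path: str | Path) -> EncodedImage:
    raw = iio.imread(path)
    if np.issubdtype(raw.dtype, np.integer):
        maxval = float(np.iinfo(raw.dtype).max)
        pixels = raw.astype(np.float64) / maxval
    else:
        pixels = raw.astype(np.float64)
    if pixels.ndim == 2:
        pixels = np.repeat(pixels[..., np.newaxis], 3, axis=-1)
    if pixels.shape[-1] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return EncodedImage(np.clip(pixels, 0.0, 1.0))


def write_image(img: EncodedImage, path: str | Path, *, bitdepth: int = 8) -> None:
    if bitdepth == 8:
        data = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        data = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"unsupported bit depth {bitdepth}")
    iio.imwrite(Path(path), data)


def write_gray_map(values: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] single-channel raster as 8-bit grayscale."""
    v = np.asarray(values, dtype=np.float64)
    iio.imwrite(Path(path), np.round(np.clip(v, 0.0, 1.0) * 255.0).astype(np.uint8))
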
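"""Raster I/O, green-channel extraction and output marking.

Images are plain numpy arrays: a color image is ``H x W x 3`` uint8 (RGB),
a grayscale image is ``H x W`` uint8.  All entropy computation downstream
runs on the green channel, which carries the strongest contrast between the
optic disc and the retinal background.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "green_channel",
    "render_marked",
    "default_marker_side",
]


def _to_uint8_rgb(pixels: np.ndarray, path: Path) -> np.ndarray:
    if pixels.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if pixels.dtype == np.uint16:
        pixels = (pixels // 257).astype(np.uint8)  # 65535 -> 255
    elif pixels.dtype != np.uint8:
        pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]  # drop alpha
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"unsupported image layout {pixels.shape} in {path}")
    return np.ascontiguousarray(pixels)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF/PPM raster as an 8-bit RGB array.

    16-bit inputs are rescaled to [0, 255] by integer division (v // 257);
    grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        pixels = iio.imread(path)
    except Exception as exc:  # backend plugins raise heterogeneous errors
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return _to_uint8_rgb(np.asarray(pixels), path)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image (lossless PNG recommended for round-trips)."""
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def green_channel(img: np.ndarray) -> np.ndarray:
    """Extract the green plane of an RGB image as a 2-D grayscale array."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    return np.ascontiguousarray(img[:, :, 1])


def default_marker_side(height: int, width: int) -> int:
    """Marker side used when none is given: 2% of the short image side, min 5 px."""
    return max(5, round(0.02 * min(height, width)))


def render_marked(
    img: np.ndarray, center: tuple[int, int], square_side: int | None = None
) -> np.ndarray:
    """Copy of ``img`` with a filled black square marking ``center``.

    The square is axis-aligned, ``square_side`` pixels on a side, centred at
    ``center = (row, col)`` and clipped to the image bounds; every other
    pixel is left untouched.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    row, col = center
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"center {center} outside {h}x{w} image")
    if square_side is None:
        square_side = default_marker_side(h, w)
    if square_side < 1:
        raise ValueError("square_side must be >= 1")
    top = max(row - (square_side - 1) // 2, 0)
    left = max(col - (square_side - 1) // 2, 0)
    bottom = min(row - (square_side - 1) // 2 + square_side, h)
    right = min(col - (square_side - 1) // 2 + square_side, w)
    out = img.copy()
    out[top:bottom, left:right] = 0
    return out
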
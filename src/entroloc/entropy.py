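"""Shannon entropy of the brightness distribution of an image region.

The texture score driving the whole localizer:

    H(I) = -sum_{j=0}^{Mg-1} p(j) * log2 p(j)

where ``p(j)`` is the fraction of pixels in the region with brightness ``j``
and ``Mg`` is the number of brightness levels (256 for 8-bit images).  A
smooth region concentrates its mass in few bins and scores near 0 bits; a
richly textured region such as the optic disc, with vessels and nerve fibres
crossing it, spreads over many bins and scores high.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type hints only
    from .grid import Region

N_LEVELS = 256  # brightness levels of an 8-bit image

__all__ = ["N_LEVELS", "histogram", "shannon_entropy", "region_entropy"]


def _check_region(img: np.ndarray, region: "Region") -> None:
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if not (0 <= region.top < region.bottom <= h and 0 <= region.left < region.right <= w):
        raise ValueError(
            f"region rows [{region.top}, {region.bottom}) x "
            f"cols [{region.left}, {region.right}) outside {h}x{w} image"
        )


def histogram(img: np.ndarray, region: "Region", n_levels: int = N_LEVELS) -> np.ndarray:
    """Brightness histogram of ``img`` restricted to ``region``.

    Returns an integer array of length ``n_levels`` whose ``j``-th entry is
    the number of pixels in the region with value ``j``; the counts sum to
    the region area.
    """
    _check_region(img, region)
    patch = img[region.as_slices()]
    counts = np.bincount(patch.ravel().astype(np.int64), minlength=n_levels)
    if counts.size > n_levels:
        raise ValueError(f"pixel value >= {n_levels} in region")
    return counts


def shannon_entropy(counts: np.ndarray) -> float:
    """Entropy in bits of the distribution given by histogram ``counts``.

    Empty bins contribute nothing (the ``0 * log2 0 = 0`` convention); the
    result lies in ``[0, log2(len(counts))]``.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("histogram is empty (total count 0)")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def region_entropy(img: np.ndarray, region: "Region") -> float:
    """Shannon entropy (bits) of a region's brightness histogram.

    This is the quality function used to rank candidate windows.
    """
    return shannon_entropy(histogram(img, region))
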
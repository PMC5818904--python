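"""Rectangular region sets for coarse-to-fine sliding-window search.

Two window layouts are used by the localizer: a *non-overlap* partition
(pairwise-disjoint patches that exactly cover the parent rectangle) and an
*overlap* subdivision (equal-size windows whose stride is smaller than the
window, so neighbours intersect).  Both are pure coordinate arithmetic on
half-open ``[top, bottom) x [left, right)`` rectangles; entropy scoring of a
region set lives in :func:`argmax_entropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .entropy import region_entropy

__all__ = [
    "Region",
    "RegionSet",
    "partition_nonoverlap",
    "refined_region",
    "subdivide_overlap",
    "argmax_entropy",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle in 0-based, half-open pixel coordinates.

    Rows increase downward.  ``label`` is the (i, j) grid index of the
    region within the region set that produced it, or ``None`` for
    free-standing rectangles such as whole-image bounds.
    """

    top: int
    bottom: int
    left: int
    right: int
    label: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(
                f"degenerate region: rows [{self.top}, {self.bottom}), "
                f"cols [{self.left}, {self.right})"
            )
        if self.top < 0 or self.left < 0:
            raise ValueError("region coordinates must be non-negative")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[int, int]:
        """Integer pixel at the floor-midpoint of the rectangle."""
        return ((self.top + self.bottom - 1) // 2, (self.left + self.right - 1) // 2)

    def as_slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def contains_point(self, row: int, col: int) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right

    def contains_region(self, other: "Region") -> bool:
        return (
            self.top <= other.top
            and other.bottom <= self.bottom
            and self.left <= other.left
            and other.right <= self.right
        )

    def intersects(self, other: "Region") -> bool:
        return (
            self.top < other.bottom
            and other.top < self.bottom
            and self.left < other.right
            and other.left < self.right
        )


@dataclass
class RegionSet:
    """Ordered (row-major by label) collection of regions on a grid.

    ``mode`` records which layout law the set satisfies: ``"nonoverlap"``
    (pairwise disjoint, exact cover of ``parent``) or ``"overlap"``
    (fixed-size windows, neighbours intersect when stride < window).
    """

    regions: list[Region]
    mode: str
    shape: tuple[int, int]
    parent: Region = field(repr=False)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, label: tuple[int, int]) -> Region:
        i, j = label
        rows, cols = self.shape
        if not (0 <= i < rows and 0 <= j < cols):
            raise KeyError(label)
        return self.regions[i * cols + j]


def _band_edges(start: int, stop: int, n: int) -> list[int]:
    """Band boundaries: n-1 bands of width (stop-start)//n, last absorbs the rest."""
    size = (stop - start) // n
    return [start + i * size for i in range(n)] + [stop]


def partition_nonoverlap(parent: Region, rows: int, cols: int) -> RegionSet:
    """Partition ``parent`` into a ``rows x cols`` grid of disjoint patches.

    Every patch has size ``(H//rows, W//cols)`` except the last row/column
    band, which absorbs the remainder so the union covers the parent exactly.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"rows and cols must be >= 1, got {rows}x{cols}")
    if rows > parent.height or cols > parent.width:
        raise ValueError(
            f"cannot split a {parent.height}x{parent.width} region "
            f"into {rows}x{cols} patches"
        )
    row_edges = _band_edges(parent.top, parent.bottom, rows)
    col_edges = _band_edges(parent.left, parent.right, cols)
    regions = [
        Region(row_edges[i], row_edges[i + 1], col_edges[j], col_edges[j + 1], label=(i, j))
        for i in range(rows)
        for j in range(cols)
    ]
    return RegionSet(regions, mode="nonoverlap", shape=(rows, cols), parent=parent)


def refined_region(winner: Region, grid: RegionSet, image_bounds: Region) -> Region:
    """Refined search region: the winning patch plus half of each neighbour.

    The winner is extended on each side where a grid neighbour exists by half
    of that neighbour's extent (floor division), then clipped to
    ``image_bounds``.  For an interior winner on a uniform grid this doubles
    the linear size of the search region, centred on the winner.
    """
    if grid.mode != "nonoverlap":
        raise ValueError("refined_region requires a non-overlap grid")
    if winner.label is None or winner not in grid.regions:
        raise ValueError("winner does not belong to the grid")
    i, j = winner.label
    rows, cols = grid.shape

    top = winner.top
    bottom = winner.bottom
    left = winner.left
    right = winner.right
    if i > 0:
        top -= grid[i - 1, j].height // 2
    if i < rows - 1:
        bottom += grid[i + 1, j].height // 2
    if j > 0:
        left -= grid[i, j - 1].width // 2
    if j < cols - 1:
        right += grid[i, j + 1].width // 2

    return Region(
        max(top, image_bounds.top),
        min(bottom, image_bounds.bottom),
        max(left, image_bounds.left),
        min(right, image_bounds.right),
    )


def subdivide_overlap(parent: Region, k: int, window_h: int, window_w: int) -> RegionSet:
    """Lay out a ``k x k`` lattice of fixed-size overlapping windows.

    Window (i, j) is placed at offset ``round(i * (H - window_h) / (k - 1))``
    from the parent's top (and analogously for columns), so the first window
    is flush with the parent's top-left corner and the last with its
    bottom-right.  Whenever the resulting stride is smaller than the window
    size, adjacent windows intersect.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if window_h < 1 or window_w < 1:
        raise ValueError("window size must be positive")
    if window_h > parent.height or window_w > parent.width:
        raise ValueError(
            f"window {window_h}x{window_w} exceeds parent "
            f"{parent.height}x{parent.width}"
        )

    def offsets(extent: int, window: int) -> list[int]:
        span = extent - window
        return [int(np.floor(i * span / (k - 1) + 0.5)) for i in range(k)]

    row_offs = offsets(parent.height, window_h)
    col_offs = offsets(parent.width, window_w)
    regions = [
        Region(
            parent.top + row_offs[i],
            parent.top + row_offs[i] + window_h,
            parent.left + col_offs[j],
            parent.left + col_offs[j] + window_w,
            label=(i, j),
        )
        for i in range(k)
        for j in range(k)
    ]
    return RegionSet(regions, mode="overlap", shape=(k, k), parent=parent)


def argmax_entropy(
    img: np.ndarray, regions: RegionSet
) -> tuple[Region, float, list[float]]:
    """Score every region by Shannon entropy and return the winner.

    Returns ``(winner, winner_entropy, entropies)`` where ``entropies`` lists
    every region's entropy in row-major label order.  Ties are broken in
    favour of the smallest row-major label, making the search deterministic.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    entropies = [region_entropy(img, r) for r in regions]
    best = int(np.argmax(entropies))  # first occurrence wins on exact ties
    return regions.regions[best], entropies[best], entropies
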
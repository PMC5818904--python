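"""Window-layout laws: disjoint exact cover, overlap intersection,
refined-region geometry and deterministic entropy argmax."""

import numpy as np
import pytest

from entroloc import (
    Region,
    argmax_entropy,
    partition_nonoverlap,
    refined_region,
    region_entropy,
    subdivide_overlap,
)


def assert_disjoint_exact_cover(rs, parent):
    total = sum(r.area for r in rs)
    assert total == parent.area
    regions = list(rs)
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            assert not regions[a].intersects(regions[b])


class TestPartitionNonoverlap:
    def test_exact_division(self):
        rs = partition_nonoverlap(Region(0, 300, 0, 300), 3, 3)
        assert len(rs) == 9
        assert all(r.height == 100 and r.width == 100 for r in rs)
        assert_disjoint_exact_cover(rs, Region(0, 300, 0, 300))

    def test_remainder_absorbed_by_last_band(self):
        parent = Region(0, 301, 0, 302)
        rs = partition_nonoverlap(parent, 3, 3)
        assert rs[2, 2].height == 101 and rs[2, 2].width == 102
        assert rs[0, 0].height == 100 and rs[0, 0].width == 100
        assert_disjoint_exact_cover(rs, parent)
        assert sum(r.area for r in rs) == 301 * 302

    def test_unit_patches(self):
        rs = partition_nonoverlap(Region(0, 3, 0, 3), 3, 3)
        assert all(r.area == 1 for r in rs)

    @pytest.mark.parametrize("rows,cols", [(0, 3), (3, 0), (11, 3), (3, 11)])
    def test_invalid_grid_shape(self, rows, cols):
        with pytest.raises(ValueError):
            partition_nonoverlap(Region(0, 10, 0, 10), rows, cols)

    def test_row_major_label_order(self):
        rs = partition_nonoverlap(Region(0, 30, 0, 30), 3, 3)
        assert [r.label for r in rs] == [(i, j) for i in range(3) for j in range(3)]


class TestRefinedRegion:
    def test_interior_winner_doubles_linear_size(self):
        bounds = Region(0, 300, 0, 300)
        grid = partition_nonoverlap(bounds, 3, 3)
        rnew = refined_region(grid[1, 1], grid, bounds)
        assert (rnew.top, rnew.bottom, rnew.left, rnew.right) == (50, 250, 50, 250)
        assert rnew.height == 200 and rnew.width == 200

    def test_corner_winner_expands_only_inward(self):
        bounds = Region(0, 300, 0, 300)
        grid = partition_nonoverlap(bounds, 3, 3)
        rnew = refined_region(grid[0, 0], grid, bounds)
        assert (rnew.top, rnew.bottom, rnew.left, rnew.right) == (0, 150, 0, 150)

    def test_single_patch_grid_is_identity(self):
        bounds = Region(0, 50, 0, 60)
        grid = partition_nonoverlap(bounds, 1, 1)
        rnew = refined_region(grid[0, 0], grid, bounds)
        assert (rnew.top, rnew.bottom, rnew.left, rnew.right) == (0, 50, 0, 60)

    def test_always_contains_winner(self):
        bounds = Region(0, 97, 0, 113)
        grid = partition_nonoverlap(bounds, 3, 3)
        for winner in grid:
            assert refined_region(winner, grid, bounds).contains_region(winner)

    def test_foreign_winner_rejected(self):
        bounds = Region(0, 300, 0, 300)
        grid = partition_nonoverlap(bounds, 3, 3)
        with pytest.raises(ValueError):
            refined_region(Region(0, 10, 0, 10, label=(0, 0)), grid, bounds)


class TestSubdivideOverlap:
    def test_even_strides(self):
        rs = subdivide_overlap(Region(0, 200, 0, 200), 5, 100, 100)
        assert len(rs) == 25
        first, last = rs[0, 0], rs[4, 4]
        assert (first.top, first.left) == (0, 0)
        assert (last.bottom, last.right) == (200, 200)
        assert rs[1, 0].top == 25  # stride (200-100)/4

    def test_rounded_strides(self):
        rs = subdivide_overlap(Region(0, 200, 0, 200), 4, 100, 100)
        tops = [rs[i, 0].top for i in range(4)]
        assert tops == [0, 33, 67, 100]

    def test_degenerate_window_equals_parent(self):
        parent = Region(0, 40, 0, 40)
        rs = subdivide_overlap(parent, 3, 40, 40)
        assert all(
            (r.top, r.bottom, r.left, r.right) == (0, 40, 0, 40) for r in rs
        )

    def test_adjacent_windows_intersect_when_stride_below_window(self):
        rs = subdivide_overlap(Region(10, 110, 20, 140), 5, 60, 70)
        for i in range(5):
            for j in range(5):
                if i + 1 < 5:
                    assert rs[i, j].intersects(rs[i + 1, j])
                if j + 1 < 5:
                    assert rs[i, j].intersects(rs[i, j + 1])

    def test_window_larger_than_parent_rejected(self):
        with pytest.raises(ValueError):
            subdivide_overlap(Region(0, 50, 0, 50), 4, 60, 40)


class TestArgmaxEntropy:
    def test_noise_patch_beats_constant_patches(self, rng):
        img = np.full((90, 90), 50, dtype=np.uint8)
        img[30:60, 60:90] = rng.integers(0, 256, size=(30, 30))
        grid = partition_nonoverlap(Region(0, 90, 0, 90), 3, 3)
        winner, best, entropies = argmax_entropy(img, grid)
        assert winner.label == (1, 2)
        assert best > 0 and len(entropies) == 9

    def test_uniform_image_tie_breaks_to_first_label(self):
        img = np.full((60, 60), 128, dtype=np.uint8)
        grid = partition_nonoverlap(Region(0, 60, 0, 60), 3, 3)
        winner, best, _ = argmax_entropy(img, grid)
        assert winner.label == (0, 0) and best == 0.0

    def test_duplicated_patches_tie_break_row_major(self, rng):
        # identical texture in two patches: the smaller label must win
        tile = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        img = np.zeros((60, 60), dtype=np.uint8)
        img[20:40, 0:20] = tile  # label (1, 0)
        img[0:20, 40:60] = tile  # label (0, 2) -- earlier in row-major order
        grid = partition_nonoverlap(Region(0, 60, 0, 60), 3, 3)
        winner, _, _ = argmax_entropy(img, grid)
        assert winner.label == (0, 2)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        img = rng.integers(0, 256, size=(47, 53)).astype(np.uint8)
        grid = partition_nonoverlap(Region(0, 47, 0, 53), 3, 3)
        winner, best, entropies = argmax_entropy(img, grid)
        oracle = sorted(
            ((region_entropy(img, r), r.label) for r in grid),
            key=lambda t: (-t[0], t[1]),
        )
        assert winner.label == oracle[0][1]
        assert best == oracle[0][0]


def test_grid_laws_random_configurations(rng):
    """Partition: disjoint exact cover; overlap: neighbours intersect,
    first/last flush with the parent edges."""
    for _ in range(60):
        h = int(rng.integers(6, 120))
        w = int(rng.integers(6, 120))
        rows = int(rng.integers(1, min(h, 6) + 1))
        cols = int(rng.integers(1, min(w, 6) + 1))
        parent = Region(0, h, 0, w)
        assert_disjoint_exact_cover(partition_nonoverlap(parent, rows, cols), parent)

        k = int(rng.integers(2, 7))
        wh = int(rng.integers(max(h // 2, 1), h + 1))
        ww = int(rng.integers(max(w // 2, 1), w + 1))
        rs = subdivide_overlap(parent, k, wh, ww)
        assert rs[0, 0].top == 0 and rs[0, 0].left == 0
        assert rs[k - 1, k - 1].bottom == h and rs[k - 1, k - 1].right == w
        for i in range(k):
            for j in range(k):
                if i + 1 < k and rs[i + 1, j].top - rs[i, j].top < wh:
                    assert rs[i, j].intersects(rs[i + 1, j])
                if j + 1 < k and rs[i, j + 1].left - rs[i, j].left < ww:
                    assert rs[i, j].intersects(rs[i, j + 1])
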
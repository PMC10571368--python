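"""Binarization, connected components, edge extraction and the dynamic threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rsaseg import (
    BinaryMask,
    DegenerateInputWarning,
    NoPeakError,
    SurfaceHistogram,
    ToothComponent,
    VoxelVolume,
    binarize,
    classify_edges,
    connected_components,
    extract_edges,
    find_threshold,
    surface_histogram,
)


def vol_from(arr, **kw):
    return VoxelVolume(np.asarray(arr, dtype=np.uint8), **kw)


def otsu_bruteforce(intensities):
    """Scan all 256 cuts, maximizing between-class variance (the oracle)."""
    hist = np.bincount(intensities.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def edge_oracle(mask2d):
    """Exhaustive per-pixel 8-neighbourhood check on one slice."""
    h, w = mask2d.shape
    out = np.zeros_like(mask2d, dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mask2d[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or not mask2d[ny, nx]:
                        out[y, x] = True
    return out


def flood_fill_26(mask):
    """Label 3-D components by explicit 26-neighbour flood fill (the oracle)."""
    visited = np.zeros(mask.shape, dtype=bool)
    sizes = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack, size = [start], 0
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(p, mask.shape)) and mask[p] and not visited[p]:
                    visited[p] = True
                    stack.append(p)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestBinarize:
    def test_single_bright_voxel(self):
        arr = np.zeros((2, 4, 4), dtype=np.uint8)
        arr[1, 2, 2] = 200
        mask = binarize(vol_from(arr), air_threshold=50)
        assert mask.values.sum() == 1 and mask.values[1, 2, 2]

    def test_auto_threshold_matches_bruteforce_on_bimodal(self, rng):
        arr = np.where(rng.random((4, 8, 8)) < 0.5, 10, 200).astype(np.uint8)
        mask = binarize(vol_from(arr))
        assert np.array_equal(mask.values, arr == 200)
        t = otsu_bruteforce(arr)
        assert np.array_equal(mask.values, arr > t)

    def test_degenerate_threshold_warns(self):
        arr = np.full((1, 4, 4), 80, dtype=np.uint8)
        with pytest.warns(DegenerateInputWarning):
            mask = binarize(vol_from(arr), air_threshold=255)
        assert not mask.values.any()


class TestConnectedComponents:
    def test_two_separated_cubes(self):
        arr = np.zeros((8, 8, 8), dtype=bool)
        arr[1:3, 1:3, 1:3] = True
        arr[5:7, 5:7, 5:7] = True
        comps = connected_components(BinaryMask(arr), min_voxels=1)
        assert [c.voxel_count for c in comps] == [8, 8]

    def test_diagonal_touch_merges_under_26_connectivity(self):
        arr = np.zeros((6, 6, 6), dtype=bool)
        arr[1:4, 1:4, 1:4] = True
        arr[4, 4, 4] = True  # touches the cube corner diagonally
        comps = connected_components(BinaryMask(arr), min_voxels=1)
        assert [c.voxel_count for c in comps] == [28]
        assert flood_fill_26(arr) == [28]

    def test_small_specks_dropped_by_default(self):
        arr = np.zeros((4, 4, 4), dtype=bool)
        arr[1, 1, 1:3] = True
        assert connected_components(BinaryMask(arr)) == []

    def test_matches_flood_fill_on_random_masks(self, rng):
        for _ in range(10):
            arr = rng.random((5, 7, 7)) < 0.35
            comps = connected_components(BinaryMask(arr), min_voxels=1)
            assert [c.voxel_count for c in comps] == flood_fill_26(arr)


def component_of(mask3d):
    return ToothComponent(component_id=1, mask=BinaryMask(mask3d), voxel_count=int(mask3d.sum()))


class TestExtractEdges:
    def test_3x3_square_has_8_edge_pixels(self):
        arr = np.zeros((1, 5, 5), dtype=bool)
        arr[0, 1:4, 1:4] = True
        edges = extract_edges(component_of(arr))
        assert edges.pixel_count == 8
        assert not edges.values[0, 2, 2]  # centre is interior

    def test_isolated_pixel_is_an_edge(self):
        arr = np.zeros((1, 3, 3), dtype=bool)
        arr[0, 1, 1] = True
        assert extract_edges(component_of(arr)).pixel_count == 1

    @pytest.mark.parametrize("s", range(2, 11))
    def test_solid_square_perimeter_formula(self, s):
        arr = np.zeros((1, s + 2, s + 2), dtype=bool)
        arr[0, 1 : s + 1, 1 : s + 1] = True
        edges = extract_edges(component_of(arr))
        assert edges.pixel_count == 4 * s - 4
        assert np.array_equal(edges.values[0], edge_oracle(arr[0]))

    def test_volume_border_counts_as_background(self):
        arr = np.ones((1, 4, 4), dtype=bool)
        edges = extract_edges(component_of(arr))
        assert np.array_equal(edges.values[0], edge_oracle(arr[0]))
        assert edges.pixel_count == 12  # 4x4 block flush to the border: ring only

    def test_matches_exhaustive_oracle_on_random_slices(self, rng):
        for _ in range(50):
            arr = (rng.random((1, 7, 7)) < 0.5)
            edges = extract_edges(component_of(arr))
            assert np.array_equal(edges.values[0], edge_oracle(arr[0]))


class TestSurfaceHistogram:
    def test_counts_by_intensity(self):
        arr = np.zeros((1, 4, 4), dtype=np.uint8)
        arr[0, 0, :3] = (10, 10, 200)
        edges = np.zeros((1, 4, 4), dtype=bool)
        edges[0, 0, :3] = True
        hist = surface_histogram(vol_from(arr), extract_edges(component_of(edges)))
        assert hist.counts[10] == 2 and hist.counts[200] == 1
        assert hist.counts.sum() == 3

    def test_mass_equals_edge_count_on_random_volume(self, rng):
        arr = rng.integers(0, 256, size=(3, 8, 8), dtype=np.uint8)
        mask = arr > 100
        comps = connected_components(BinaryMask(mask), min_voxels=1)
        for comp in comps:
            edges = extract_edges(comp)
            hist = surface_histogram(vol_from(arr), edges)
            # independent voxelwise tally
            tally = sum(1 for v in arr[edges.values])
            assert hist.counts.sum() == edges.pixel_count == tally

    def test_empty_edges_warn(self):
        arr = np.zeros((1, 4, 4), dtype=np.uint8)
        with pytest.warns(DegenerateInputWarning):
            hist = surface_histogram(vol_from(arr), extract_edges(component_of(np.zeros((1, 4, 4), bool))))
        assert hist.counts.sum() == 0


def two_triangle_histogram():
    """Exact peaks at 80 and 180, unique zero valley at 130."""
    counts = np.zeros(256, dtype=np.int64)
    for i in range(1, 51):
        counts[80 - i] = 50 - i
        counts[80 + i] = 50 - i
        counts[180 - i] = 50 - i
        counts[180 + i] = 50 - i
    counts[80] = counts[180] = 50
    return SurfaceHistogram(counts)


class TestFindThreshold:
    def test_noiseless_bimodal_triangles(self):
        res = find_threshold(two_triangle_histogram(), smoothing_window=1)
        assert (res.P, res.X) == (80, 130)

    def test_unimodal_histogram_raises(self):
        counts = np.zeros(256, dtype=np.int64)
        for i in range(30):
            counts[100 - i] = 30 - i
            counts[100 + i] = 30 - i
        with pytest.raises(NoPeakError):
            find_threshold(SurfaceHistogram(counts), smoothing_window=1)

    def test_two_delta_histogram_threshold_between_modes(self):
        for a, b in [(20, 40), (90, 190), (3, 250)]:
            counts = np.zeros(256, dtype=np.int64)
            counts[a] = counts[b] = 500
            res = find_threshold(SurfaceHistogram(counts), smoothing_window=1)
            assert res.P == a
            assert a < res.X < b

    @settings(derandomize=True, max_examples=60)
    @given(a=st.integers(1, 234), sep=st.integers(21, 150), mass=st.integers(1, 10**6))
    def test_two_delta_threshold_lies_between_modes_property(self, a, sep, mass):
        b = a + sep
        if b > 254:
            return
        counts = np.zeros(256, dtype=np.int64)
        counts[a] = counts[b] = mass
        res = find_threshold(SurfaceHistogram(counts), smoothing_window=1)
        assert res.P == a
        assert a < res.X < b

    def test_noisy_bimodal_recovers_mixture_valley(self):
        rng = np.random.default_rng(42)
        samples = np.concatenate(
            [rng.normal(90, 10, 2500), rng.normal(190, 10, 2500)]
        )
        values = np.clip(np.round(samples), 0, 255).astype(int)
        hist = SurfaceHistogram(np.bincount(values, minlength=256))
        res = find_threshold(hist)
        # dense evaluation of the known mixture density between the means
        x = np.linspace(90, 190, 20001)
        density = stats.norm.pdf(x, 90, 10) + stats.norm.pdf(x, 190, 10)
        valley = x[np.argmin(density)]
        assert abs(res.X - valley) <= 3

    def test_constant_offset_leaves_P_and_X_unchanged(self):
        base = two_triangle_histogram()
        res0 = find_threshold(base, smoothing_window=1)
        shifted = SurfaceHistogram(base.counts + 1000)
        res1 = find_threshold(shifted, smoothing_window=1)
        assert (res0.P, res0.X) == (res1.P, res1.X)

    def test_smoothed_curve_is_returned_and_ordered(self):
        res = find_threshold(two_triangle_histogram(), smoothing_window=5)
        assert res.smoothed_counts.shape == (256,)
        assert 0 <= res.P < res.X <= 255


class TestClassifyEdges:
    def test_counts_split_at_threshold(self):
        arr = np.zeros((1, 4, 4), dtype=np.uint8)
        arr[0, 0, :3] = (100, 100, 200)
        edges = np.zeros((1, 4, 4), dtype=bool)
        edges[0, 0, :3] = True
        lab = classify_edges(vol_from(arr), extract_edges(component_of(edges)), 150)
        assert lab.root_edges.pixel_count == 2
        assert lab.crown_edges.pixel_count == 1

    def test_zero_threshold_sends_everything_to_crown(self):
        arr = np.full((1, 4, 4), 10, dtype=np.uint8)
        edges = extract_edges(component_of(np.ones((1, 4, 4), bool)))
        lab = classify_edges(vol_from(arr), edges, 0)
        assert lab.root_edges.pixel_count == 0
        assert lab.crown_edges.pixel_count == edges.pixel_count

    def test_partition_property_on_random_phantoms(self, rng):
        for _ in range(20):
            arr = rng.integers(0, 256, size=(2, 6, 6), dtype=np.uint8)
            edges = extract_edges(component_of(arr > 50))
            x = int(rng.integers(0, 256))
            lab = classify_edges(vol_from(arr), edges, x)
            union = lab.root_edges.values | lab.crown_edges.values
            inter = lab.root_edges.values & lab.crown_edges.values
            assert np.array_equal(union, edges.values)
            assert not inter.any()
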
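import numpy as np
import pytest
from scipy import ndimage as ndi

from flymuscle.errors import DegenerateHistogramError, GeometryError, SegmentationFailure
from flymuscle.segmentation import (
    LevelSetParams,
    SeedPolygon,
    evolve_levelset,
    manual_roi,
    otsu_threshold,
    rasterize_polygon,
    segment_nuclei,
)
from conftest import capsule_mask


def brute_force_even_odd(vertices, shape):
    """Independent ray-casting rasteriser (even-odd rule, pixel centres)."""
    verts = np.asarray(vertices, float)
    h, w = shape
    mask = np.zeros(shape, bool)
    n = len(verts)
    for y in range(h):
        for x in range(w):
            inside = False
            on_edge = False
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                # boundary check: point on segment
                cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
                if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 \
                        and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
                    on_edge = True
                    break
                if (y1 > y) != (y2 > y):
                    xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                    if x < xin:
                        inside = not inside
            mask[y, x] = inside or on_edge
    return mask


class TestRasterizePolygon:
    def test_axis_aligned_square_pixel_count(self):
        sq = SeedPolygon([(0.5, 0.5), (10.5, 0.5), (10.5, 10.5), (0.5, 10.5)])
        assert rasterize_polygon(sq, (16, 16)).sum() == 100

    def test_triangle_matches_ray_casting_oracle(self):
        tri = [(3.2, 4.7), (55.9, 10.1), (20.3, 58.4)]
        got = rasterize_polygon(SeedPolygon(tri), (64, 64))
        expected = brute_force_even_odd(tri, (64, 64))
        np.testing.assert_array_equal(got, expected)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            SeedPolygon([(0, 0), (5, 5)])

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(GeometryError):
            SeedPolygon([(0, 0), (4, 4), (4, 0), (0, 4)])  # bow-tie


class TestLevelSet:
    def _disk_image(self, r=20, contrast=200, background=10, shape=(64, 64)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        c = (shape[1] // 2, shape[0] // 2)
        disk = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r**2
        img = np.full(shape, background, float)
        img[disk] = contrast
        return img, disk

    def test_bright_disk_recovered(self):
        img, disk = self._disk_image()
        seed = SeedPolygon([(4, 4), (59, 4), (59, 59), (4, 59)])
        roi = evolve_levelset(img, seed)
        jac = (roi.mask & disk).sum() / (roi.mask | disk).sum()
        assert jac >= 0.95

    def test_seed_on_boundary_stays_put(self):
        img, disk = self._disk_image(r=18)
        # many-sided seed polygon drawn exactly on the disk boundary
        angles = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        seed = SeedPolygon(
            np.column_stack([32 + 18.0 * np.cos(angles), 32 + 18.0 * np.sin(angles)])
        )
        roi = evolve_levelset(img, seed)
        seed_mask = rasterize_polygon(seed, img.shape)
        frac_changed = np.count_nonzero(roi.mask ^ seed_mask) / seed_mask.sum()
        assert frac_changed <= 0.02

    def test_uniform_image_signals_failure(self):
        img = np.full((48, 48), 120.0)
        seed = SeedPolygon([(8, 8), (40, 8), (40, 40), (8, 40)])
        with pytest.raises(SegmentationFailure):
            evolve_levelset(img, seed)

    def test_output_contained_in_seed(self, rng):
        img, _ = self._disk_image()
        img = img + rng.normal(0, 3, img.shape)
        # irregular seed polygon fully enclosing the disk
        angles = np.linspace(0, 2 * np.pi, 9, endpoint=False)
        radii = rng.uniform(24, 28, 9)
        seed = SeedPolygon(
            np.column_stack([32 + radii * np.cos(angles), 32 + radii * np.sin(angles)])
        )
        roi = evolve_levelset(img, seed)
        assert not (roi.mask & ~rasterize_polygon(seed, img.shape)).any()


class TestManualROI:
    def test_square_area(self):
        sq = SeedPolygon([(0.5, 0.5), (10.5, 0.5), (10.5, 10.5), (0.5, 10.5)])
        roi = manual_roi(sq, (16, 16))
        assert roi.area_px == 100
        assert roi.source == "manual"

    def test_deterministic_apart_from_id(self):
        sq = SeedPolygon([(1, 1), (8, 1), (8, 6), (1, 6)])
        a = manual_roi(sq, (16, 16))
        b = manual_roi(sq, (16, 16))
        assert a.roi_id != b.roi_id
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.centroid == b.centroid

    def test_out_of_bounds_rejected(self):
        sq = SeedPolygon([(10, 10), (30, 10), (30, 30), (10, 30)])
        with pytest.raises(GeometryError):
            manual_roi(sq, (16, 16))


def exhaustive_otsu(hist):
    """Independent exhaustive search over all 255 cut points."""
    hist = np.asarray(hist, float)
    levels = np.arange(256)
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = hist[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[:t] * hist[:t]).sum() / w0
        mu1 = (levels[t:] * hist[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        hist = np.zeros(256)
        hist[10] = 500
        hist[200] = 500
        assert 10 < otsu_threshold(hist) <= 200

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(1000):
            hist = np.zeros(256)
            idx = rng.integers(0, 256, size=rng.integers(2, 40))
            counts = rng.integers(1, 100, size=len(idx))
            np.add.at(hist, idx, counts)
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == exhaustive_otsu(hist)

    def test_constant_image_degenerate(self):
        hist = np.zeros(256)
        hist[37] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist)


class TestSegmentNuclei:
    def _roi_with_mask(self, mask):
        poly = SeedPolygon(
            [(-0.5, -0.5), (mask.shape[1] - 0.5, -0.5),
             (mask.shape[1] - 0.5, mask.shape[0] - 0.5), (-0.5, mask.shape[0] - 0.5)]
        )
        from flymuscle.segmentation import MuscleROI, mask_centroid

        return MuscleROI(
            roi_id=999,
            stack_name="t",
            frame_idx=0,
            polygon=poly.vertices,
            mask=mask,
            centroid=mask_centroid(mask),
            source="manual",
        )

    def test_three_blobs_found(self):
        img = np.full((60, 60), 8.0)
        for cx, cy in [(15, 15), (40, 20), (25, 45)]:
            yy, xx = np.mgrid[0:60, 0:60]
            img += 180 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 3.0**2))
        roi = self._roi_with_mask(np.ones((60, 60), bool))
        regions = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8), roi)
        assert len(regions) == 3

    def test_uniform_red_gives_no_regions(self):
        roi = self._roi_with_mask(np.ones((20, 20), bool))
        assert segment_nuclei(np.full((20, 20), 50, np.uint8), roi) == []

    def test_blob_clipped_to_parent_roi(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = np.full((40, 40), 5.0)
        img += 200 * np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * 4.0**2))
        half = np.zeros((40, 40), bool)
        half[:, :21] = True  # ROI covers only the left half of the blob
        roi = self._roi_with_mask(half)
        regions = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8), roi)
        assert regions
        for r in regions:
            assert not (r.mask & ~roi.mask).any()

    def test_regions_disjoint_and_contained(self, rng):
        img = np.full((50, 50), 10.0)
        for _ in range(4):
            cx, cy = rng.uniform(8, 42, 2)
            yy, xx = np.mgrid[0:50, 0:50]
            img += 170 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.5**2))
        mask = capsule_mask((50, 50), (5, 25), (45, 25), 30)
        roi = self._roi_with_mask(mask)
        regions = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8), roi)
        total = np.zeros((50, 50), int)
        for r in regions:
            assert not (r.mask & ~mask).any()
            total += r.mask
        assert total.max() <= 1  # pairwise disjoint
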
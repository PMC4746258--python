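import numpy as np
import pytest

import hypoquant as hq
from hypoquant.segmentation import SegmentationParams, _otsu_threshold

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_force_pair_saliencies(labels, smoothed):
    """All adjacent region pairs with dam-minimum saliency, by full scan."""
    h, w = labels.shape
    region_min = {}
    for k in np.unique(labels):
        if k > 0:
            region_min[int(k)] = smoothed[labels == k].min()
    dammin = {}
    for r in range(h):
        for c in range(w):
            if labels[r, c] != 0:
                continue
            touching = set()
            for dr, dc in NB8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                    touching.add(int(labels[rr, cc]))
            for a in touching:
                for b in touching:
                    if a < b:
                        key = (a, b)
                        dammin[key] = min(dammin.get(key, np.inf), smoothed[r, c])
    return {
        k: v - max(region_min[k[0]], region_min[k[1]]) for k, v in dammin.items()
    }


def brute_force_merge(labels, smoothed, threshold):
    """Reference merger: rescan everything after every single merge."""
    labels = labels.copy()
    while True:
        sal = brute_force_pair_saliencies(labels, smoothed)
        if not sal:
            break
        (a, b), s = min(sal.items(), key=lambda kv: (kv[1], kv[0]))
        if s >= threshold:
            break
        h, w = labels.shape

        def touching(r, c):
            return {
                int(labels[r + dr, c + dc])
                for dr, dc in NB8
                if 0 <= r + dr < h and 0 <= c + dc < w and labels[r + dr, c + dc] > 0
            }

        # dam pixels lying *between* the two regions, recorded before merging
        between = [
            (r, c)
            for r in range(h)
            for c in range(w)
            if labels[r, c] == 0 and {a, b} <= touching(r, c)
        ]
        labels[labels == b] = a
        for r, c in between:
            if touching(r, c) == {a}:
                labels[r, c] = a
    from skimage.segmentation import relabel_sequential

    return relabel_sequential(labels)[0]


def brute_force_otsu(values, nbins=256):
    """Exhaustive between-class-variance scan over equal-width bin edges."""
    values = np.asarray(values, float)
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return None
    edges = np.linspace(vmin, vmax, nbins + 1)
    best, best_t = -1.0, None
    for t in edges[1:-1]:
        lo = values[values < t]
        hi = values[values >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best + 1e-12:
            best, best_t = v, t
    return best_t


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_constant_raster_unchanged(self):
        ref = np.full((9, 9), 7.0)
        np.testing.assert_allclose(hq.smooth_reference(ref, 1.0), ref)

    def test_unit_impulse_mass_conserved(self):
        ref = np.zeros((21, 21))
        ref[10, 10] = 1.0
        out = hq.smooth_reference(ref, 1.0)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_variance_zero_is_identity(self):
        ref = np.random.default_rng(0).uniform(0, 255, (8, 8))
        np.testing.assert_array_equal(hq.smooth_reference(ref, 0.0), ref)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            hq.smooth_reference(np.zeros((4, 4)), -1.0)


# ---------------------------------------------------------------------------
# watershed + merging
# ---------------------------------------------------------------------------

class TestWatershedToys:
    def test_deep_dam_survives(self, toys):
        f = toys["two_basin_deep"]
        labels = hq.watershed_cells(f["raster"], SegmentationParams(0.0, f["merge_threshold"]))
        assert labels.max() == f["expected_n_regions"] == 2

    def test_shallow_dam_merges(self, toys):
        f = toys["two_basin_shallow"]
        labels = hq.watershed_cells(f["raster"], SegmentationParams(0.0, f["merge_threshold"]))
        assert labels.max() == f["expected_n_regions"] == 1

    def test_chain_merges_transitively(self, toys):
        f = toys["three_chain"]
        labels = hq.watershed_cells(f["raster"], SegmentationParams(0.0, f["merge_threshold"]))
        assert labels.max() == 1

    def test_toy_saliencies_match_embedded_values(self, toys):
        from skimage.segmentation import watershed
        from skimage.morphology import local_minima
        from scipy import ndimage as ndi

        for name in ("two_basin_deep", "two_basin_shallow"):
            f = toys[name]
            raster = f["raster"]
            markers, _ = ndi.label(local_minima(raster, connectivity=1))
            labels = watershed(raster, markers, connectivity=1, watershed_line=True)
            sal = brute_force_pair_saliencies(labels, raster)
            assert pytest.approx(min(sal.values())) == f["expected_saliency"]

    def test_flat_image_single_region_warns(self, caplog):
        with caplog.at_level("WARNING"):
            labels = hq.watershed_cells(np.full((8, 8), 3.0), SegmentationParams(0.0, 10.0))
        assert labels.max() == 1

    def test_constant_intensity_shift_invariance(self, toys):
        raster = toys["three_chain"]["raster"]
        a = hq.watershed_cells(raster, SegmentationParams(0.0, 5.0))
        b = hq.watershed_cells(raster + 40.0, SegmentationParams(0.0, 5.0))
        np.testing.assert_array_equal(a, b)


class TestMergeShallowRegions:
    @pytest.fixture()
    def random_watershed(self):
        """Small random landscape with its raw watershed labels."""
        from skimage.segmentation import watershed
        from skimage.morphology import local_minima
        from scipy import ndimage as ndi

        rng = np.random.default_rng(5)
        raster = hq.smooth_reference(rng.uniform(0, 60, (28, 28)), 1.0)
        markers, _ = ndi.label(local_minima(raster, connectivity=1))
        labels = watershed(raster, markers, connectivity=1, watershed_line=True)
        return labels.astype(np.int32), raster

    def test_threshold_zero_is_identity(self, random_watershed):
        labels, raster = random_watershed
        out = hq.merge_shallow_regions(labels, raster, 0.0)
        assert out.max() == labels.max()

    def test_matches_brute_force_reference(self, random_watershed):
        labels, raster = random_watershed
        for thr in (2.0, 5.0, 10.0):
            ours = hq.merge_shallow_regions(labels, raster, thr)
            ref = brute_force_merge(labels, raster, thr)
            # identical partitions (label names may differ)
            assert ours.max() == ref.max()
            joint = set(zip(ours.ravel().tolist(), ref.ravel().tolist()))
            assert len(joint) == len({a for a, _ in joint})
            assert len(joint) == len({b for _, b in joint})

    def test_pairwise_decision_against_oracle(self, toys):
        # saliency 5 merges below threshold 10, saliency 190 is kept
        for name, merged in (("two_basin_shallow", True), ("two_basin_deep", False)):
            raster = toys[name]["raster"]
            labels = hq.watershed_cells(raster, SegmentationParams(0.0, 10.0))
            assert bool(labels.max() == 1) == merged

    def test_region_count_monotone_in_threshold(self, random_watershed):
        labels, raster = random_watershed
        counts = [
            hq.merge_shallow_regions(labels, raster, thr).max()
            for thr in (0.0, 1.0, 3.0, 6.0, 12.0, 30.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hq.merge_shallow_regions(np.ones((3, 3), int), np.zeros((4, 4)), 1.0)


# ---------------------------------------------------------------------------
# lumen extraction (per-cell Otsu)
# ---------------------------------------------------------------------------

class TestExtractLumen:
    def test_bimodal_cell_exact_lumen(self, toys):
        f = toys["bimodal_cell"]
        roil = hq.extract_lumen(f["reference"], f["roic"])
        np.testing.assert_array_equal(roil > 0, f["expected_lumen_mask"])

    def test_threshold_between_modes(self, toys):
        f = toys["bimodal_cell"]
        thr = _otsu_threshold(f["reference"][f["roic"] > 0])
        lo, hi = f["modes"]
        assert lo < thr < hi

    def test_per_cell_thresholds_match_brute_force(self):
        rng = np.random.default_rng(2)
        ref = np.zeros((10, 22))
        roic = np.zeros((10, 22), dtype=np.int32)
        # two cells with different contrast ranges
        roic[:, :10] = 1
        roic[:, 12:] = 2
        ref[:, :10] = rng.normal(30, 4, (10, 10)).clip(0)
        ref[:3, :10] = rng.normal(120, 6, (3, 10))
        ref[:, 12:] = rng.normal(10, 1, (10, 10)).clip(0)
        ref[:3, 12:] = rng.normal(40, 2, (3, 10))
        thresholds = {}
        for k in (1, 2):
            vals = ref[roic == k]
            thresholds[k] = _otsu_threshold(vals)
            assert thresholds[k] == pytest.approx(brute_force_otsu(vals))
        assert thresholds[1] != thresholds[2]
        # thresholds agree with skimage's Otsu to within one histogram bin
        from skimage.filters import threshold_otsu

        for k in (1, 2):
            vals = ref[roic == k]
            bin_width = (vals.max() - vals.min()) / 256
            assert abs(thresholds[k] - threshold_otsu(vals, nbins=256)) <= bin_width

    def test_constant_cell_has_empty_lumen(self):
        ref = np.full((5, 5), 9.0)
        roic = np.ones((5, 5), dtype=np.int32)
        assert hq.extract_lumen(ref, roic).max() == 0


# ---------------------------------------------------------------------------
# wall derivation + cropping + invariants
# ---------------------------------------------------------------------------

class TestDeriveWall:
    def test_partition_identity(self, toys):
        f = toys["bimodal_cell"]
        roil = hq.extract_lumen(f["reference"], f["roic"])
        roiw = hq.derive_wall(f["roic"], roil)
        assert (roiw > 0).sum() + (roil > 0).sum() == (f["roic"] > 0).sum()

    def test_empty_lumen_gives_full_wall(self):
        roic = np.ones((4, 4), dtype=np.int32)
        roiw = hq.derive_wall(roic, np.zeros_like(roic))
        np.testing.assert_array_equal(roiw, roic)

    def test_full_lumen_warns_empty_wall(self):
        roic = np.ones((4, 4), dtype=np.int32)
        with pytest.warns(UserWarning, match="empty wall"):
            roiw = hq.derive_wall(roic, roic.copy())
        assert roiw.max() == 0

    def test_inconsistent_lumen_rejected(self):
        roic = np.zeros((4, 4), dtype=np.int32)
        roic[:2] = 1
        roil = np.zeros_like(roic)
        roil[3, 3] = 1  # lumen pixel outside cell 1
        with pytest.raises(ValueError):
            hq.derive_wall(roic, roil)


class TestCropRestrict:
    @pytest.fixture()
    def two_cell_seg(self):
        roic = np.zeros((10, 20), dtype=np.int32)
        roic[2:8, 2:8] = 1    # centroid x=4.5
        roic[2:8, 12:18] = 2  # centroid x=14.5
        roil = np.zeros_like(roic)
        roil[4:6, 4:6] = 1
        roiw = np.where((roic > 0) & (roil == 0), roic, 0)
        return hq.CellSegmentation(roic, roil, roiw)

    def test_full_rectangle_is_identity(self, two_cell_seg):
        out = hq.crop_restrict(two_cell_seg, (0, 0, 20, 10))
        np.testing.assert_array_equal(out.roic, two_cell_seg.roic)

    def test_left_half_keeps_left_centroid_cell(self, two_cell_seg):
        out = hq.crop_restrict(two_cell_seg, (0, 0, 10, 10))
        assert out.n_cells == 1
        # full footprint retained, not clipped
        assert (out.roic > 0).sum() == 36

    def test_point_rectangle_on_centroid(self, two_cell_seg):
        out = hq.crop_restrict(two_cell_seg, (14.5, 4.5, 14.5, 4.5))
        assert out.n_cells == 1
        assert (out.roic > 0).sum() == 36

    def test_empty_result_rejected(self, two_cell_seg):
        with pytest.raises(ValueError):
            hq.crop_restrict(two_cell_seg, (0, 0, 1, 1))


class TestConsistencyInvariants:
    def test_segment_image_maps_mutually_consistent(self, small_tissue):
        image, _ = small_tissue
        seg = hq.segment_image(image.reference)
        seg.validate()  # raises on any violated invariant
        assert seg.n_cells > 10

    def test_crop_preserves_consistency(self, small_tissue):
        image, truth = small_tissue
        seg = hq.segment_image(image.reference)
        cropped = hq.crop_restrict(seg, (64, 64, 192, 192))
        cropped.validate()
        assert 0 < cropped.n_cells < seg.n_cells
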
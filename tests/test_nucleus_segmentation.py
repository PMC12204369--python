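import numpy as np
import pytest
from scipy import ndimage

from chromodomain3d.image_io import ImageStack
from chromodomain3d.nucleus_segmentation import (
    NoNucleusFoundError,
    accept_nucleus,
    candidate_regions,
    circularity,
    dapi_threshold_mask,
    detect_boundary,
    refine_region,
    segment_nucleus,
)
from chromodomain3d.synthetic_data import generate_cell, rasterize_ellipsoid
from chromodomain3d.z_interpolation import interpolate_z

from conftest import small_spec


def disk(radius, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return yy**2 + xx**2 <= radius**2


class TestThreshold:
    def test_strictly_greater_semantics(self):
        slide = np.array([[400.0, 500.0, 600.0]])
        np.testing.assert_array_equal(
            dapi_threshold_mask(slide, 500), [[False, False, True]]
        )

    def test_all_zero_slide_gives_empty_mask(self):
        assert not dapi_threshold_mask(np.zeros((5, 5))).any()

    def test_zero_threshold_on_positive_slide_is_all_on(self):
        assert dapi_threshold_mask(np.ones((4, 4)), 0).all()


class TestCandidates:
    def test_diagonal_pixels_join_under_8_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        regions = candidate_regions(mask)
        assert len(regions) == 1
        assert regions[0].sum() == 2

    def test_top_k_truncation(self):
        mask = np.zeros((5, 100), bool)
        for i in range(20):  # 20 disjoint blobs
            mask[1:3, 5 * i : 5 * i + 2] = True
        assert len(candidate_regions(mask, top_k=15)) == 15

    def test_empty_mask_yields_no_regions(self):
        assert candidate_regions(np.zeros((3, 3), bool)) == []

    def test_sorted_by_size_then_position(self):
        mask = np.zeros((10, 30), bool)
        mask[1:4, 1:4] = True      # 9 px at (1,1)
        mask[6:8, 6:8] = True      # 4 px at (6,6)
        mask[1:3, 20:22] = True    # 4 px at (1,20) -> before (6,6) on tie
        regions = candidate_regions(mask)
        sizes = [int(r.sum()) for r in regions]
        assert sizes == [9, 4, 4]
        assert regions[1][1, 20] and regions[2][6, 6]


def brute_force_dilate(mask, iterations):
    """Oracle: 8-neighbour max filter applied `iterations` times."""
    out = mask.copy()
    for _ in range(iterations):
        out = ndimage.maximum_filter(out.astype(np.uint8), size=3).astype(bool)
    return out


class TestRefine:
    def test_matches_brute_force_dilation_oracle(self):
        rng = np.random.default_rng(4)
        mask = rng.random((40, 40)) > 0.8
        got = refine_region(mask, dilation_iters=3)
        oracle = ndimage.binary_fill_holes(
            brute_force_dilate(ndimage.binary_fill_holes(mask), 3)
        )
        np.testing.assert_array_equal(got, oracle)

    def test_disk_grows_by_dilation_radius(self):
        d = disk(10, pad=15)
        refined = refine_region(d, dilation_iters=10)
        assert refined.sum() > d.sum()
        assert refined[d].all()  # superset of the input
        # 10 iterations of a 3x3 element extend the half-width by 10 px
        assert refined[25, 25 + 20] and not refined[25, 25 + 21]

    def test_annulus_is_filled(self):
        yy, xx = np.mgrid[:27, :27] - 13
        r2 = yy**2 + xx**2
        ring = (r2 <= 100) & (r2 > 36)
        refined = refine_region(ring, dilation_iters=1)
        assert refined[13, 13]  # centre hole closed

    def test_empty_stays_empty(self):
        assert not refine_region(np.zeros((5, 5), bool)).any()


class TestAcceptance:
    def test_large_round_disk_accepted(self):
        ok, score = accept_nucleus(disk(200), min_pixels=100_000)
        assert ok and score > 0.9

    def test_small_disk_rejected_on_size(self):
        ok, score = accept_nucleus(disk(100), min_pixels=100_000)
        assert not ok and score > 0.9  # shape fine, size not

    def test_thin_line_rejected_on_shape(self):
        line = np.zeros((3, 2000), bool)
        line[1] = True
        ok, score = accept_nucleus(line, min_pixels=1000, min_shape=0.4)
        assert not ok and score < 0.05


def erosion_difference(mask):
    """Oracle: ON pixels with at least one OFF 4-neighbour."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


class TestBoundary:
    def test_rectangle_boundary_equals_erosion_difference(self):
        mask = np.zeros((12, 15), bool)
        mask[3:9, 4:12] = True
        got = {tuple(p) for p in detect_boundary(mask)}
        expected = {tuple(p) for p in erosion_difference(mask)}
        assert got == expected

    def test_random_blobs_sound_against_oracle(self):
        """On arbitrary blobs the Sobel boundary is a subset of the
        erosion-difference boundary, and any pixel it misses has an
        exactly cancelling gradient (1-px-thin structure)."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            mask = ndimage.binary_dilation(rng.random((30, 30)) > 0.93, iterations=2)
            got = {tuple(p) for p in detect_boundary(mask)}
            expected = {tuple(p) for p in erosion_difference(mask)}
            assert got <= expected
            gy = ndimage.sobel(mask.astype(float), axis=0, mode="constant")
            gx = ndimage.sobel(mask.astype(float), axis=1, mode="constant")
            for p in expected - got:
                assert np.hypot(gy[p], gx[p]) == 0.0

    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert {tuple(p) for p in detect_boundary(mask)} == {(2, 2)}

    def test_empty_mask_has_no_boundary(self):
        assert detect_boundary(np.zeros((4, 4), bool)).size == 0


class TestSegmentNucleus:
    def test_recovers_synthetic_ellipsoid(self, small_cell):
        stack, truth = small_cell
        interp = interpolate_z(stack)
        nucleus = segment_nucleus(interp, min_pixels=1200)
        true_mask = rasterize_ellipsoid(
            truth.nucleus_center_um, truth.nucleus_semiaxes_um,
            interp.shape_zyx, interp.spacing,
        )
        recall = (nucleus.mask & true_mask).sum() / true_mask.sum()
        assert recall >= 0.95

    def test_boundary_voxels_touch_background(self, small_cell):
        stack, _ = small_cell
        interp = interpolate_z(stack)
        nucleus = segment_nucleus(interp, min_pixels=1200)
        m = nucleus.mask
        for z, y, x in nucleus.boundary[::37]:
            assert m[z, y, x]
            neigh = [
                m[z, yy, xx]
                for yy, xx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1))
                if 0 <= yy < m.shape[1] and 0 <= xx < m.shape[2]
            ]
            assert (not all(neigh)) or len(neigh) < 4

    def test_raising_threshold_never_enlarges_mask(self, small_cell):
        stack, _ = small_cell
        interp = interpolate_z(stack)
        low = segment_nucleus(interp, threshold=500, min_pixels=1200)
        high = segment_nucleus(interp, threshold=650, min_pixels=1200)
        assert not (high.mask & ~low.mask).any()

    def test_all_background_stack_raises(self):
        vox = np.full((1, 4, 32, 32), 50.0)
        stack = ImageStack(vox, (0.05, 0.06, 0.06), ["DAPI"])
        with pytest.raises(NoNucleusFoundError, match="no nucleus"):
            segment_nucleus(stack, min_pixels=10)

    def test_two_nuclei_detected_as_disjoint_regions(self):
        spec = small_spec(n_domains=0, nucleus_semiaxes_um=(0.5, 1.3, 1.3))
        stack, truth = generate_cell(spec)
        # add a second, well-separated nucleus to the DAPI channel
        second = rasterize_ellipsoid(
            (truth.nucleus_center_um[0], 1.0, 1.0), (0.45, 0.8, 0.8),
            stack.shape_zyx, stack.spacing,
        )
        vox = stack.voxels.copy()
        vox[0][second] = 800.0
        stack2 = ImageStack(vox, stack.spacing, stack.channel_names)
        nucleus = segment_nucleus(stack2, min_pixels=400)
        mid = [r for r in nucleus.per_slide_regions if r.slide == stack.shape_zyx[0] // 2]
        assert len(mid) == 2

    def test_circularity_of_perfect_disk_near_one(self):
        assert circularity(disk(50)) == pytest.approx(1.0, abs=0.12)
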
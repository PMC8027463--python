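import numpy as np
import pytest

from hemoflow.synthetic import generate_band_frame
from hemoflow.vesselmap import (
    VesselMask,
    binarize,
    detect_nodes,
    prune_spurs,
    skeletonize_mask,
    split_segments,
    vesselness_filter,
)


def band_mask_segments(width_px, orientation_deg, calibration, shape=(140, 140)):
    """Run skeleton -> nodes -> segments on an ideal band mask."""
    _, mask_true = generate_band_frame(shape, width_px, orientation_deg)
    vm = VesselMask(mask_true, mask_true.astype(float))
    skel = skeletonize_mask(vm)
    return split_segments(skel, detect_nodes(skel), vm, calibration, min_length_px=10)


class TestVesselness:
    def test_constant_frame_gives_zero_response(self):
        assert not vesselness_filter(np.full((32, 32), 0.7)).any()

    def test_ridge_maximum_on_band_midline(self):
        # scales matched to the half-width; much smaller sigmas respond
        # at the band edges instead of its centre
        frame, mask = generate_band_frame((80, 80), 10.0, 0.0)
        resp = vesselness_filter(frame, scales=(3, 6, 9, 12))
        col = resp[10:-10, 40]
        assert abs((np.argmax(col) + 10) - 39.5) <= 1.0

    def test_two_band_widths_both_detected(self):
        f1, _ = generate_band_frame((120, 120), 6.0, 0.0)
        f2, _ = generate_band_frame((120, 120), 30.0, 90.0)
        frame = np.minimum(f1, f2)
        resp = vesselness_filter(frame, scales=(2.5, 6, 9, 15))
        mid = 59  # midline index for both bands
        assert resp[mid, 30] > 0.5 * resp.max()  # horizontal band of width 6
        assert resp[30, mid] > 0.5 * resp.max()  # vertical band of width 30

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            vesselness_filter(np.zeros((8, 8)), scales=[])


class TestBinarize:
    def test_zero_response_gives_empty_mask(self):
        m = binarize(np.zeros((16, 16)))
        assert not m.binary.any()

    def test_single_band_recovered(self):
        # scales up to the band half-width: larger sigmas respond with
        # support wider than the structure
        frame, mask_true = generate_band_frame((100, 100), 10.0, 30.0)
        m = binarize(vesselness_filter(frame, scales=(2.5, 5.0)))
        hits = (m.binary & mask_true).sum()
        assert hits / mask_true.sum() >= 0.9
        assert (m.binary & ~mask_true).sum() <= 0.1 * m.binary.sum()

    def test_subthreshold_ridge_dropped(self):
        resp = np.zeros((60, 60))
        resp[10, 5:55] = 1.0  # strong ridge
        resp[40, 5:55] = 0.01  # below the low threshold fraction
        m = binarize(resp, low=0.05, high=0.15, min_size=10)
        from skimage.measure import label

        assert label(m.binary, connectivity=2).max() == 1


class TestSkeleton:
    def test_band_skeleton_on_midline(self, calib2):
        _, mask_true = generate_band_frame((80, 80), 10.0, 0.0)
        skel = skeletonize_mask(VesselMask(mask_true, mask_true.astype(float)))
        rows = np.argwhere(skel)[:, 0]
        assert np.all(np.abs(rows - 39.5) <= 1.0)

    def test_empty_mask_empty_skeleton(self):
        m = VesselMask(np.zeros((10, 10), bool), np.zeros((10, 10)))
        assert not skeletonize_mask(m).any()

    def test_plus_shape_has_one_branch_cluster(self):
        mask = np.zeros((60, 60), bool)
        mask[27:33, 5:55] = True
        mask[5:55, 27:33] = True
        skel = skeletonize_mask(VesselMask(mask, mask.astype(float)))
        clusters, _ = detect_nodes(skel)
        assert len(clusters) == 1


class TestDetectNodes:
    def test_straight_line(self):
        skel = np.zeros((20, 20), bool)
        skel[10, 2:18] = True
        clusters, ends = detect_nodes(skel)
        assert len(ends) == 2 and len(clusters) == 0

    def test_y_shape(self):
        skel = np.zeros((30, 30), bool)
        skel[15, 2:15] = True  # stem
        for i in range(1, 12):  # two diagonal arms
            skel[15 - i, 14 + i] = True
            skel[15 + i, 14 + i] = True
        clusters, ends = detect_nodes(skel)
        assert len(ends) == 3
        assert len(clusters) == 1

    def test_closed_loop(self):
        # ring annulus thinned to a 1-px loop
        yy, xx = np.mgrid[0:40, 0:40]
        r = np.hypot(yy - 19.5, xx - 19.5)
        ring = (r > 8) & (r < 14)
        skel = skeletonize_mask(VesselMask(ring, ring.astype(float)))
        clusters, ends = detect_nodes(skel)
        assert len(ends) == 0 and len(clusters) == 0


class TestSplitSegments:
    def test_band_diameter_in_um(self, calib2):
        segs = band_mask_segments(10.0, 20.0, calib2)
        assert len(segs) == 1
        assert segs[0].diameter_um == pytest.approx(20.0, abs=2 * calib2.pixel_scale_um)

    def test_thin_band_lands_in_group_one(self):
        from hemoflow.hemodynamics import assign_group
        from hemoflow.video_io import CalibrationProfile

        cal = CalibrationProfile(1.5, 60.0)
        segs = band_mask_segments(3.0, 0.0, cal)
        assert segs[0].diameter_um == pytest.approx(4.5, abs=1.6)
        assert assign_group(segs[0].diameter_um) == 1

    def test_y_vessel_gives_three_segments(self, calib2):
        mask = np.zeros((80, 80), bool)
        mask[37:43, 2:40] = True
        for i in range(36):
            r = 40 - i // 2
            mask[r - 3 : r + 3, 39 + i // 2] = True
            r = 40 + i // 2
            mask[r - 3 : r + 3, 39 + i // 2] = True
        vm = VesselMask(mask, mask.astype(float))
        skel = skeletonize_mask(vm)
        segs = split_segments(skel, detect_nodes(skel), vm, calib2, min_length_px=5)
        assert len(segs) == 3

    def test_empty_skeleton_gives_no_segments(self, calib2):
        m = VesselMask(np.zeros((10, 10), bool), np.zeros((10, 10)))
        assert split_segments(np.zeros((10, 10), bool), ([], []), m, calib2) == []

    def test_pixel_conservation(self, calib2):
        """Segment body pixels + branch pixels account for every skeleton pixel."""
        mask = np.zeros((80, 80), bool)
        mask[37:43, 2:78] = True
        mask[2:78, 37:43] = True
        vm = VesselMask(mask, mask.astype(float))
        skel = skeletonize_mask(vm)
        nodes = detect_nodes(skel)
        segs = split_segments(skel, nodes, vm, calib2, min_length_px=1)
        branch_px = {tuple(p) for c in nodes[0] for p in c}
        seg_px = set()
        for s in segs:
            seg_px.update(map(tuple, s.points))
        assert seg_px | branch_px == set(map(tuple, np.argwhere(skel)))

    @pytest.mark.parametrize("width", [6.0, 14.0, 28.0])
    def test_diameter_invariant_to_90_degree_rotation(self, width, calib2):
        d0 = band_mask_segments(width, 0.0, calib2)[0].diameter_um
        d90 = band_mask_segments(width, 90.0, calib2)[0].diameter_um
        assert d90 == pytest.approx(d0, rel=0.02)

    @pytest.mark.parametrize("orientation", [0, 30, 45, 60, 90, 135])
    def test_band_width_recovery_across_orientations(self, orientation, calib2):
        for width in (4, 12, 24, 40):
            segs = band_mask_segments(width, orientation, calib2)
            segs.sort(key=lambda s: -len(s.points))
            d_px = segs[0].diameter_um / calib2.pixel_scale_um
            assert abs(d_px - width) <= 1.5


class TestPruneSpurs:
    def test_short_terminal_branch_removed(self):
        skel = np.zeros((40, 40), bool)
        skel[20, 2:38] = True
        for i in range(1, 6):  # 5-px spur
            skel[20 - i, 10 + i] = True
        pruned = prune_spurs(skel, min_branch_px=8)
        clusters, ends = detect_nodes(pruned)
        assert len(clusters) == 0 and len(ends) == 2

    def test_long_branches_kept(self):
        from skimage.measure import label

        skel = np.zeros((40, 40), bool)
        skel[20, 2:38] = True
        for i in range(1, 15):
            skel[20 - i, 10 + i] = True
        pruned = prune_spurs(skel, min_branch_px=8)
        # topology preserved: still one component with three free ends
        assert label(pruned, connectivity=2).max() == 1
        _, ends = detect_nodes(pruned)
        assert len(ends) == 3
        assert pruned.sum() >= skel.sum() - 2
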
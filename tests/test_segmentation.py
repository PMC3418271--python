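"""The morphological segmentation stages and their oracle equivalences."""

import numpy as np
import pytest
from scipy import ndimage

from lungct import (
    CTVolume,
    Mode,
    SegmentationParams,
    body_roi,
    erode_roi,
    external_air_mask,
    largest_component_3d,
    segment_aerated_lung,
    threshold_air,
)


def _hu(values):
    return CTVolume(np.asarray(values, dtype=np.float64), calibrated=True)


class TestThresholdAir:
    def test_uniform_below(self):
        assert threshold_air(_hu(np.full((2, 3, 3), -1000.0)), -580).all()

    def test_uniform_above(self):
        assert not threshold_air(_hu(np.zeros((2, 3, 3))), -580).any()

    def test_boundary_included(self):
        mask = threshold_air(_hu(np.full((1, 1, 1), -580.0)), -580)
        assert mask.all()

    def test_random_volume_matches_voxel_scan(self, rng):
        vox = rng.uniform(-1000, 0, size=(5, 8, 8))
        mask = threshold_air(_hu(vox), -580)
        brute = np.zeros_like(mask)
        for idx in np.ndindex(vox.shape):  # independent voxel-by-voxel scan
            brute[idx] = vox[idx] <= -580
        assert np.array_equal(mask, brute)

    def test_monotone_in_threshold(self, rng):
        vox = rng.uniform(-1000, 0, size=(4, 6, 6))
        vol = _hu(vox)
        loose = threshold_air(vol, -400)
        tight = threshold_air(vol, -700)
        assert np.all(loose[tight])  # lowering the threshold never adds voxels

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            threshold_air(CTVolume(np.zeros((1, 2, 2))), -580)


def _frame_and_disk_slice(n=16):
    """Air frame touching the border plus an enclosed air disk."""
    sl = np.zeros((n, n), bool)
    sl[:2] = sl[-2:] = sl[:, :2] = sl[:, -2:] = True  # border-connected frame
    sl[7:10, 7:10] = True  # enclosed pore
    return sl


class TestExternalAirMask:
    def test_frame_kept_pore_removed(self):
        air = _frame_and_disk_slice()[None]
        ext = external_air_mask(air)
        assert ext[0, 0, 0] and ext[0, 1, 8]
        assert not ext[0, 8, 8]

    def test_all_air_slice_fully_kept(self):
        air = np.ones((1, 8, 8), bool)
        assert external_air_mask(air).all()

    def test_matches_flood_fill_oracle(self, rng):
        """Per-slice equality with a flood fill seeded from border air."""
        air = rng.random((6, 24, 24)) < 0.45
        ext = external_air_mask(air)
        structure = np.ones((3, 3), bool)  # 8-connectivity
        for z in range(air.shape[0]):
            seed = np.zeros_like(air[z])
            seed[0, :] = seed[-1, :] = seed[:, 0] = seed[:, -1] = True
            seed &= air[z]
            flooded = ndimage.binary_propagation(seed, mask=air[z], structure=structure)
            assert np.array_equal(ext[z], flooded)


class TestBodyRoi:
    def test_complement(self):
        air = _frame_and_disk_slice()[None]
        ext = external_air_mask(air)
        roi = body_roi(air.shape, ext)
        assert np.array_equal(roi, ~ext)
        assert roi[0, 8, 8]  # enclosed pore belongs to the body ROI

    def test_no_external_air_full_fov(self):
        roi = body_roi((2, 4, 4), np.zeros((2, 4, 4), bool))
        assert roi.all()

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError, match="no subject"):
            body_roi((1, 4, 4), np.ones((1, 4, 4), bool))


class TestErodeRoi:
    def test_square_arithmetic(self):
        roi = np.zeros((1, 50, 50), bool)
        roi[0, 10:40, 10:40] = True  # 30x30 square
        eroded = erode_roi(roi, radius_px=10)
        expected = np.zeros_like(roi)
        expected[0, 20:30, 20:30] = True  # 10x10 remains
        assert np.array_equal(eroded, expected)

    def test_vanishing_roi_errors(self):
        roi = np.zeros((1, 40, 40), bool)
        roi[0, 10:25, 10:25] = True  # 15x15 < (2*10+1)
        with pytest.raises(ValueError, match="vanished"):
            erode_roi(roi, radius_px=10)

    def test_matches_chebyshev_distance_oracle(self, rng):
        roi = ndimage.binary_dilation(
            rng.random((4, 40, 40)) < 0.05, np.ones((1, 9, 9), bool)
        )
        if not roi.any():
            pytest.skip("degenerate draw")
        r = 3
        eroded = erode_roi(roi, radius_px=r)
        for z in range(roi.shape[0]):
            padded = np.pad(roi[z], 1)  # outside the image is background
            dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
            assert np.array_equal(eroded[z], dist[1:-1, 1:-1] > r)

    def test_radius_zero_identity(self):
        roi = np.zeros((1, 5, 5), bool)
        roi[0, 2, 2] = True
        assert np.array_equal(erode_roi(roi, 0), roi)


class TestLargestComponent:
    def test_size_order(self):
        mask = np.zeros((1, 10, 30), bool)
        mask[0, 2:7, 2:22] = True  # 100 voxels
        mask[0, 8, 25:30] = True  # 5 voxels
        kept = largest_component_3d(mask)
        assert kept[0, 4, 10] and not kept[0, 8, 27]
        assert kept.sum() == 100

    def test_single_component_idempotent(self):
        mask = np.zeros((2, 5, 5), bool)
        mask[:, 1:4, 1:4] = True
        once = largest_component_3d(mask)
        assert np.array_equal(once, mask)
        assert np.array_equal(largest_component_3d(once), once)

    def test_equal_components_lexicographic_tie(self):
        mask = np.zeros((1, 10, 10), bool)
        mask[0, 0:2, 0:2] = True  # contains (0,0,0)
        mask[0, 6:8, 6:8] = True  # same size, later seed
        kept = largest_component_3d(mask)
        # exhaustive check: the kept component holds the smallest voxel
        seeds = sorted(map(tuple, np.argwhere(mask)))
        assert kept[seeds[0]]
        assert kept.sum() == 4
        assert not kept[0, 6, 6]

    def test_diagonal_voxels_are_26_connected(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert largest_component_3d(mask).sum() == 2

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty segmentation"):
            largest_component_3d(np.zeros((1, 2, 2), bool))


class TestFullPipeline:
    def test_recovers_ground_truth(self, thorax_phantom):
        volumes, truth = thorax_phantom
        res = segment_aerated_lung(volumes[0])
        gt = truth.lung_masks[0]
        dice = 2 * np.count_nonzero(res.lung_mask & gt) / (
            res.voxel_count + truth.lung_voxels[0]
        )
        assert dice >= 0.95
        assert abs(res.voxel_count - truth.lung_voxels[0]) <= 0.05 * truth.lung_voxels[0]

    def test_nesting_invariants(self, thorax_phantom, thorax_spec):
        volumes, _ = thorax_phantom
        vol = volumes[3]
        params = SegmentationParams()
        air = threshold_air(vol, params.air_threshold_hu)
        roi = body_roi(vol.shape, external_air_mask(air))
        eroded = erode_roi(roi, params.erosion_radius_px)
        res = segment_aerated_lung(vol, params)
        assert np.all(roi[eroded])  # eroded ⊆ body ROI
        assert np.all(eroded[res.lung_mask])  # lung ⊆ eroded ROI

    def test_single_component_output(self, thorax_phantom):
        volumes, _ = thorax_phantom
        res = segment_aerated_lung(volumes[1])
        _, n = ndimage.label(res.lung_mask, structure=np.ones((3, 3, 3), bool))
        assert n == 1

    def test_volume_units_conserved(self, thorax_phantom, thorax_spec):
        volumes, _ = thorax_phantom
        res = segment_aerated_lung(volumes[2])
        assert res.volume_mm3 == res.voxel_count * (thorax_spec.voxel_size_um / 1000.0) ** 3

    def test_in_vivo_mode_only_changes_threshold(self):
        p = SegmentationParams(mode=Mode.IN_VIVO)
        q = SegmentationParams(mode=Mode.EUTHANIZED)
        assert p.air_threshold_hu == -383.0 and q.air_threshold_hu == -580.0
        assert p.erosion_radius_px == q.erosion_radius_px == 10

    def test_solid_phantom_raises_empty(self, thorax_phantom):
        volumes, truth = thorax_phantom
        solid = CTVolume(
            volumes[0].voxels.copy(),
            voxel_size_um=volumes[0].voxel_size_um,
            calibrated=True,
        )
        solid.voxels[truth.lung_masks[0]] = 40.0
        solid.voxels[truth.speckle_mask] = 40.0
        with pytest.raises(ValueError, match="empty segmentation"):
            segment_aerated_lung(solid)

    def test_speckle_pockets_do_not_change_lung_mask(self, thorax_spec):
        from dataclasses import replace
        from lungct import make_thorax_phantom

        with_s, _ = make_thorax_phantom(replace(thorax_spec, speckles=True), phases=[3])
        without_s, _ = make_thorax_phantom(replace(thorax_spec, speckles=False), phases=[3])
        m1 = segment_aerated_lung(with_s[3]).lung_mask
        m0 = segment_aerated_lung(without_s[3]).lung_mask
        assert np.array_equal(m1, m0)
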
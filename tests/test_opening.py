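"""Enhancement normalization, opening volumetry, Gd delivery, tissue breakdown."""

import numpy as np
import pytest

from cavimap.errors import ConfigurationError, DegenerateInputError
from cavimap.grids import VolumeGrid
from cavimap.opening import (
    VoiSpec,
    delivered_gd,
    enhancement_map,
    opening_volume,
    per_tissue_breakdown,
)
from cavimap.relaxometry import GdMap, segment_tissue


def centered_grid(shape=(40, 24, 24), value=0.0):
    """1 mm grid with the world origin at the grid centre (mirror plane x=0)."""
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
    return VolumeGrid(np.full(shape, float(value)), affine)


def box_mask(grid, center, half):
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    w = np.stack([ii, jj, kk], axis=-1) @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    m = np.ones(grid.shape, dtype=bool)
    for a in range(3):
        m &= np.abs(w[..., a] - center[a]) <= half[a]
    return m


class TestEnhancementMap:
    def test_linear_normalization_arithmetic(self):
        pre = centered_grid(value=1.0)
        post = pre.with_voxels(np.full(pre.shape, 1.25))
        thal = box_mask(pre, (-10, 0, 0), (2, 2, 2))
        aca = box_mask(pre, (10, 0, 0), (2, 2, 2))
        post.voxels[thal] = 1.0  # thalamus ratio 1.0
        post.voxels[aca] = 1.5  # ACA ratio 1.5
        enh = enhancement_map(post, pre, thal, aca)
        probe = ~thal & ~aca
        assert np.allclose(enh.voxels[probe], 0.5)
        assert np.nanmean(enh.voxels[thal]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanmean(enh.voxels[aca]) == pytest.approx(1.0, abs=1e-12)

    def test_below_thalamus_maps_negative(self):
        pre = centered_grid(value=1.0)
        post = pre.with_voxels(np.full(pre.shape, 0.9))
        thal = box_mask(pre, (-10, 0, 0), (2, 2, 2))
        aca = box_mask(pre, (10, 0, 0), (2, 2, 2))
        post.voxels[thal] = 1.0
        post.voxels[aca] = 1.5
        enh = enhancement_map(post, pre, thal, aca)
        assert np.all(enh.voxels[~thal & ~aca] < 0)

    def test_equal_references_degenerate(self):
        pre = centered_grid(value=1.0)
        post = pre.with_voxels(np.ones(pre.shape))
        thal = box_mask(pre, (-10, 0, 0), (2, 2, 2))
        aca = box_mask(pre, (10, 0, 0), (2, 2, 2))
        with pytest.raises(DegenerateInputError):
            enhancement_map(post, pre, thal, aca)

    def test_empty_or_overlapping_references_rejected(self):
        pre = centered_grid(value=1.0)
        post = pre.with_voxels(np.ones(pre.shape))
        empty = np.zeros(pre.shape, dtype=bool)
        some = box_mask(pre, (0, 0, 0), (2, 2, 2))
        with pytest.raises(ConfigurationError):
            enhancement_map(post, pre, empty, some)
        with pytest.raises(ConfigurationError):
            enhancement_map(post, pre, some, some)

    def test_zero_pre_voxels_flagged_invalid(self):
        pre = centered_grid(value=1.0)
        pre.voxels[0, 0, 0] = 0.0
        post = pre.with_voxels(np.full(pre.shape, 1.2))
        thal = box_mask(pre, (-10, 0, 0), (2, 2, 2))
        aca = box_mask(pre, (10, 0, 0), (2, 2, 2))
        post.voxels[aca] = 1.5
        post.voxels[thal] = 1.0
        enh = enhancement_map(post, pre, thal, aca)
        assert np.isnan(enh.voxels[0, 0, 0])


def opening_setup(blob_half=(5, 4, 5), contra_blob=False, value=1.0):
    enh = centered_grid()
    brain = np.ones(enh.shape, dtype=bool)
    blob = box_mask(enh, (10, 0, 0), blob_half)
    enh.voxels[blob] = value
    if contra_blob:
        enh.voxels[box_mask(enh, (-10, 0, 0), blob_half)] = value
    voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16), mirror_plane_x=0.0)
    return enh, brain, blob, voi


class TestOpeningVolume:
    def test_zero_enhancement_not_significant(self):
        enh = centered_grid()
        voi = VoiSpec(center=(10, 0, 0), extents=(10, 10, 10))
        res = opening_volume(enh, np.ones(enh.shape, bool), None, voi, voxel_cutoff=0.1)
        assert res.opening_volume_mm3 == 0.0
        assert not res.significant

    def test_blob_counted_exactly(self):
        enh, brain, blob, voi = opening_setup()
        res = opening_volume(enh, brain, None, voi, voxel_cutoff=0.5)
        assert res.opening_volume_mm3 == pytest.approx(blob.sum() * 1.0)
        assert res.significant  # 11*9*11 = 1089 mm^3 > 80

    def test_symmetric_blobs_cancel(self):
        enh, brain, _, voi = opening_setup(contra_blob=True)
        res = opening_volume(enh, brain, None, voi, voxel_cutoff=0.5)
        assert res.opening_volume_mm3 == 0.0

    def test_sham_subtraction_removes_shared_pattern(self):
        enh, brain, blob, voi = opening_setup()
        sham = enh.with_voxels(enh.voxels.copy())  # sham shows the same pattern
        res = opening_volume(enh, brain, sham, voi, voxel_cutoff=0.1)
        assert res.opening_volume_mm3 == 0.0

    def test_monotone_in_true_blob_size(self):
        vols = []
        for half in [(2, 2, 2), (3, 3, 3), (5, 4, 5)]:
            enh, brain, _, voi = opening_setup(blob_half=half)
            vols.append(
                opening_volume(enh, brain, None, voi, voxel_cutoff=0.5).opening_volume_mm3
            )
        assert vols[0] < vols[1] < vols[2]

    def test_min_cluster_removes_isolated_noise_voxels(self):
        enh, brain, blob, voi = opening_setup()
        enh.voxels[2, 2, 2] = 5.0  # lone speck far from the blob, inside contra side? no: keep ipsi
        enh.voxels[30, 20, 20] = 5.0
        res = opening_volume(enh, brain, None, voi, voxel_cutoff=0.5, min_cluster_voxels=10)
        assert res.opening_volume_mm3 == pytest.approx(blob.sum() * 1.0)

    def test_voi_outside_grid_warns_and_clips(self):
        enh = centered_grid()
        voi = VoiSpec(center=(18, 0, 0), extents=(20, 10, 10))
        with pytest.warns(UserWarning, match="clip"):
            opening_volume(enh, np.ones(enh.shape, bool), None, voi)

    def test_significance_threshold_boundary(self):
        # half-integer voxel centres: a +/-2 mm box holds 4^3 = 64 voxels
        enh, brain, _, voi = opening_setup(blob_half=(2, 2, 2))
        res = opening_volume(enh, brain, None, voi, voxel_cutoff=0.5)
        assert res.opening_volume_mm3 == 64.0
        assert not res.significant  # below the 80 mm^3 sham-derived threshold
        res50 = opening_volume(
            enh, brain, None, voi, voxel_cutoff=0.5, significance_threshold_mm3=50.0
        )
        assert res50.significant
        res64 = opening_volume(
            enh, brain, None, voi, voxel_cutoff=0.5, significance_threshold_mm3=64.0
        )
        assert not res64.significant  # strict inequality at the threshold


def gd_map_with_blob(conc_mM=0.05, blob_half=(4, 3, 5), contra=0.0, background=0.0,
                     blob_center=(10, 0, 0)):
    grid = centered_grid(value=background)
    blob = box_mask(grid, blob_center, blob_half)
    grid.voxels[blob] = conc_mM
    if contra:
        grid.voxels[box_mask(grid, (-10, 0, 0), blob_half)] = contra
    conc = grid.with_voxels(grid.voxels, units="mM")
    valid = grid.with_voxels(np.ones(grid.shape, bool), units="bool")
    return GdMap(concentration=conc, r1=4.0, valid=valid), blob


class TestDeliveredGd:
    def test_printed_delivery_identity(self):
        """0.05 mM over ~300 mm^3 -> 15 nmol and 0.0015% of a 1 mmol injection."""
        # 10 x 6 x 5 = 300 voxels; the half-voxel z-shift gives the odd count
        gd, blob = gd_map_with_blob(
            conc_mM=0.05, blob_half=(4.5, 2.5, 2), blob_center=(10, 0, 0.5)
        )
        assert blob.sum() == 300
        voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16))
        res = delivered_gd(gd, np.ones(gd.concentration.shape, bool), 0.2, voi)
        assert res.delivered_nmol == pytest.approx(15.0, rel=1e-9)
        assert res.efficiency_pct == pytest.approx(0.0015, rel=1e-9)

    def test_linearity_in_concentration(self):
        voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16))
        brain = None
        res = []
        for c in (0.02, 0.04):
            gd, _ = gd_map_with_blob(conc_mM=c)
            brain = np.ones(gd.concentration.shape, bool)
            res.append(delivered_gd(gd, brain, 0.2, voi).delivered_nmol)
        assert res[1] == pytest.approx(2 * res[0], rel=1e-12)

    def test_vessel_filter_zeroes_above_aca(self):
        gd, _ = gd_map_with_blob(conc_mM=0.5)
        voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16))
        res = delivered_gd(gd, np.ones(gd.concentration.shape, bool), 0.2, voi)
        assert res.delivered_nmol == 0.0

    def test_mirror_symmetric_map_delivers_zero(self):
        gd, _ = gd_map_with_blob(conc_mM=0.05, contra=0.05)
        voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16))
        res = delivered_gd(gd, np.ones(gd.concentration.shape, bool), 0.2, voi)
        assert res.delivered_nmol == 0.0

    def test_background_retention_cancels_contralaterally(self):
        gd, blob = gd_map_with_blob(conc_mM=0.07, background=0.02)
        voi = VoiSpec(center=(10, 0, 0), extents=(16, 16, 16))
        res = delivered_gd(gd, np.ones(gd.concentration.shape, bool), 0.2, voi)
        expected = (0.07 - 0.02) * 1e-3 * blob.sum() * 1e-6 * 1e9
        assert res.delivered_nmol == pytest.approx(expected, rel=1e-9)


class TestPerTissueBreakdown:
    @staticmethod
    def seg_half_gray_half_white(shape=(20, 10, 10)):
        t1 = np.full(shape, 1500.0)  # gray
        t1[shape[0] // 2:] = 900.0  # white
        return segment_tissue(VolumeGrid(t1, units="ms"))

    def test_opening_entirely_in_gray(self):
        seg = self.seg_half_gray_half_white()
        opened = np.zeros(seg.labels.shape, dtype=bool)
        opened[2:5, 2:5, 2:5] = True  # gray half
        bd = per_tissue_breakdown(
            seg.labels.with_voxels(opened), seg, np.ones(opened.shape, bool)
        )
        assert bd.table.loc["gray", "fraction_of_opening_pct"] == pytest.approx(100.0)
        assert bd.table.loc["white", "fraction_of_opening_pct"] == 0.0

    def test_binomial_probability_ratio_recovers_three(self):
        """Opening probability 0.6 in gray vs 0.2 in white -> ratio ~3."""
        seg = self.seg_half_gray_half_white(shape=(40, 25, 25))
        rng = np.random.default_rng(7)
        gray = seg.mask("gray")
        white = seg.mask("white")
        opened = np.zeros(seg.labels.shape, dtype=bool)
        opened[gray] = rng.random(int(gray.sum())) < 0.6
        opened[white] = rng.random(int(white.sum())) < 0.2
        bd = per_tissue_breakdown(
            seg.labels.with_voxels(opened), seg, np.ones(opened.shape, bool)
        )
        assert bd.gray_white_probability_ratio == pytest.approx(3.0, rel=0.1)
        assert bd.ratio_defined

    def test_no_opened_voxels_flags_ratio_undefined(self):
        seg = self.seg_half_gray_half_white()
        opened = np.zeros(seg.labels.shape, dtype=bool)
        bd = per_tissue_breakdown(
            seg.labels.with_voxels(opened), seg, np.ones(opened.shape, bool)
        )
        assert not bd.ratio_defined
        assert np.isnan(bd.gray_white_probability_ratio)

    def test_empty_sonicated_region_rejected(self):
        seg = self.seg_half_gray_half_white()
        opened = np.zeros(seg.labels.shape, dtype=bool)
        with pytest.raises(ConfigurationError):
            per_tissue_breakdown(
                seg.labels.with_voxels(opened), seg, np.zeros(opened.shape, bool)
            )
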
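import numpy as np
import pytest
import tifffile

import braincode as bc
from conftest import matrix_from_sets


class TestVolumeIO:
    def test_nrrd_round_trip_preserves_grid_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 255, size=(7, 5, 3)).astype(np.float32)
        vol = bc.IntensityVolume(grid, (0.62, 0.62, 0.62))
        path = tmp_path / "v.nrrd"
        bc.write_volume(vol, path)
        back = bc.read_volume(path)
        np.testing.assert_array_equal(back.grid, grid)
        assert back.voxel_size == pytest.approx((0.62, 0.62, 0.62))

    def test_zero_nrrd_reads_as_zero_volume(self, tmp_path):
        path = tmp_path / "z.nrrd"
        bc.write_volume(bc.IntensityVolume(np.zeros((4, 4, 4))), path)
        vol = bc.read_volume(path)
        assert vol.shape == (4, 4, 4)
        assert np.count_nonzero(vol.grid) == 0

    def test_tiff_pages_become_z_axis(self, tmp_path):
        arr = np.arange(10 * 32 * 32, dtype=np.uint16).reshape(10, 32, 32)
        path = tmp_path / "s.tif"
        tifffile.imwrite(path, arr)
        vol = bc.read_volume(path)
        assert vol.shape == (32, 32, 10)
        assert vol.voxel_size == (1.0, 1.0, 1.0)
        # page p, row y, col x maps to grid[x, y, p]
        assert vol.grid[3, 2, 1] == arr[1, 2, 3]

    def test_multichannel_tiff_rejected_naming_channels(self, tmp_path):
        path = tmp_path / "c.tif"
        tifffile.imwrite(path, np.zeros((4, 8, 8, 3), dtype=np.uint8))
        with pytest.raises(bc.FormatError, match="3 channels"):
            bc.read_volume(path)

    def test_unreadable_file_raises_oserror(self, tmp_path):
        path = tmp_path / "bad.nrrd"
        path.write_text("not an image")
        with pytest.raises(OSError):
            bc.read_volume(path)

    def test_label_round_trip_is_bit_exact(self, tmp_path):
        labels = np.random.default_rng(1).integers(0, 9, size=(6, 5, 4))
        path = tmp_path / "lab.nrrd"
        bc.write_labels(labels, path)
        np.testing.assert_array_equal(bc.read_labels(path), labels)


class TestDownsample:
    def test_factor_one_is_identity(self):
        vol = bc.IntensityVolume(np.arange(8.0).reshape(2, 2, 2))
        out = bc.downsample(vol, 1)
        np.testing.assert_array_equal(out.grid, vol.grid)

    def test_block_mean(self):
        grid = np.array([0, 0, 0, 0, 8, 8, 8, 8], dtype=float).reshape(2, 2, 2)
        out = bc.downsample(bc.IntensityVolume(grid), 2)
        assert out.shape == (1, 1, 1)
        assert out.grid[0, 0, 0] == pytest.approx(4.0)

    def test_constant_invariance_with_partial_blocks(self):
        out = bc.downsample(bc.IntensityVolume(np.full((3, 3, 3), 5.0)), 2)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out.grid, 5.0)

    def test_voxel_size_scales(self):
        vol = bc.IntensityVolume(np.zeros((4, 4, 4)), (0.5, 0.5, 1.0))
        assert bc.downsample(vol, 2).voxel_size == (1.0, 1.0, 2.0)

    def test_invalid_factor(self):
        vol = bc.IntensityVolume(np.zeros((2, 2, 2)))
        with pytest.raises(bc.ParameterError):
            bc.downsample(vol, 0)

    def test_mask_majority_rule(self):
        grid = np.zeros((4, 2, 2), dtype=bool)
        grid[:2] = True            # first block fully inside
        grid[2, 0, 0] = True       # second block 1/8 inside
        ds = bc.downsample_mask(bc.RegionMask(grid), 2)
        assert ds.grid[0, 0, 0] and not ds.grid[1, 0, 0]

    def test_label_majority_vote_ties_to_smaller(self):
        grid = np.zeros((2, 2, 2), dtype=np.int32)
        grid[0] = 1
        grid[1] = 2                # 4 voxels each: tie -> label 1
        assert bc.downsample_labels(grid, 2)[0, 0, 0] == 1


class TestBuildMatrix:
    def _mask3(self):
        g = np.zeros((3, 1, 1), dtype=bool)
        g[:] = True
        return bc.RegionMask(g)

    def _vol(self, vals):
        return bc.IntensityVolume(np.array(vals, dtype=float).reshape(3, 1, 1))

    def test_saturated_and_empty_rows(self):
        mask = self._mask3()
        vols = [self._vol([100, 100, 100])]
        m = bc.build_matrix(vols, ["a"], mask, threshold=50)
        assert m.occupancy.all()
        m = bc.build_matrix(vols, ["a"], mask, threshold=101)
        assert not m.occupancy.any()

    def test_elementwise_threshold(self):
        mask = self._mask3()
        vols = [self._vol([10, 80, 80]), self._vol([80, 10, 10])]
        m = bc.build_matrix(vols, ["a", "b"], mask, threshold=50)
        np.testing.assert_array_equal(
            m.occupancy, [[False, True, True], [True, False, False]]
        )
        np.testing.assert_allclose(m.mean_intensity[0], [10, 80, 80])

    def test_occupancy_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        mask = bc.RegionMask(np.ones((4, 4, 4), dtype=bool))
        vols = [bc.IntensityVolume(rng.random((4, 4, 4)) * 100) for _ in range(5)]
        ids = [f"l{i}" for i in range(5)]
        lo = bc.build_matrix(vols, ids, mask, threshold=20)
        hi = bc.build_matrix(vols, ids, mask, threshold=60)
        assert not (hi.occupancy & ~lo.occupancy).any()

    def test_shape_mismatch_names_line(self):
        mask = self._mask3()
        vols = [self._vol([1, 1, 1]), bc.IntensityVolume(np.zeros((2, 1, 1)))]
        with pytest.raises(bc.RegistrationError, match="bad_line"):
            bc.build_matrix(vols, ["ok", "bad_line"], mask, threshold=1)


class TestFilterVoxels:
    def test_no_empty_voxels_is_identity(self):
        m = matrix_from_sets([{"a"}, {"a", "b"}])
        out = bc.filter_voxels(m, 1)
        np.testing.assert_array_equal(out.occupancy, m.occupancy)
        np.testing.assert_array_equal(out.voxels.coords, m.voxels.coords)

    def test_count_filter_and_empty_region(self):
        occ = np.zeros((5, 3), dtype=bool)
        occ[:2, 1] = True
        occ[:, 2] = True  # counts per voxel: 0, 2, 5
        m = bc.ExpressionMatrix(
            [f"l{i}" for i in range(5)], occ,
            bc.VoxelTable(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])),
        )
        out = bc.filter_voxels(m, 1)
        assert out.n_voxels == 2
        with pytest.raises(bc.EmptyRegionError):
            bc.filter_voxels(m, 6)

    def test_idempotent(self):
        m = matrix_from_sets([{"a"}, {"b"}, {"a", "b"}])
        once = bc.filter_voxels(m, 1)
        twice = bc.filter_voxels(once, 1)
        np.testing.assert_array_equal(once.occupancy, twice.occupancy)
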
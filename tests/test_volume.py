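"""volume module: grids, I/O, resampling, pitch rotation, left-right flip."""

import numpy as np
import nibabel as nib
import pytest
from hypothesis import given, settings, strategies as st

from zsmap.volume import (ImageVolume, RigidRotation, VolumeFormatError, VolumeGrid,
                          flip_left_right, read_volume, resample_to, rotate_pitch,
                          write_volume)

from conftest import make_grid, uniform_volume


class TestGridAndVolume:
    def test_grid_equality_is_field_wise(self):
        a = VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0))
        assert a == VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0))
        assert a != VolumeGrid((4, 4, 4), (2.0, 2.0, 3.0))
        assert a != VolumeGrid((4, 4, 5), (2.0, 2.0, 2.0))
        assert a != VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0), origin=(1.0, 0.0, 0.0))

    def test_grid_validation(self):
        with pytest.raises(VolumeFormatError):
            VolumeGrid((0, 4, 4), (2.0, 2.0, 2.0))
        with pytest.raises(VolumeFormatError):
            VolumeGrid((4, 4, 4), (2.0, -1.0, 2.0))

    def test_volume_rejects_inf_and_negative_counts(self):
        grid = make_grid((4, 4, 4))
        bad = np.ones(grid.shape)
        bad[0, 0, 0] = np.inf
        with pytest.raises(VolumeFormatError):
            ImageVolume(grid, bad, "SPECT")
        with pytest.raises(VolumeFormatError):
            ImageVolume(grid, -np.ones(grid.shape), "SPECT")
        with pytest.raises(VolumeFormatError):
            ImageVolume(grid, 2.0 * np.ones(grid.shape), "probability")
        with pytest.raises(VolumeFormatError):
            ImageVolume(grid, np.full(grid.shape, np.nan), "T1")
        # NaN is allowed for Z maps (undefined outside the analysis domain)
        ImageVolume(grid, np.full(grid.shape, np.nan), "zmap")

    def test_rigid_rotation_validation(self):
        with pytest.raises(ValueError):
            RigidRotation(95.0)
        with pytest.raises(ValueError):
            RigidRotation(10.0, sign=2)
        assert RigidRotation(10.0).inverse().angle_deg == -10.0


class TestIO:
    def test_roundtrip_identity(self, tmp_path):
        vol = uniform_volume(1.0, shape=(4, 4, 4), voxel=1.5)
        path = write_volume(vol, tmp_path / "ones.nii.gz")
        back = read_volume(path)
        assert back.grid == vol.grid
        assert np.array_equal(back.values, vol.values)

    def test_voxel_size_passthrough(self, tmp_path):
        vol = uniform_volume(3.0, shape=(5, 6, 7), voxel=2.0)
        back = read_volume(write_volume(vol, tmp_path / "v.nii.gz"))
        assert back.grid.voxel_size == (2.0, 2.0, 2.0)

    def test_float32_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = make_grid((6, 6, 6))
        vals = rng.uniform(0, 100, grid.shape).astype(np.float32)
        vol = ImageVolume(grid, vals, "SPECT")
        back = read_volume(write_volume(vol, tmp_path / "r.nii.gz"))
        assert np.array_equal(np.asarray(back.values, dtype=np.float32), vals)

    def test_non_3d_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.ones((8, 8), dtype=np.float32), np.eye(4))
        path = tmp_path / "flat.nii.gz"
        nib.save(img, str(path))
        with pytest.raises(VolumeFormatError):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "missing.nii.gz")


class TestResample:
    def test_identity_grid(self):
        rng = np.random.default_rng(1)
        grid = make_grid((6, 6, 6))
        vol = ImageVolume(grid, rng.uniform(0, 1, grid.shape), "SPECT")
        out = resample_to(vol, grid)
        assert np.array_equal(out.values, vol.values)

    def test_uniform_preserved(self):
        vol = uniform_volume(7.0, shape=(8, 8, 8), voxel=2.0)
        # interior-covering coarser target (avoid extrapolation at the border)
        target = VolumeGrid((3, 3, 3), (4.0, 4.0, 4.0), origin=(1.0, 1.0, 1.0))
        out = resample_to(vol, target)
        assert np.allclose(out.values, 7.0)

    def test_downsampled_ramp_matches_linear_interpolation(self):
        grid = VolumeGrid((9, 4, 4), (1.0, 1.0, 1.0))
        ramp = np.broadcast_to(np.arange(9, dtype=float)[:, None, None], grid.shape)
        vol = ImageVolume(grid, np.ascontiguousarray(ramp), "SPECT")
        target = VolumeGrid((4, 4, 4), (2.0, 1.0, 1.0), origin=(0.5, 0.0, 0.0))
        out = resample_to(vol, target)
        # ramp value equals the world x coordinate: 0.5, 2.5, 4.5, 6.5
        expected = 0.5 + 2.0 * np.arange(4)
        assert np.allclose(np.asarray(out.values)[:, 1, 1], expected)

    def test_unknown_interpolation(self):
        vol = uniform_volume(1.0)
        with pytest.raises(ValueError):
            resample_to(vol, vol.grid, interpolation="cubic")


def _centered_ball(shape=(32, 32, 32), voxel=2.0, offset=(0, 10, 0), radius=6.0):
    grid = make_grid(shape, voxel)
    x, y, zc = np.meshgrid(*grid.world_coords(), indexing="ij")
    c = grid.center_mm
    r = np.sqrt((x - c[0] - offset[0]) ** 2 + (y - c[1] - offset[1]) ** 2
                + (zc - c[2] - offset[2]) ** 2)
    return ImageVolume(grid, np.clip(radius - r, 0, None), "SPECT")


class TestRotatePitch:
    def test_zero_angle_identity(self):
        vol = _centered_ball()
        out = rotate_pitch(vol, RigidRotation(0.0))
        assert np.array_equal(out.values, vol.values)

    def test_plus_minus_roundtrip(self):
        vol = _centered_ball()
        out = rotate_pitch(rotate_pitch(vol, RigidRotation(10.0)), RigidRotation(-10.0))
        span = float(np.ptp(np.asarray(vol.values)))
        diff = np.abs(np.asarray(out.values) - np.asarray(vol.values)).mean()
        assert diff < 0.01 * span

    @pytest.mark.parametrize("angle", [10.0, 34.0])
    def test_centroid_matches_closed_form(self, angle):
        vol = _centered_ball(offset=(0, 14.0, 6.0), radius=4.0)
        out = rotate_pitch(vol, RigidRotation(angle))
        vals = np.asarray(out.values)
        x, y, zc = np.meshgrid(*vol.grid.world_coords(), indexing="ij")
        w = vals / vals.sum()
        centroid = np.array([(x * w).sum(), (y * w).sum(), (zc * w).sum()])
        expected_yz = RigidRotation(angle).matrix_yz @ np.array([14.0, 6.0])
        expected = vol.grid.center_mm + np.array([0.0, expected_yz[0], expected_yz[1]])
        assert np.all(np.abs(centroid - expected) < 2.0)  # within one 2-mm voxel

    def test_signal_conserved_for_padded_volume(self):
        vol = _centered_ball(shape=(40, 40, 40), offset=(0, 6, 0))
        out = rotate_pitch(vol, RigidRotation(34.0))
        total_in = float(np.asarray(vol.values).sum())
        total_out = float(np.asarray(out.values).sum())
        assert abs(total_out - total_in) < 0.01 * total_in


class TestFlip:
    def test_double_flip_identity_and_involution(self):
        rng = np.random.default_rng(2)
        grid = make_grid((7, 5, 5))
        vol = ImageVolume(grid, rng.uniform(0, 1, grid.shape), "SPECT")
        assert np.array_equal(flip_left_right(flip_left_right(vol)).values, vol.values)

    def test_symmetric_volume_unchanged(self):
        grid = make_grid((6, 4, 4))
        vals = np.zeros(grid.shape)
        vals[1] = vals[4] = 1.0  # mirror-symmetric planes
        vol = ImageVolume(grid, vals, "SPECT")
        assert np.array_equal(flip_left_right(vol).values, vals)

    def test_delta_index_mirror(self):
        grid = make_grid((10, 4, 4))
        vals = np.zeros(grid.shape)
        vals[1, 2, 2] = 1.0
        out = np.asarray(flip_left_right(ImageVolume(grid, vals, "SPECT")).values)
        assert out[8, 2, 2] == 1.0 and out.sum() == 1.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_flip_involution_property(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(s) for s in rng.integers(2, 9, 3))
        grid = VolumeGrid(shape, (1.0, 1.0, 1.0))
        vol = ImageVolume(grid, rng.uniform(0, 10, shape), "SPECT")
        assert np.array_equal(flip_left_right(flip_left_right(vol)).values, vol.values)
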
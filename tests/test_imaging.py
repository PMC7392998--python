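import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualkin.imaging import (
    DynamicImage,
    EmptyIntersectionError,
    FrameSchedule,
    GridMismatchError,
    TimeCurve,
    VoxelMask,
    extract_voi_curve,
    frame_midpoints,
    fwhm_to_sigma,
    gaussian_smooth,
    intersect_masks,
    read_dynamic,
    write_dynamic,
)
from dualkin.phantom import dce_frame_schedule, pet_frame_schedule


class TestFrameSchedule:
    def test_first_pet_frame_midpoint(self, pet_schedule):
        assert frame_midpoints(pet_schedule)[0] == pytest.approx(5.0)

    def test_pet_schedule_histogramming(self, pet_schedule):
        # 12x10 + 12x20 + 4x60 + 5x120 + 8x300 s = 41 frames over one hour
        assert pet_schedule.n_frames == 41
        assert pet_schedule.total_duration == pytest.approx(3600.0)
        assert frame_midpoints(pet_schedule)[-1] == pytest.approx(3450.0)
        assert pet_schedule.is_contiguous

    def test_dce_schedule_last_midpoint(self, dce_schedule):
        assert dce_schedule.n_frames == 120
        assert frame_midpoints(dce_schedule)[-1] == pytest.approx(119 * 3.03 + 3.03 / 2)

    @given(
        durations=st.lists(
            st.floats(0.5, 400.0, allow_nan=False), min_size=1, max_size=60
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_midpoints_strictly_increasing(self, durations):
        sched = FrameSchedule.from_durations(durations)
        assert np.all(np.diff(sched.midpoints) > 0)

    @pytest.mark.parametrize(
        "starts,durations",
        [([], []), ([0.0], [0.0]), ([0.0, 5.0], [10.0, 10.0, 10.0]), ([5.0, 0.0], [1.0, 1.0])],
    )
    def test_invalid_schedules_rejected(self, starts, durations):
        with pytest.raises(ValueError):
            FrameSchedule(np.asarray(starts), np.asarray(durations))

    def test_csv_round_trip(self, tmp_path, pet_schedule):
        path = tmp_path / "sched.csv"
        pet_schedule.to_csv(path)
        back = FrameSchedule.from_csv(path)
        np.testing.assert_array_equal(back.starts, pet_schedule.starts)
        np.testing.assert_array_equal(back.durations, pet_schedule.durations)


class TestNiftiIO:
    def test_write_read_round_trip_bit_exact(self, tmp_path):
        sched = FrameSchedule.from_durations([10.0] * 5)
        rng = np.random.default_rng(0)
        img = DynamicImage(
            data=rng.random((6, 5, 4, 5)), voxel_size=[2.0, 2.0, 2.0],
            schedule=sched, units="kBq/mL",
        )
        path = tmp_path / "img.nii.gz"
        write_dynamic(img, path)
        back = read_dynamic(path, sched, units="kBq/mL")
        np.testing.assert_array_equal(back.data, img.data)
        np.testing.assert_allclose(back.voxel_size, img.voxel_size)

    def test_schedule_length_mismatch_rejected(self, tmp_path):
        sched5 = FrameSchedule.from_durations([10.0] * 5)
        sched7 = FrameSchedule.from_durations([10.0] * 7)
        img = DynamicImage(
            data=np.zeros((4, 4, 4, 5)), voxel_size=[2.0] * 3,
            schedule=sched5, units="kBq/mL",
        )
        path = tmp_path / "img.nii.gz"
        write_dynamic(img, path)
        with pytest.raises(ValueError, match="frames"):
            read_dynamic(path, sched7, units="kBq/mL")


def _dyn(data, vs=2.0):
    sched = FrameSchedule.from_durations([10.0] * data.shape[3])
    return DynamicImage(data=data, voxel_size=[vs] * 3, schedule=sched, units="kBq/mL")


class TestGaussianSmooth:
    def test_fwhm_to_sigma(self):
        # 8 mm FWHM on a 2 mm grid: sigma = 8 / (2 sqrt(2 ln 2)) mm
        assert fwhm_to_sigma(8.0) == pytest.approx(3.39728, abs=1e-4)
        assert fwhm_to_sigma(8.0) / 2.0 == pytest.approx(1.69864, abs=1e-4)

    def test_constant_frame_unchanged(self):
        img = _dyn(np.full((12, 12, 8, 2), 7.5))
        out = gaussian_smooth(img, 8.0)
        np.testing.assert_allclose(out.data, img.data, rtol=1e-10)

    def test_impulse_mass_conserved(self):
        data = np.zeros((24, 24, 24, 1))
        data[12, 12, 12, 0] = 5.0
        out = gaussian_smooth(_dyn(data), 6.0)
        assert out.data.sum() == pytest.approx(5.0, rel=1e-6)
        assert out.data[12, 12, 12, 0] < 5.0

    def test_commutes_with_scalar_multiplication(self):
        rng = np.random.default_rng(1)
        data = rng.random((10, 10, 6, 3))
        a = gaussian_smooth(_dyn(3.0 * data), 8.0).data
        b = 3.0 * gaussian_smooth(_dyn(data), 8.0).data
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_interior_support_sum_preserved(self):
        data = np.zeros((30, 30, 30, 1))
        data[12:18, 12:18, 12:18, 0] = np.random.default_rng(2).random((6, 6, 6))
        out = gaussian_smooth(_dyn(data), 4.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_non_positive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(_dyn(np.zeros((4, 4, 4, 1))), 0.0)


def _mask(bits, vs=2.0):
    return VoxelMask(data=np.asarray(bits, bool), voxel_size=[vs] * 3)


class TestIntersectMasks:
    def test_idempotent(self):
        m = _mask(np.random.default_rng(0).random((6, 6, 6)) > 0.5)
        out = intersect_masks([m, m])
        np.testing.assert_array_equal(out.data, m.data)

    def test_disjoint_masks_raise(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        with pytest.raises(EmptyIntersectionError):
            intersect_masks([_mask(a), _mask(b)])

    def test_matches_brute_force_voxel_loop(self):
        rng = np.random.default_rng(3)
        masks = [_mask(rng.random((5, 5, 5)) > 0.3) for _ in range(4)]
        out = intersect_masks(masks)
        for idx in np.ndindex(5, 5, 5):
            expected = all(m.data[idx] for m in masks)
            assert out.data[idx] == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_commutative_associative(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (_mask(rng.random((5, 5, 5)) > 0.3) for _ in range(3))
        try:
            abc = intersect_masks([a, b, c]).data
        except EmptyIntersectionError:
            pytest.skip("random masks disjoint")
        np.testing.assert_array_equal(abc, intersect_masks([c, a, b]).data)
        np.testing.assert_array_equal(
            abc, intersect_masks([intersect_masks([a, b]), c]).data
        )

    def test_grid_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4), bool))
        b = _mask(np.ones((5, 4, 4), bool))
        with pytest.raises(GridMismatchError):
            intersect_masks([a, b])


class TestExtractVoiCurve:
    def test_uniform_image(self):
        img = _dyn(np.tile(np.array([1.0, 2.0, 3.0]), (5, 5, 5, 1)))
        mask = _mask(np.ones((5, 5, 5), bool))
        curve = extract_voi_curve(img, mask)
        np.testing.assert_allclose(curve.values, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.times, img.schedule.midpoints)

    def test_single_voxel_mask(self):
        rng = np.random.default_rng(4)
        img = _dyn(rng.random((5, 5, 5, 4)))
        bits = np.zeros((5, 5, 5), bool)
        bits[2, 3, 1] = True
        curve = extract_voi_curve(img, _mask(bits))
        np.testing.assert_array_equal(curve.values, img.data[2, 3, 1, :])

    def test_matches_hand_computed_means(self):
        rng = np.random.default_rng(5)
        img = _dyn(rng.random((6, 6, 6, 3)))
        bits = np.zeros((6, 6, 6), bool)
        chosen = [tuple(rng.integers(0, 6, 3)) for _ in range(10)]
        for c in chosen:
            bits[c] = True
        curve = extract_voi_curve(img, _mask(bits))
        voxels = np.unique(np.argwhere(bits), axis=0)
        for t in range(3):
            manual = np.mean([img.data[ix, iy, iz, t] for ix, iy, iz in voxels])
            assert curve.values[t] == pytest.approx(manual)

    def test_empty_mask_rejected(self):
        img = _dyn(np.zeros((4, 4, 4, 2)))
        with pytest.raises(ValueError):
            extract_voi_curve(img, _mask(np.zeros((4, 4, 4), bool)))


class TestTimeCurve:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            TimeCurve(times=[0.0, 1.0, 1.0], values=[1.0, 2.0, 3.0])

    def test_csv_round_trip(self, tmp_path):
        curve = TimeCurve(times=[0.0, 1.5, 4.0], values=[0.1, 0.9, 0.4])
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = TimeCurve.from_csv(path)
        np.testing.assert_array_equal(back.times, curve.times)
        np.testing.assert_array_equal(back.values, curve.values)
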
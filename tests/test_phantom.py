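import numpy as np
import pytest

from dualkin.aif import parker_aif
from dualkin.dce_model import SPGRAcquisition, signal_to_concentration, tofts_forward
from dualkin.imaging import TimeCurve
from dualkin.pet_model import SokoloffParams, sokoloff_forward
from dualkin.phantom import (
    PhantomSpec,
    Region,
    build_phantom,
    dce_frame_schedule,
    default_phantom_spec,
    pet_frame_schedule,
    simulate_dce,
    simulate_pet,
)

from conftest import small_phantom_spec


class TestBuildPhantom:
    def test_deterministic_given_seed(self):
        gt1 = build_phantom(small_phantom_spec(seed=5))
        gt2 = build_phantom(small_phantom_spec(seed=5))
        for name in gt1.pet_maps:
            np.testing.assert_array_equal(
                gt1.pet_maps[name], gt2.pet_maps[name]
            )
        for name in gt1.dce_maps:
            np.testing.assert_array_equal(gt1.dce_maps[name], gt2.dce_maps[name])

    def test_zero_jitter_gives_two_distinct_parameter_vectors(self):
        gt = build_phantom(small_phantom_spec(jitter=0.0))
        mask = gt.tumor_mask.data
        k1 = gt.pet_maps["K1"][mask]
        assert set(np.round(np.unique(k1), 10)) == {0.08, 0.15}
        ktrans = gt.dce_maps["Ktrans"][mask]
        assert len(np.unique(np.round(ktrans, 10))) == 2

    def test_region_voxel_counts_match_brute_force(self):
        spec = small_phantom_spec(jitter=0.0)
        gt = build_phantom(spec)
        vs = spec.voxel_size_mm
        for i, region in enumerate(spec.regions, start=1):
            count = 0
            for idx in np.ndindex(*spec.shape):
                center = (np.asarray(idx) + 0.5) * vs
                d = (center - np.asarray(region.center_mm)) / np.asarray(region.radii_mm)
                inner = False
                for j, other in enumerate(spec.regions[i:], start=i + 1):
                    od = (center - np.asarray(other.center_mm)) / np.asarray(
                        other.radii_mm
                    )
                    if (od**2).sum() <= 1.0:
                        inner = True
                if (d**2).sum() <= 1.0 and not inner:
                    count += 1
            assert (gt.region_labels == i).sum() == count

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(
                shape=(16, 16, 8),
                regions=[
                    Region("r", (30.0, 16.0, 8.0), (6.0, 5.0, 4.0),
                           (0.1, 0.2, 0.05, 0.05), (0.2, 0.3, 0.05))
                ],
            )

    def test_subregion_outside_envelope_rejected(self):
        spec = small_phantom_spec()
        spec.regions[1].center_mm = (20.0, 14.0, 12.0)  # off the rim
        with pytest.raises(ValueError, match="envelope"):
            build_phantom(spec)

    def test_parameters_within_physiological_bounds(self):
        gt = build_phantom(default_phantom_spec(seed=11))
        mask = gt.tumor_mask.data
        for name in ("K1", "k2", "k3"):
            vals = gt.pet_maps[name][mask]
            assert np.all((vals >= 0) & (vals <= 5))
        assert np.all((gt.pet_maps["vb"][mask] >= 0) & (gt.pet_maps["vb"][mask] <= 1))
        ve = gt.dce_maps["ve"][mask]
        vp = gt.dce_maps["vp"][mask]
        assert np.all(ve + vp <= 1.0)


class TestSimulatePet:
    def test_noiseless_matches_forward_model(self, small_ground_truth):
        gt = small_ground_truth
        sched = pet_frame_schedule()
        img = simulate_pet(gt, sched, noise_scale=0.0)
        ix, iy, iz = np.argwhere(gt.tumor_mask.data)[0]
        grid = np.arange(0.0, 3601.0)
        from dualkin.aif import feng_aif

        cp = TimeCurve(grid, feng_aif(grid, delay_s=gt.spec.pet_bolus_delay_s))
        p = SokoloffParams(
            gt.pet_maps["K1"][ix, iy, iz], gt.pet_maps["k2"][ix, iy, iz],
            gt.pet_maps["k3"][ix, iy, iz], gt.pet_maps["vb"][ix, iy, iz],
        )
        expected = sokoloff_forward(p, cp, None, None, schedule=sched)
        np.testing.assert_allclose(img.data[ix, iy, iz, :], expected, rtol=1e-8)

    def test_inert_voxel_has_zero_activity(self):
        spec = small_phantom_spec(jitter=0.0)
        spec.regions = [
            Region("dead", (44.0, 32.0, 12.0), (6.0, 5.0, 4.0),
                   (0.0, 0.0, 0.0, 0.0), (0.0, 0.3, 0.0))
        ]
        gt = build_phantom(spec)
        img = simulate_pet(gt, noise_scale=0.0)
        np.testing.assert_array_equal(img.data[gt.tumor_mask.data, :], 0.0)

    def test_noise_sd_scales_inversely_with_frame_duration(self):
        # var = scale^2 * mean / duration: a 300 s frame has sqrt(10/300)
        # times the SD of a 10 s frame at equal mean
        spec = small_phantom_spec(jitter=0.0)
        gt = build_phantom(spec)
        from dualkin.imaging import FrameSchedule

        sched = FrameSchedule.from_durations([10.0, 300.0])
        # constant input makes both frame means equal
        ix, iy, iz = np.argwhere(gt.tumor_mask.data)[0]
        base = simulate_pet(gt, sched, noise_scale=0.0).data[ix, iy, iz, :]
        reps = np.array(
            [
                simulate_pet(gt, sched, noise_scale=2.0, seed=s).data[ix, iy, iz, :]
                for s in range(400)
            ]
        )
        sd = (reps - base).std(axis=0)
        expected_sd = 2.0 * np.sqrt(np.maximum(base, 0) / np.array([10.0, 300.0]))
        np.testing.assert_allclose(sd, expected_sd, rtol=0.2)

    def test_deterministic_given_seed(self, small_ground_truth):
        a = simulate_pet(small_ground_truth, noise_scale=1.5, seed=9)
        b = simulate_pet(small_ground_truth, noise_scale=1.5, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_aorta_carries_input_function(self, small_ground_truth):
        img = simulate_pet(small_ground_truth, noise_scale=0.0)
        voi = img.data[small_ground_truth.aorta_voi_mask.data, :]
        assert np.ptp(voi, axis=0).max() == pytest.approx(0.0)  # uniform blood pool
        assert voi.max() > 10.0  # carries the bolus


class TestSimulateDce:
    def test_inert_voxel_signal_constant_at_s0(self):
        spec = small_phantom_spec(jitter=0.0)
        spec.regions = [
            Region("dead", (44.0, 32.0, 12.0), (6.0, 5.0, 4.0),
                   (0.1, 0.2, 0.05, 0.05), (0.0, 0.3, 0.0))
        ]
        gt = build_phantom(spec)
        img = simulate_dce(gt, noise_frac=0.0)
        vox = img.data[gt.tumor_mask.data, :]
        np.testing.assert_allclose(vox, spec.s0, rtol=1e-12)

    def test_conversion_round_trip_recovers_concentration(self, small_ground_truth):
        gt = small_ground_truth
        acq = SPGRAcquisition()
        sched = dce_frame_schedule()
        img = simulate_dce(gt, sched, acq=acq, noise_frac=0.0)
        ix, iy, iz = np.argwhere(gt.tumor_mask.data)[5]
        mids = sched.midpoints
        cp = TimeCurve(mids, parker_aif(mids, delay_s=gt.spec.dce_bolus_delay_s))
        from dualkin.dce_model import ToftsParams

        truth_ct = tofts_forward(
            ToftsParams(
                gt.dce_maps["Ktrans"][ix, iy, iz], gt.dce_maps["ve"][ix, iy, iz],
                gt.dce_maps["vp"][ix, iy, iz],
            ),
            cp,
        )
        sig = TimeCurve(mids, img.data[ix, iy, iz, :])
        conc, valid = signal_to_concentration(
            sig, acq, float(gt.t10_map[ix, iy, iz]), gt.spec.s0
        )
        assert valid.all()
        np.testing.assert_allclose(
            conc.values, truth_ct, rtol=1e-6, atol=1e-9
        )

    def test_deterministic_given_seed(self, small_ground_truth):
        a = simulate_dce(small_ground_truth, noise_frac=0.02, seed=4)
        b = simulate_dce(small_ground_truth, noise_frac=0.02, seed=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_series_nonnegative(self, small_ground_truth):
        img = simulate_dce(small_ground_truth, noise_frac=0.0)
        assert img.data.min() >= 0.0


class TestSpecYaml:
    def test_yaml_round_trip(self, tmp_path, small_spec):
        path = tmp_path / "spec.yaml"
        small_spec.to_yaml(path)
        back = PhantomSpec.from_yaml(path)
        assert back.shape == small_spec.shape
        assert back.seed == small_spec.seed
        assert len(back.regions) == 2
        assert back.regions[0].pet == small_spec.regions[0].pet
        gt1 = build_phantom(small_spec)
        gt2 = build_phantom(back)
        np.testing.assert_array_equal(gt1.pet_maps["K1"], gt2.pet_maps["K1"])
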
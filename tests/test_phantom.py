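import dataclasses

import numpy as np
import pytest

import ctrsa
from ctrsa.phantom import AIR, CORTICAL, METAL, SOFT


class TestRasterize:
    def test_stem_interior_is_metal_before_smoothing(self, small_spec, small_labels):
        cx, cy = small_spec.center_xy
        zt = small_spec.bone_z_top
        # sample voxel centers strictly inside the stem
        sp = np.array(small_spec.spacing)
        idx = np.round(
            np.array([cx, cy + small_spec.stem_offset_mm, zt - small_spec.stem_length / 2]) / sp
        ).astype(int)
        assert small_labels[idx[0], idx[1], idx[2]] == METAL
        hu = ctrsa.rasterize_scene(small_spec, smooth=False)
        # within a fraction of a percent of the palette value (the soft
        # occupancy edge has an exponentially small interior tail)
        assert hu.data[idx[0], idx[1], idx[2]] == pytest.approx(small_spec.hu_metal, rel=0.005)

    def test_all_tissue_classes_present(self, small_labels):
        assert set(np.unique(small_labels)) == {AIR, SOFT, CORTICAL, METAL}

    def test_translation_equivariance_integer_shift(self, small_spec, small_volume):
        # 3.0 mm = 5 voxels in x: the shifted render must equal the shifted array
        shift = ctrsa.RigidTransform(np.eye(3), (3.0, 0.0, 0.0))
        moved = ctrsa.rasterize_scene(small_spec, scene_pose=shift)
        # compare away from the grid borders, where the smoothing padding
        # differs between the two renders
        m = 4
        np.testing.assert_allclose(
            moved.data[5 + m:-m, m:-m, m:-m],
            small_volume.data[m:-5 - m, m:-m, m:-m],
            atol=0.05,
        )

    def test_implant_migration_displaces_metal_centroid(self, small_spec, small_volume):
        mig = ctrsa.RigidTransform(np.eye(3), (0.0, 1.0, 0.0))
        moved = ctrsa.rasterize_scene(small_spec, implant_migration=mig)
        sp = np.array(small_spec.spacing)

        def metal_centroid(vol):
            # metal-excess-weighted centroid: sub-voxel accurate where the
            # hard mask centroid is quantized by the thin plate's few slices
            w = np.clip(vol.data - 2200.0, 0.0, None)
            idx = np.indices(vol.data.shape).reshape(3, -1)
            return (idx * w.ravel()).sum(axis=1) / w.sum() * sp

        delta = metal_centroid(moved) - metal_centroid(small_volume)
        assert abs(delta[1] - 1.0) <= 0.5 * small_spec.spacing[1]
        assert np.all(np.abs(delta[[0, 2]]) <= 0.5 * sp[[0, 2]])

    def test_bone_and_soft_unaffected_by_migration(self, small_spec):
        mig = ctrsa.RigidTransform(np.eye(3), (0.0, 1.0, 0.0))
        lab0 = ctrsa.rasterize_labels(small_spec)
        lab1 = ctrsa.rasterize_labels(small_spec, implant_migration=mig)
        np.testing.assert_array_equal(lab0 == CORTICAL, lab1 == CORTICAL)

    def test_out_of_fov_names_shape(self, small_spec):
        push = ctrsa.RigidTransform(np.eye(3), (30.0, 0.0, 0.0))
        with pytest.raises(ctrsa.FieldOfViewError, match="soft_tissue|bone|implant"):
            ctrsa.rasterize_scene(small_spec, scene_pose=push)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ctrsa.ConfigError):
            ctrsa.PhantomSpec(stem_radius=10.0)  # stem wider than canal
        with pytest.raises(ctrsa.ConfigError):
            ctrsa.PhantomSpec(hu_cortical=150.0)  # below the bone threshold

    def test_threshold_separability(self, small_spec, small_volume, small_labels):
        """The clinical thresholds recover the rasterized classes up to the
        one-voxel smoothing shell."""
        from scipy.ndimage import binary_dilation, binary_erosion

        cube = np.ones((3, 3, 3), bool)
        metal_truth = small_labels == METAL
        metal_mask = small_volume.data >= 2200.0
        assert not (metal_mask & ~binary_dilation(metal_truth, cube)).any()
        assert (binary_erosion(metal_truth, cube, iterations=2) <= metal_mask).all()
        dense_truth = (small_labels == METAL) | (small_labels == CORTICAL)
        bone_mask = small_volume.data >= 200.0
        assert not (bone_mask & ~binary_dilation(dense_truth, cube, iterations=2)).any()
        assert (binary_erosion(dense_truth, cube, iterations=2) <= bone_mask).all()


class TestDegrade:
    def test_noop_profile_is_bit_identical(self, small_volume):
        out = ctrsa.degrade(small_volume, ctrsa.NO_DEGRADATION, seed=3)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_deterministic_given_seed(self, small_volume):
        prof = ctrsa.ScannerProfile("test", noise_sd=20.0,
                                    artifact_amplitude=100.0, artifact_n_streaks=3)
        a = ctrsa.degrade(small_volume, prof, seed=42)
        b = ctrsa.degrade(small_volume, prof, seed=42)
        np.testing.assert_array_equal(a.data, b.data)
        c = ctrsa.degrade(small_volume, prof, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_noise_sd_matches_request(self):
        flat = ctrsa.Volume(np.zeros((50, 50, 50), np.float32), (1, 1, 1))
        prof = ctrsa.ScannerProfile("noise", noise_sd=20.0)
        out = ctrsa.degrade(flat, prof, seed=0)
        assert out.data.std() == pytest.approx(20.0, rel=0.10)

    def test_streaks_emanate_from_metal(self, small_volume):
        prof = ctrsa.ScannerProfile("streaky", artifact_amplitude=300.0,
                                    artifact_n_streaks=4)
        out = ctrsa.degrade(small_volume, prof, seed=1)
        delta = np.abs(out.data - small_volume.data)
        assert delta.max() > 100.0  # streaks present
        # but confined to thin planes: most voxels barely touched
        assert np.mean(delta < 30.0) > 0.5


class TestSeries:
    def test_seven_poses_enable_21_pairs(self, small_spec):
        series = ctrsa.simulate_series(small_spec, ctrsa.NO_DEGRADATION,
                                       n_poses=7, pose_magnitude=1.0, seed=5)
        assert len(series) == 7
        n = len(series)
        assert n * (n - 1) // 2 == 21
        # scan 1 at identity, zero-motion design throughout
        assert series[0][1].scene_pose.is_identity()
        for _, gt in series:
            assert gt.implant_migration.is_identity()

    def test_series_deterministic(self, small_spec):
        a = ctrsa.simulate_series(small_spec, ctrsa.GE_LIKE, n_poses=2,
                                  pose_magnitude=1.0, seed=9)
        b = ctrsa.simulate_series(small_spec, ctrsa.GE_LIKE, n_poses=2,
                                  pose_magnitude=1.0, seed=9)
        for (va, ga), (vb, gb) in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)
            assert ga.scene_pose.allclose(gb.scene_pose, 1e-12, 1e-12)

    def test_needs_two_poses(self, small_spec):
        with pytest.raises(ctrsa.ConfigError):
            ctrsa.simulate_series(small_spec, ctrsa.NO_DEGRADATION, n_poses=1)

    def test_truth_relative_motion_zero_for_shared_migration(self, small_spec):
        series = ctrsa.simulate_series(small_spec, ctrsa.NO_DEGRADATION,
                                       n_poses=3, pose_magnitude=1.0, seed=2)
        rel = ctrsa.truth_relative_motion(series[1][1], series[2][1])
        assert rel.is_identity(1e-9, 1e-9)

    def test_migration_pair_truth_equals_injected(self, small_spec):
        mig = ctrsa.RigidTransform.from_euler((0, 0.5, 0), (0.3, 0, 0))
        (b, gb), (f, gf) = ctrsa.migration_pair(small_spec, mig,
                                                pose_magnitude=1.0, seed=4)
        rel = ctrsa.truth_relative_motion(gb, gf)
        assert rel.allclose(mig, 1e-9, 1e-9)

    def test_ground_truth_json_roundtrip(self, small_spec, tmp_path):
        series = ctrsa.simulate_series(small_spec, ctrsa.NO_DEGRADATION,
                                       n_poses=2, pose_magnitude=1.0, seed=1)
        gt = series[1][1]
        path = tmp_path / "truth.json"
        gt.save(path)
        back = ctrsa.GroundTruth.load(path)
        assert back.scene_pose.allclose(gt.scene_pose, 1e-10, 1e-10)
        assert back.seed == gt.seed


class TestImplantModel:
    def test_features_first_and_labeled(self, small_model):
        assert small_model.labels[:5] == list(ctrsa.phantom.FEATURE_LABELS)
        assert len(small_model) > 200

    def test_feature_geometry(self, small_spec, small_model):
        med = small_model.select("medial")[0]
        lat = small_model.select("lateral")[0]
        tip = small_model.select("tip")[0]
        assert med[0] > lat[0]  # medial is +x
        assert np.allclose(med[2], lat[2])
        assert tip[2] < med[2]  # tip is distal
        assert np.linalg.norm(med - lat) == pytest.approx(small_spec.plate_extent[0])

    def test_model_points_lie_on_metal_surface(self, small_spec, small_model):
        lab = ctrsa.rasterize_labels(small_spec)
        sp = np.array(small_spec.spacing)
        from scipy.ndimage import binary_dilation

        near = binary_dilation(lab == METAL, np.ones((3, 3, 3), bool))
        idx = np.clip(np.round(small_model.points / sp).astype(int), 0,
                      np.array(lab.shape) - 1)
        frac = near[tuple(idx.T)].mean()
        assert frac > 0.97
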
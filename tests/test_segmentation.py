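"""Automated islet quantitation: pancreas delineation, islet objects, spots."""

import numpy as np
import pytest

from isletmorph import (
    HeadTailROI,
    SceneSpec,
    VolumetricImage,
    count_spots,
    delineate_pancreas,
    islet_report,
    render_scene,
    segment_islets,
)

FULL_FIELD_ROI = HeadTailROI(np.array([[0.0, 0.1], [100.0, 0.1]]), tail_side=1)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


class TestDelineatePancreas:
    def test_clean_ellipsoid_recovered(self, two_sphere_scene):
        spec, red, green, truth = two_sphere_scene
        result = delineate_pancreas(red, FULL_FIELD_ROI)
        assert not result.empty
        assert dice(result.mask, truth.pancreas_mask) >= 0.95

    def test_zero_signal_flagged_not_raised(self):
        red = VolumetricImage(np.zeros((8, 16, 16)), (1.0, 0.5, 0.5))
        result = delineate_pancreas(red, FULL_FIELD_ROI)
        assert result.empty
        assert not result.mask.any()

    def test_flipping_tail_side_confines_mask_to_other_half(self):
        spec = SceneSpec(grid_shape=(16, 64, 64), voxel_size=(1.0, 0.5, 0.5),
                         pancreas_center=(8.0, 16.0, 10.0),
                         pancreas_semiaxes=(6.0, 10.0, 6.0), n_cells=0,
                         noise_gaussian_sd=0.5, seed=1)
        red, _, _ = render_scene(spec, centers=np.zeros((0, 3)), radii=np.zeros(0))
        # vertical split at x = 16 µm: blob lives on the x < 16 side
        roi_left = HeadTailROI(np.array([[0.0, 16.0], [32.0, 16.0]]), tail_side=-1)
        roi_right = HeadTailROI(np.array([[0.0, 16.0], [32.0, 16.0]]), tail_side=1)
        left = delineate_pancreas(red, roi_left)
        right = delineate_pancreas(red, roi_right)
        assert not left.empty
        x_um = (np.arange(64) + 0.5) * 0.5
        assert np.all(x_um[np.where(left.mask)[2]] < 16.0)
        assert right.empty or np.all(x_um[np.where(right.mask)[2]] > 16.0)


class TestSegmentIslets:
    def test_min_volume_filter_keeps_exactly_the_large_sphere(self, two_sphere_scene):
        spec, red, green, truth = two_sphere_scene
        objects = segment_islets(green, truth.pancreas_mask, min_volume=100.0)
        assert len(objects) == 1
        assert objects[0].volume == pytest.approx(truth.islet_volumes[0], rel=0.15)

    def test_empty_green_channel_gives_empty_list(self, two_sphere_scene):
        spec, red, green, truth = two_sphere_scene
        blank = VolumetricImage(np.zeros_like(green.voxels), green.voxel_size)
        assert segment_islets(blank, truth.pancreas_mask) == []

    def test_empty_pancreas_mask_is_an_error(self, two_sphere_scene):
        _, _, green, _ = two_sphere_scene
        with pytest.raises(ValueError, match="empty"):
            segment_islets(green, np.zeros_like(green.voxels, dtype=bool))

    def test_volume_error_shrinks_with_resolution(self):
        analytic = (4.0 / 3.0) * np.pi * 4.0**3
        errors = []
        for h in (1.0, 0.5):
            n = int(24 / h)
            spec = SceneSpec(grid_shape=(n, n, n), voxel_size=(h, h, h),
                             pancreas_center=(12.0,) * 3, pancreas_semiaxes=(11.0,) * 3,
                             n_cells=1, psf_sigma=(0, 0, 0), noise_gaussian_sd=0,
                             noise_poisson_scale=None, seed=0)
            _, green, truth = render_scene(spec, centers=np.array([[12.0] * 3]), radii=4.0)
            objects = segment_islets(green, truth.pancreas_mask, min_volume=100.0,
                                     smoothing_sigma=0.0, background_radius=0.0)
            assert len(objects) == 1
            rel_err = abs(objects[0].volume - analytic) / analytic
            # bounded by the one-voxel surface-shell fraction of the sphere
            shell_fraction = 4 * np.pi * 4.0**2 * h / analytic
            assert rel_err <= shell_fraction
            errors.append(rel_err)
        assert errors[1] < errors[0]

    def test_raising_min_volume_is_monotone_in_object_count(self, two_sphere_scene):
        spec, red, green, truth = two_sphere_scene
        counts = [
            len(segment_islets(green, truth.pancreas_mask, min_volume=mv))
            for mv in (0.0, 50.0, 100.0, 300.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_total_islet_volume_within_pancreas_volume(self, two_sphere_scene):
        spec, red, green, truth = two_sphere_scene
        objects = segment_islets(green, truth.pancreas_mask, min_volume=0.0)
        pancreas_volume = truth.pancreas_mask.sum() * np.prod(spec.voxel_size)
        assert sum(o.volume for o in objects) <= pancreas_volume

    def test_axis_rotation_equivariance(self):
        spec = SceneSpec(grid_shape=(40, 40, 40), voxel_size=(0.5, 0.5, 0.5),
                         pancreas_center=(10.0, 10.0, 8.0),
                         pancreas_semiaxes=(9.0, 8.0, 7.0), n_cells=2,
                         psf_sigma=(0.3,) * 3, noise_gaussian_sd=0.5, seed=4)
        centers = np.array([[10.0, 8.0, 8.0], [10.0, 14.0, 9.0]])
        _, green, truth = render_scene(spec, centers=centers, radii=np.array([3.0, 2.8]))
        objs = segment_islets(green, truth.pancreas_mask, min_volume=50.0)
        rot = VolumetricImage(np.rot90(green.voxels, axes=(1, 2)), spec.voxel_size)
        objs_rot = segment_islets(rot, np.rot90(truth.pancreas_mask, axes=(1, 2)),
                                  min_volume=50.0)
        assert sorted(o.voxel_count for o in objs) == sorted(o.voxel_count for o in objs_rot)


class TestCountSpots:
    def _nuclei_scene(self, centers, seed=3):
        spec = SceneSpec(grid_shape=(30, 60, 60), voxel_size=(1.0, 0.5, 0.5),
                         pancreas_center=(15.0, 15.0, 15.0),
                         pancreas_semiaxes=(13.0, 14.0, 14.0), n_cells=0,
                         psf_sigma=(0.5, 0.3, 0.3), noise_gaussian_sd=0.5, seed=seed)
        _, green, truth = render_scene(spec, centers=centers, radii=2.5)
        return green, truth

    def test_three_nuclei_counted(self):
        centers = np.array([[15.0, 8.0, 8.0], [15.0, 15.0, 20.0], [10.0, 20.0, 12.0]])
        green, _ = self._nuclei_scene(centers)
        spots = count_spots(green, np.ones(green.voxels.shape, bool),
                            diameter=5.0, intensity_threshold=20.0)
        assert len(spots) == 3

    def test_nucleus_outside_mask_excluded(self):
        centers = np.array([[15.0, 8.0, 8.0], [15.0, 15.0, 20.0], [10.0, 20.0, 12.0]])
        green, _ = self._nuclei_scene(centers)
        mask = np.ones(green.voxels.shape, bool)
        mask[:, :, 30:] = False  # x >= 15 µm excluded, cuts the x=20 nucleus
        spots = count_spots(green, mask, diameter=5.0, intensity_threshold=20.0)
        assert len(spots) == 2

    def test_seeded_random_nuclei_all_found_near_truth(self):
        rng = np.random.default_rng(12)
        # 12 non-overlapping positions on a jittered grid
        base = np.array([(z, y, x) for z in (8.0, 20.0) for y in (7.0, 15.0, 23.0)
                         for x in (8.0, 21.0)])
        centers = base + rng.uniform(-1, 1, base.shape)
        green, truth = self._nuclei_scene(centers, seed=12)
        spots = count_spots(green, np.ones(green.voxels.shape, bool),
                            diameter=5.0, intensity_threshold=20.0)
        assert len(spots) == 12
        for c in truth.cell_centers:
            nearest = np.min(np.linalg.norm(spots.centers - c, axis=1))
            assert nearest <= max(green.voxel_size)

    def test_empty_mask_gives_empty_spotset(self):
        green, _ = self._nuclei_scene(np.array([[15.0, 15.0, 15.0]]))
        spots = count_spots(green, np.zeros(green.voxels.shape, bool), diameter=5.0)
        assert len(spots) == 0


class TestIsletReport:
    def _objects(self, n, offset=0):
        from isletmorph.segmentation import IsletObject

        return [
            IsletObject(label=i + 1, volume=120.0 + 10 * (i + offset),
                        centroid=(1.0, 2.0, 3.0), voxel_count=100, mean_intensity=50.0)
            for i in range(n)
        ]

    def test_row_per_object(self, tmp_path):
        table = islet_report(
            {"s1": self._objects(3), "s2": self._objects(2, offset=5)},
            {"s1": "CTL", "s2": "LY"},
            out_dir=tmp_path,
        )
        assert len(table) == 5
        assert set(table["group"]) == {"CTL", "LY"}

    def test_empty_sample_still_logged(self, tmp_path):
        import json

        table = islet_report({"s1": self._objects(2), "s2": []}, {"s1": "a", "s2": "b"},
                             out_dir=tmp_path)
        assert len(table) == 2
        log = json.loads((tmp_path / "run_log.json").read_text())
        assert log["samples"]["s2"]["n_objects"] == 0

    def test_rerun_is_byte_identical(self, tmp_path):
        objs = {"s1": self._objects(3), "s2": self._objects(2)}
        groups = {"s1": "CTL", "s2": "LY"}
        islet_report(objs, groups, out_dir=tmp_path / "a")
        islet_report(objs, groups, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "islet_volumes.csv").read_bytes() == \
               (tmp_path / "b" / "islet_volumes.csv").read_bytes()
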
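"""Surface shape-index histogram and mask-geometry descriptors."""

import numpy as np
import pytest

from deltarad import LesionMask
from deltarad.features import (
    boundary_radius_std,
    max_diameter,
    shape_index_features,
    tumor_volume,
)
from deltarad.features.geometry import surface_voxels
from deltarad.errors import DegenerateLesionError
from conftest import make_ball_mask


def random_blob_mask(rng, shape=(9, 9, 9), p=0.4):
    data = (rng.random(shape) < p).astype(np.uint8)
    data[4, 4, 4] = 1  # guarantee nonempty
    return LesionMask(data=data, spacing=(1.0, 1.0, 1.0))


class TestShapeIndex:
    def test_fractions_partition_the_surface(self, rng):
        si = shape_index_features(random_blob_mask(rng))
        assert sum(si.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in si.values())

    def test_ball_surface_is_dominated_by_the_cap_bin(self, ball8):
        # sphere: kappa1 = kappa2 = 1/r > 0 maps to s ~ 0, i.e. bin SI1
        si = shape_index_features(ball8)
        assert si["Shape_SI1"] >= 0.8

    def test_mirror_image_has_identical_histogram(self, rng):
        mask = random_blob_mask(rng)
        flipped = LesionMask(data=mask.data[:, :, ::-1].copy(), spacing=mask.spacing)
        a = shape_index_features(mask)
        b = shape_index_features(flipped)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateLesionError):
            shape_index_features(
                LesionMask(data=np.zeros((4, 4, 4)), spacing=(1, 1, 1))
            )


class TestVolumeAndDiameter:
    def test_single_voxel_volume_arithmetic(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1
        mask = LesionMask(data=data, spacing=(0.25, 0.25, 0.25))
        assert tumor_volume(mask) == pytest.approx(0.015625)

    def test_voxel_count_times_voxel_volume(self):
        mask = LesionMask(data=np.ones((10, 10, 10)), spacing=(1, 1, 1))
        assert tumor_volume(mask) == pytest.approx(1000.0)

    def test_ball_volume_within_5pct_of_analytic(self):
        mask = make_ball_mask(6.0, 1.0)
        assert abs(tumor_volume(mask) - 904.78) / 904.78 < 0.05

    def test_two_voxel_diameter(self):
        data = np.zeros((1, 1, 12))
        data[0, 0, 0] = data[0, 0, 10] = 1
        mask = LesionMask(data=data, spacing=(0.7, 0.7, 0.7))
        assert max_diameter(mask) == pytest.approx(7.0)

    def test_single_voxel_diameter_is_zero(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1
        assert max_diameter(LesionMask(data=data, spacing=(1, 1, 1))) == 0.0

    def test_matches_exhaustive_pairwise_search(self, rng):
        for _ in range(5):
            mask = random_blob_mask(rng, shape=(7, 8, 6), p=0.3)
            surf = surface_voxels(mask) * np.asarray(mask.spacing)
            brute = 0.0
            for i in range(len(surf)):
                for j in range(i + 1, len(surf)):
                    brute = max(brute, float(np.linalg.norm(surf[i] - surf[j])))
            assert max_diameter(mask) == pytest.approx(brute)

    def test_hull_shortcut_agrees_with_brute_force_on_large_surface(self, rng):
        mask = make_ball_mask(8.0, 1.0)  # > 400 surface voxels: hull path
        surf = surface_voxels(mask).astype(float)
        from scipy.spatial.distance import pdist

        assert max_diameter(mask) == pytest.approx(pdist(surf).max())
        assert abs(max_diameter(mask) - 16.0) <= np.sqrt(3)


class TestBoundaryRadiusStd:
    def test_single_voxel_is_zero(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1
        assert boundary_radius_std(LesionMask(data=data, spacing=(1, 1, 1))) == 0.0

    def test_ball_is_nearly_zero(self):
        mask = make_ball_mask(8.0, 0.5)
        assert boundary_radius_std(mask) < 0.5

    def test_matches_explicit_loop_oracle(self, rng):
        mask = random_blob_mask(rng)
        spacing = np.asarray(mask.spacing)
        fg = np.argwhere(mask.data > 0) * spacing
        centroid = fg.mean(axis=0)
        dists = [float(np.linalg.norm(v * spacing - centroid)) for v in surface_voxels(mask)]
        expected = float(np.std(dists))
        assert boundary_radius_std(mask) == pytest.approx(expected, rel=1e-12)

    def test_scales_linearly_with_spacing(self, rng):
        mask1 = random_blob_mask(rng)
        mask2 = LesionMask(data=mask1.data, spacing=(2.0, 2.0, 2.0))
        assert boundary_radius_std(mask2) == pytest.approx(2 * boundary_radius_std(mask1))
        assert max_diameter(mask2) == pytest.approx(2 * max_diameter(mask1))
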
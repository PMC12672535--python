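"""Morphometry: components, Feret, sphericity, nodule criteria, capillary
densities, volume fractions, shrinkage correction, group tests."""

import numpy as np
import pytest

from lymphomorph import morphometry as morph
from lymphomorph.phantom import rasterize_ellipsoid
from lymphomorph.volumes import CLASS_MAP, LabelVolume
from tests.test_phantom import flood_fill_count


def _labels_from(arr: np.ndarray, voxel_um: float = 1.8) -> LabelVolume:
    return LabelVolume(arr.astype(np.uint8), voxel_um)


class TestConnectedComponents:
    def test_empty_class_gives_empty_list(self):
        labels = _labels_from(np.ones((5, 5, 5)))
        assert morph.connected_components(labels, "nodule") == []

    def test_two_disjoint_balls(self):
        arr = np.ones((40, 40, 40), dtype=np.uint8)
        ball = rasterize_ellipsoid(8.0, (1.0, 1.0))
        n = ball.shape[0]
        arr[2:2 + n, 2:2 + n, 2:2 + n][ball] = 6
        arr[25:25 + n, 25:25 + n, 25:25 + n][ball] = 6
        labels = _labels_from(arr)
        objs = morph.connected_components(labels, "nodule")
        assert len(objs) == flood_fill_count(arr == 6) == 2
        assert all(o.voxel_count == int(ball.sum()) for o in objs)

    def test_phantom_ground_truth_count(self, small_phantom, small_spec):
        _, labels = small_phantom
        objs = morph.connected_components(labels, "nodule")
        assert len(objs) == small_spec.nodule_count

    def test_unknown_class_raises(self, small_phantom):
        _, labels = small_phantom
        with pytest.raises(KeyError):
            morph.connected_components(labels, "spleen")

    def test_deterministic_ordering(self):
        arr = np.ones((30, 30, 30), dtype=np.uint8)
        arr[20:24, 2:6, 2:6] = 6
        arr[2:6, 20:24, 20:24] = 6
        objs = morph.connected_components(_labels_from(arr), "nodule")
        firsts = [o.bounding_box[0][0] for o in objs]
        assert firsts == sorted(firsts)


class TestFeret:
    def test_single_voxel_is_voxel_pitch(self):
        assert morph.feret_diameter(np.array([[3, 3, 3]]), 1.8) == 1.8

    def test_rod_twenty_voxels(self):
        coords = np.array([[0, 0, i] for i in range(20)])
        assert morph.feret_diameter(coords, 1.8) == pytest.approx(
            19 * 1.8 + 1.8)

    def test_ball_brute_force_oracle(self):
        ball = rasterize_ellipsoid(20.0, (1.0, 1.0))
        coords = np.argwhere(ball)
        # independent oracle: brute force over all voxel pairs
        surf = coords
        d2 = 0.0
        step = max(1, len(surf) // 600)
        sub = surf[::step].astype(float)
        d2 = np.max(np.sum((sub[:, None] - sub[None]) ** 2, axis=-1))
        brute = np.sqrt(d2) + 1.0
        assert morph.feret_diameter(coords, 1.0) >= brute - 1e-9
        assert morph.feret_diameter(coords, 1.0) == pytest.approx(21.0, abs=1.0)

    def test_translation_invariance(self):
        ball = rasterize_ellipsoid(12.0, (1.0, 1.0))
        coords = np.argwhere(ball)
        shifted = coords + np.array([7, 3, 11])
        assert morph.feret_diameter(coords, 1.0) == pytest.approx(
            morph.feret_diameter(shifted, 1.0))


class TestSphericity:
    def test_large_ball_close_to_one(self):
        coords = np.argwhere(rasterize_ellipsoid(30.0, (1.0, 1.0)))
        assert morph.sphericity(coords) >= 0.9

    def test_rod_far_from_spherical(self):
        coords = np.array([[0, 0, i] for i in range(20)])
        assert morph.sphericity(coords) < 0.6

    def test_bounded_above(self):
        for d in (6.0, 10.0, 16.0):
            coords = np.argwhere(rasterize_ellipsoid(d, (0.8, 0.9)))
            assert 0.0 < morph.sphericity(coords) <= 1.05

    def test_tiny_object_raises(self):
        with pytest.raises(ValueError):
            morph.sphericity(np.array([[0, 0, 0]]))


class TestClassifyNodules:
    def test_cortical_sphere_rejected_by_localisation(self, small_phantom):
        _, labels = small_phantom
        objs = morph.connected_components(labels, "follicle")
        # follicles satisfy shape and (mostly) size criteria but sit in the
        # cortex: the medulla criterion must reject all of them
        crit = morph.NoduleCriteria(feret_um_range=(30.0, 400.0),
                                    sphericity_min=0.0)
        accepted = morph.classify_nodules(objs, labels, crit)
        assert accepted == []

    def test_size_window_rejects_small_objects(self, small_phantom):
        _, labels = small_phantom
        objs = morph.connected_components(labels, "nodule")
        crit = morph.NoduleCriteria(feret_um_range=(400.0, 500.0), min_voxels=1)
        assert morph.classify_nodules(objs, labels, crit) == []

    def test_phantom_nodules_all_accepted(self, small_phantom, small_spec):
        _, labels = small_phantom
        objs = morph.connected_components(labels, "nodule")
        accepted = morph.classify_nodules(objs, labels,
                                          morph.NoduleCriteria(min_voxels=8))
        assert len(accepted) == small_spec.nodule_count

    def test_subset_of_components(self, small_phantom):
        _, labels = small_phantom
        objs = morph.connected_components(labels, "nodule")
        accepted = morph.classify_nodules(objs, labels,
                                          morph.NoduleCriteria(min_voxels=8))
        ids = {o.object_id for o in objs}
        assert {o.object_id for o in accepted} <= ids

    def test_missing_medulla_raises(self):
        labels = _labels_from(np.ones((6, 6, 6)))
        with pytest.raises(ValueError):
            morph.MedullaRegion(labels)


class TestCapillaryDensity:
    def test_hand_built_block(self):
        # 10x10x10 DCU block inside parenchyma with 100 interior capillary
        # voxels: density = 100 / 1000 by construction
        arr = np.ones((20, 20, 20), dtype=np.uint8)
        arr[5:15, 5:15, 5:15] = 3  # dcu
        arr[8:12, 8:12, 7:13] = 10  # 96 capillary voxels fully inside
        cap = int((arr == 10).sum())
        assert cap == 96
        labels = _labels_from(arr)
        density = morph.capillary_density(labels, "dcu")
        assert density == pytest.approx(cap / 1000.0)

    def test_no_capillaries_zero_density(self, small_phantom):
        _, labels = small_phantom
        # the small phantom has no capillaries configured for nodules
        assert morph.capillary_density(labels, "nodule") == 0.0

    def test_density_in_unit_interval(self, small_phantom):
        _, labels = small_phantom
        stats = morph.capillary_stats(labels)
        for s in stats.values():
            assert 0.0 <= s.capillary_density <= 1.0

    def test_empty_compartment_raises(self, small_phantom):
        _, labels = small_phantom
        with pytest.raises(ValueError):
            morph.capillary_density(labels, "background")


class TestDensityRatio:
    def test_identical_stats_ratio_one(self):
        s = morph.CompartmentStats("dcu", 1000, 100, 0.1, 10.0)
        assert morph.density_ratio(s, s) == 1.0

    def test_hand_arithmetic(self):
        a = morph.CompartmentStats("follicle", 1000, 220, 0.22, 5.0)
        b = morph.CompartmentStats("dcu", 1000, 100, 0.10, 20.0)
        assert morph.density_ratio(a, b) == pytest.approx(2.2)

    def test_zero_reference_raises(self):
        a = morph.CompartmentStats("follicle", 10, 1, 0.1, 1.0)
        b = morph.CompartmentStats("dcu", 10, 0, 0.0, 1.0)
        with pytest.raises(ZeroDivisionError):
            morph.density_ratio(a, b)


class TestVolumeFraction:
    def test_absent_class_zero(self, small_phantom):
        _, labels = small_phantom
        assert morph.volume_fraction(labels, "outer_vasculature") >= 0.0

    def test_counting_oracle(self):
        arr = np.ones((10, 10, 10), dtype=np.uint8)
        flat = arr.reshape(-1)
        flat[:47] = 6
        labels = _labels_from(arr)
        assert morph.volume_fraction(labels, "nodule") == pytest.approx(4.7)

    def test_partition_sums_to_hundred(self, small_phantom):
        _, labels = small_phantom
        total = sum(
            morph.volume_fraction(labels, name)
            for name in CLASS_MAP.values()
            if name not in ("background", "adjacent_tissue"))
        assert total == pytest.approx(100.0, abs=1e-9)


class TestShrinkageCorrect:
    def test_zero_shrinkage_identity(self):
        assert morph.shrinkage_correct(90.0, 0.0) == 90.0

    def test_printed_correction(self):
        assert morph.shrinkage_correct(90.0, 0.30) == pytest.approx(128.571,
                                                                    abs=0.001)

    def test_roundtrip_exact(self):
        d = 123.4
        assert morph.shrinkage_correct(d * (1 - 0.3), 0.3) == pytest.approx(d)

    def test_invalid_factor_raises(self):
        with pytest.raises(ValueError):
            morph.shrinkage_correct(90.0, 1.0)


class TestCompareGroups:
    def test_exact_enumeration_small_groups(self):
        _, p = morph.compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = morph.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_stars_convention(self):
        assert morph.significance_stars(0.005) == "**"
        assert morph.significance_stars(0.03) == "*"
        assert morph.significance_stars(0.2) == "ns"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            morph.compare_groups([], [1.0])
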
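"""Voxel encodings and sphere-cell intersection geometry."""

import numpy as np
import pytest

from voxelppi.tensorize import (ATOM_RADII, EncodingConfig, VoxelGrid,
                                circle_rect_area, encode_distance,
                                encode_one_hot, encode_volume,
                                intersection_volume_integral,
                                intersection_volume_mc, render)
from voxelppi.preprocess import compute_interface

from conftest import ca, make_complex

SPHERE = lambda r: 4.0 / 3.0 * np.pi * r ** 3


def single_atom_complex(xyz_a, xyz_b=(40.0, 0.0, 0.0), elem_a="C"):
    return make_complex([ca(1, xyz_a, element=elem_a)], [ca(1, xyz_b)])


class TestIntersectionVolume:
    def test_integral_inscribed_sphere(self):
        v = intersection_volume_integral((-0.5, -0.5, -0.5), (0, 0, 0), 0.5)
        assert v == pytest.approx(SPHERE(0.5), abs=1e-9)

    def test_integral_disjoint(self):
        assert intersection_volume_integral((5, 5, 5), (0, 0, 0), 0.7) == 0.0

    def test_integral_conserves_sphere_volume(self):
        center = np.array([0.31, 0.47, 0.59])
        total = sum(
            intersection_volume_integral((i, j, k), center, 0.7)
            for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3))
        assert total == pytest.approx(SPHERE(0.7), abs=1e-9)

    def test_mc_cell_inside_sphere(self):
        v = intersection_volume_mc((-0.5, -0.5, -0.5), (0, 0, 0), 3.0,
                                   n_points=1000, seed=0)
        assert v == 1.0

    def test_mc_cell_outside_sphere(self):
        v = intersection_volume_mc((5, 5, 5), (0, 0, 0), 0.7,
                                   n_points=1000, seed=0)
        assert v == 0.0

    def test_mc_corner_centered_octant(self):
        v = intersection_volume_mc((0, 0, 0), (0, 0, 0), 0.7,
                                   n_points=200_000, seed=1)
        assert v == pytest.approx(SPHERE(0.7) / 8.0, abs=0.004)

    def test_mc_deterministic_given_seed(self):
        args = ((0.1, -0.2, 0.0), (0.4, 0.3, 0.3), 0.65)
        v1 = intersection_volume_mc(*args, n_points=10_000, seed=42)
        v2 = intersection_volume_mc(*args, n_points=10_000, seed=42)
        assert v1 == v2

    def test_mc_matches_integral_on_random_cells(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            radius = rng.choice(list(ATOM_RADII.values()))
            center = rng.uniform(-1, 1, 3)
            corner = rng.uniform(-1, 0, 3)
            exact = intersection_volume_integral(corner, center, radius)
            mc = intersection_volume_mc(corner, center, radius,
                                        n_points=100_000,
                                        seed=int(rng.integers(2**31)))
            assert mc == pytest.approx(exact, abs=3e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            intersection_volume_integral((0, 0, 0), (0, 0, 0), -1.0)
        with pytest.raises(ValueError):
            intersection_volume_mc((0, 0, 0), (0, 0, 0), 0.5, n_points=0)


class TestCircleRectArea:
    def test_full_disk_inside_rectangle(self):
        assert circle_rect_area(-2, 2, -2, 2, 1.0) == pytest.approx(np.pi)

    def test_quarter_disk(self):
        assert circle_rect_area(0, 2, 0, 2, 1.0) == pytest.approx(np.pi / 4)

    def test_matches_grid_estimate(self):
        rng = np.random.default_rng(0)
        xs = np.linspace(-1.5, 1.5, 601)
        for _ in range(5):
            x0, y0 = rng.uniform(-1.2, 0.2, 2)
            x1, y1 = x0 + rng.uniform(0.3, 1.5), y0 + rng.uniform(0.3, 1.5)
            r = rng.uniform(0.3, 1.2)
            gx, gy = np.meshgrid(xs, xs, indexing="ij")
            inside = ((gx > x0) & (gx < x1) & (gy > y0) & (gy < y1)
                      & (gx ** 2 + gy ** 2 < r ** 2))
            est = inside.mean() * 3.0 ** 2
            assert circle_rect_area(x0, x1, y0, y1, r) == pytest.approx(
                est, abs=3e-3)


class TestOneHot:
    def test_single_atom_at_center(self):
        cfg = EncodingConfig(encoding="one_hot")
        s = single_atom_complex((0.0, 0.0, 0.0))
        g = encode_one_hot(s, (0.0, 0.0, 0.0), cfg)
        # chain A carbon occupies channel 0; chain B carbon channel 4
        assert g.values[..., 0].sum() == 1.0
        assert g.values[32, 32, 32, 0] == 1.0

    def test_out_of_box_atom_ignored(self):
        cfg = EncodingConfig(encoding="one_hot")
        s = make_complex([ca(1, (40.0, 0.0, 0.0))], [ca(1, (45.0, 0.0, 0.0))])
        g = encode_one_hot(s, (0.0, 0.0, 0.0), cfg)
        assert g.values.sum() == 0.0

    def test_atom_count_preserved(self):
        cfg = EncodingConfig(encoding="one_hot")
        coords_a = [(0.2, 0.2, 0.2), (3.1, 0.0, 0.0), (0.0, 5.4, 0.0)]
        coords_b = [(10.0, 0.0, 0.0), (0.0, -7.3, 0.0), (-4.0, 2.0, 1.0),
                    (6.6, 6.6, 6.6)]
        s = make_complex([ca(i + 1, c) for i, c in enumerate(coords_a)],
                         [ca(i + 1, c) for i, c in enumerate(coords_b)])
        g = encode_one_hot(s, (0.0, 0.0, 0.0), cfg)
        assert g.values.sum() == 7.0

    def test_values_binary(self, small_fixture_complex):
        cfg = EncodingConfig(encoding="one_hot")
        g = render(small_fixture_complex, cfg)
        assert set(np.unique(g.values)) <= {0.0, 1.0}

    def test_same_cell_collision_saturates(self):
        cfg = EncodingConfig(encoding="one_hot")
        s = make_complex([ca(1, (0.1, 0.1, 0.1)), ca(2, (0.3, 0.3, 0.3))],
                         [ca(1, (10.0, 0.0, 0.0))])
        g = encode_one_hot(s, (0.0, 0.0, 0.0), cfg)
        assert g.values[..., 0].max() == 1.0
        assert g.values[..., 0].sum() == 1.0


class TestVolume:
    def test_channel_sum_conserves_sphere_volume(self):
        cfg = EncodingConfig(encoding="volume")
        s = single_atom_complex((0.37, 0.21, -0.43))
        g = encode_volume(s, (0.0, 0.0, 0.0), cfg)
        assert g.values[..., 0].sum() == pytest.approx(SPHERE(0.70),
                                                       rel=1e-5)

    def test_corner_atom_eightfold_symmetry(self):
        cfg = EncodingConfig(encoding="volume")
        # center chosen so the atom sits exactly on a cell corner
        s = single_atom_complex((0.0, 0.0, 0.0))
        g = encode_volume(s, (0.0, 0.0, 0.0), cfg)
        nz = g.values[..., 0][g.values[..., 0] > 0]
        assert len(nz) == 8
        assert np.allclose(nz, nz[0], rtol=1e-6)

    def test_values_bounded_by_cell_volume(self, small_fixture_complex):
        cfg = EncodingConfig(encoding="volume")
        g = render(small_fixture_complex, cfg)
        assert g.values.min() >= 0.0
        # overlapping same-channel spheres may sum, but a single sulfur
        # sphere cannot fill more than the 1 A^3 cell
        assert g.values.max() <= 2.0

    def test_sulfur_uses_larger_radius(self):
        cfg = EncodingConfig(encoding="volume")
        s = make_complex([("S", 1, (0.5, 0.5, 0.5), 90.0, False),
                          ca(2, (5.5, 0.5, 0.5))],
                         [ca(1, (10.0, 0.0, 0.0))])
        g = encode_volume(s, (0.0, 0.0, 0.0), cfg)
        assert g.values[..., 3].sum() == pytest.approx(SPHERE(1.00), rel=1e-5)
        assert g.values[..., 0].sum() == pytest.approx(SPHERE(0.70), rel=1e-5)


class TestDistance:
    def test_single_atom_distances(self):
        cfg = EncodingConfig(encoding="distance")
        s = single_atom_complex((0.5, 0.5, 0.5))  # a cell center
        g = encode_distance(s, (0.0, 0.0, 0.0), cfg)
        i = int(np.floor(0.5 - g.origin[0]))
        assert g.values[i, i, i, 0] == pytest.approx(1e-3)
        assert g.values[i + 5, i, i, 0] == pytest.approx(5.0)
        assert g.values[i + 13, i, i, 0] == 0.0

    def test_nearest_atom_wins(self):
        cfg = EncodingConfig(encoding="distance")
        s = make_complex([ca(1, (4.5, 0.5, 0.5)), ca(2, (-9.5, 0.5, 0.5))],
                         [ca(1, (0.5, 30.0, 0.5))])
        g = encode_distance(s, (0.0, 0.0, 0.0), cfg)
        i = int(np.floor(0.5 - g.origin[0]))
        # cell at (0.5, 0.5, 0.5): 4 A from atom 1, 10 A from atom 2
        assert g.values[i, i, i, 0] == pytest.approx(4.0)

    def test_channels_filled_independently(self):
        cfg = EncodingConfig(encoding="distance")
        s = make_complex([("N", 1, (3.5, 0.5, 0.5), 90.0, False),
                          ("O", 1, (-2.5, 0.5, 0.5), 90.0, False),
                          ca(2, (0.5, 20.5, 0.5))],
                         [ca(1, (0.5, -30.0, 0.5))])
        g = encode_distance(s, (0.0, 0.0, 0.0), cfg)
        i = int(np.floor(0.5 - g.origin[0]))
        assert g.values[i, i, i, 1] == pytest.approx(3.0)  # N channel
        assert g.values[i, i, i, 2] == pytest.approx(3.0)  # O channel

    def test_values_capped(self, small_fixture_complex):
        cfg = EncodingConfig(encoding="distance")
        g = render(small_fixture_complex, cfg)
        assert g.values.max() <= 12.0
        assert g.values.min() >= 0.0


class TestRender:
    def test_translation_invariance(self, small_fixture_complex):
        cfg = EncodingConfig(encoding="one_hot")
        g1 = render(small_fixture_complex, cfg)
        g2 = render(small_fixture_complex.translate((100.0, 100.0, 100.0)),
                    cfg)
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_encodings_mark_same_atom_cells(self, small_fixture_complex):
        cfg_oh = EncodingConfig(encoding="one_hot")
        cfg_d = EncodingConfig(encoding="distance")
        center = compute_interface(small_fixture_complex).center
        g_oh = encode_one_hot(small_fixture_complex, center, cfg_oh)
        g_d = encode_distance(small_fixture_complex, center, cfg_d)
        occupied = g_oh.values > 0
        assert np.all(g_d.values[occupied] > 0)

    def test_grid_save_load_roundtrip(self, tmp_path, small_fixture_complex):
        cfg = EncodingConfig(encoding="distance", grid_side=16)
        g = render(small_fixture_complex, cfg)
        path = tmp_path / "grid.npz"
        g.save(path)
        g2 = VoxelGrid.load(path)
        np.testing.assert_array_equal(g.values, g2.values)
        assert g2.encoding == "distance"
        np.testing.assert_allclose(g2.center, g.center)
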
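"""Slice geometry, map summaries, co-stimulation bias, depth split."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from synaptomap import map_analysis as ma
from synaptomap import synthgen


def axis_aligned_scene():
    rng = np.random.default_rng(0)
    surface = np.column_stack([rng.uniform(0, 400, 20),
                               rng.uniform(0, 400, 20),
                               np.zeros(20)])
    dorsal = np.array([200.0, 400.0, 0.0])
    ventral = np.array([200.0, 0.0, 0.0])
    return surface, dorsal, ventral


class TestCoordinateTransform:
    def test_axis_aligned_depth(self):
        surface, dorsal, ventral = axis_aligned_scene()
        coords = ma.slice_coordinate_transform(
            surface, dorsal, ventral, np.array([[200.0, 200.0, -50.0]]))
        assert coords.ap_um.iloc[0] == pytest.approx(50.0, abs=1e-9)

    def test_rigid_rotation_leaves_coordinates_unchanged(self):
        surface, dorsal, ventral = axis_aligned_scene()
        cells = np.array([[100.0, 150.0, -30.0], [250.0, 300.0, -80.0]])
        a = ma.slice_coordinate_transform(surface, dorsal, ventral, cells)
        rot = Rotation.from_euler("xyz", [17.0, -32.0, 64.0], degrees=True)
        shift = np.array([120.0, -40.0, 300.0])
        b = ma.slice_coordinate_transform(
            rot.apply(surface) + shift, rot.apply(dorsal) + shift,
            rot.apply(ventral) + shift, rot.apply(cells) + shift)
        np.testing.assert_allclose(np.abs(a.to_numpy()),
                                   np.abs(b.to_numpy()), atol=1e-6)

    def test_tilted_surface_uses_normal_distance_not_z(self):
        theta = np.deg2rad(11.2)  # typical tilt of a held slice surface
        rng = np.random.default_rng(1)
        xy = np.column_stack([rng.uniform(0, 400, 20),
                              rng.uniform(0, 400, 20)])
        surface = np.column_stack([xy, xy[:, 0] * np.tan(theta)])
        dorsal = np.array([0.0, 400.0, 0.0])
        ventral = np.array([0.0, 0.0, 0.0])
        # cell 50 um below the tilted plane along its normal
        n = np.array([-np.sin(theta), 0.0, np.cos(theta)])
        base = np.array([200.0, 200.0, 200.0 * np.tan(theta)])
        cell = base - 50.0 * n
        coords = ma.slice_coordinate_transform(surface, dorsal, ventral,
                                               cell[None, :])
        assert coords.ap_um.iloc[0] == pytest.approx(50.0, abs=1e-6)
        assert abs(coords.ap_um.iloc[0] - 50.0) < abs(
            (base[2] - cell[2]) - 50.0) + 1e-9

    def test_pairwise_distances_preserved(self):
        surface, dorsal, ventral = axis_aligned_scene()
        rng = np.random.default_rng(2)
        cells = rng.uniform(0, 400, (6, 3))
        coords = ma.slice_coordinate_transform(surface, dorsal, ventral,
                                               cells).to_numpy()
        d_in = np.linalg.norm(cells[:, None] - cells[None, :], axis=2)
        d_out = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d_in, d_out, atol=1e-6)

    def test_collinear_surface_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0),
                                np.zeros(5)])
        with pytest.raises(ValueError):
            ma.slice_coordinate_transform(line, np.zeros(3), np.ones(3),
                                          np.zeros((1, 3)))


def simple_map(strengths=(20.0, 0, 0, 0), connected=(1, 0, 0, 0),
               offsets=None):
    n = len(strengths)
    if offsets is None:
        offsets = np.column_stack([np.linspace(-100, 100, n),
                                   np.linspace(-50, 50, n), np.zeros(n)])
    return ma.ConnectivityMap(
        recorded_position_um=np.zeros(3), positions_um=offsets,
        responsive=np.ones(n, bool), connected=np.array(connected, bool),
        strengths_pa=np.array(strengths, float))


class TestMapSummaries:
    def test_probability_within_radius(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-150, 150, (10, 3))
        m = ma.ConnectivityMap(np.zeros(3), pos, np.ones(10, bool),
                               np.r_[np.ones(2), np.zeros(8)].astype(bool),
                               np.r_[10.0, 20.0, np.zeros(8)])
        s = ma.map_summaries(m, radius_um=300.0)
        assert s.probability == pytest.approx(0.2)

    def test_weighted_input_zero_fills_nonconnected(self):
        s = ma.map_summaries(simple_map())
        assert s.weighted_input_pa == pytest.approx(5.0)
        assert s.mean_strength_pa == pytest.approx(20.0)

    def test_directional_input_zero_on_empty_side(self):
        # single connected cell medial (negative ML): lateral side is zero
        s = ma.map_summaries(simple_map())
        assert s.directional_pa["ml_neg"] > 0
        assert s.directional_pa["ml_pos"] == 0.0

    def test_weighted_input_bounded_by_mean_strength(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            n = 12
            conn = rng.random(n) < 0.4
            if not conn.any():
                continue
            strengths = np.where(conn, rng.uniform(5, 30, n), 0.0)
            m = ma.ConnectivityMap(np.zeros(3),
                                   rng.uniform(-200, 200, (n, 3)),
                                   np.ones(n, bool), conn, strengths)
            s = ma.map_summaries(m)
            assert s.weighted_input_pa <= s.mean_strength_pa + 1e-9

    def test_equality_when_all_responsive_connected(self):
        m = simple_map(strengths=(10, 20, 30, 40), connected=(1, 1, 1, 1))
        s = ma.map_summaries(m)
        assert s.weighted_input_pa == pytest.approx(s.mean_strength_pa)

    def test_no_responsive_cells_rejected(self):
        m = simple_map()
        m.responsive[:] = False
        m.connected[:] = False
        with pytest.raises(ValueError):
            ma.map_summaries(m)


class TestCostimulationBias:
    def test_paper_fraction_gives_bias(self):
        assert ma.costim_bias_from_fraction(0.13) == pytest.approx(
            0.115, abs=5e-4)

    def test_isolated_cells_have_zero_bias(self):
        pos = np.array([[0, 0, 0], [500.0, 0, 0], [0, 500.0, 0]])
        stats = ma.costimulation_bias(pos)
        assert stats.fraction_with_neighbor == 0.0 and stats.bias == 0.0

    def test_full_cofraction_gives_half_bias(self):
        assert ma.costim_bias_from_fraction(1.0) == pytest.approx(0.5)

    def test_adjacent_pair_detected(self):
        pos = np.array([[0, 0, 0], [5.0, 0, 0], [400.0, 400, 200]])
        stats = ma.costimulation_bias(pos)
        assert stats.fraction_with_neighbor == pytest.approx(2 / 3)
        assert stats.mean_neighbors_given_any == 1.0

    def test_monotone_in_fwhm(self):
        vol = synthgen.simulate_cell_volume(8e4, seed=0).to_numpy()
        fracs = [ma.costimulation_bias(vol, fwhm_axial_um=a,
                                       fwhm_radial_um=r).fraction_with_neighbor
                 for a, r in ((30, 12), (55.9, 24.2), (110, 50))]
        assert fracs == sorted(fracs)

    def test_semi_axis_reading_is_wider(self):
        vol = synthgen.simulate_cell_volume(8e4, seed=1).to_numpy()
        narrow = ma.costimulation_bias(vol)
        wide = ma.costimulation_bias(vol, semi_axis_equals_fwhm=True)
        assert (wide.fraction_with_neighbor
                >= narrow.fraction_with_neighbor)


class TestDepthSplit:
    def _maps(self, p_above, p_below, n_maps=30, n_cells=40, seed=0):
        rng = np.random.default_rng(seed)
        maps = []
        for _ in range(n_maps):
            depth = rng.uniform(20, 120, n_cells)
            d0 = 70.0
            p = np.where(depth < d0, p_above, p_below)
            conn = rng.random(n_cells) < p
            pos = np.column_stack([rng.uniform(-200, 200, (n_cells, 2)),
                                   depth])
            maps.append(ma.ConnectivityMap(
                np.array([0, 0, d0]), pos, np.ones(n_cells, bool), conn,
                np.where(conn, rng.uniform(10, 25, n_cells), 0.0),
                recorded_depth_um=d0))
        return maps

    def test_uniform_connectivity_gives_unit_ratio(self):
        split = ma.depth_split_connectivity(self._maps(0.1, 0.1, seed=1))
        assert split.ratio_below_over_above == pytest.approx(1.0, abs=0.25)

    def test_planted_depth_effect_recovered(self):
        split = ma.depth_split_connectivity(
            self._maps(0.021, 0.021 * 1.77, n_maps=120, seed=2))
        se = 1.77 * np.sqrt(2 / (120 * 20 * 0.021 * 1.77))
        assert abs(split.ratio_below_over_above - 1.77) < 3 * se

    def test_identical_strength_distributions_match(self):
        split = ma.depth_split_connectivity(self._maps(0.2, 0.2, seed=3))
        assert split.strength_above_pa == pytest.approx(
            split.strength_below_pa, rel=0.1)


class TestAttenuation:
    @pytest.mark.parametrize("depth,expected", [
        (0.0, 1.0), (147.6, np.e)])
    def test_known_values(self, depth, expected):
        assert ma.attenuation_compensation(depth) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ma.attenuation_compensation(-1.0)
        with pytest.raises(ValueError):
            ma.attenuation_compensation(10.0, tau_um=0.0)
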
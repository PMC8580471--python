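import math

import numpy as np
import pytest

import fibrinbd as fb


def _chain_along(axis, n=8, r0=22.5e-9, box=3e-6):
    pos = np.zeros((1, n, 3))
    pos[0, :, axis] = np.arange(n) * r0
    return fb.FibreNetwork(positions=pos, box_lengths=[box] * 3)


class TestSegmentOrientation:
    def test_axis_aligned_cases(self):
        assert fb.segment_orientation(_chain_along(2)).fibre_means[0] == \
            pytest.approx(0.0)
        assert fb.segment_orientation(_chain_along(0)).fibre_means[0] == \
            pytest.approx(math.pi / 2)

    def test_folding_is_direction_agnostic(self):
        net = _chain_along(2)
        net.positions[..., 2] *= -1.0
        assert fb.segment_orientation(net).fibre_means[0] == pytest.approx(0.0)

    def test_angles_bounded_and_weights_sum_to_contour(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(scale=2e-8, size=(5, 10, 3)), axis=1)
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        stats = fb.segment_orientation(net)
        assert np.all(stats.segment_angles >= 0)
        assert np.all(stats.segment_angles <= math.pi / 2 + 1e-12)
        np.testing.assert_allclose(stats.segment_lengths.sum(axis=1),
                                   net.contour_lengths())

    def test_length_weighting(self):
        # one long z segment + one short x segment: mean pulled toward 0
        pos = np.array([[[0, 0, 0], [0, 0, 90e-9], [10e-9, 0, 90e-9]]])
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        mean = fb.segment_orientation(net).fibre_means[0]
        assert mean == pytest.approx((math.pi / 2) * 10 / 100)


class TestOrientationProbability:
    def test_all_z_mass_in_first_band(self):
        net = _chain_along(2)
        stats = fb.segment_orientation(net)
        dens = fb.orientation_probability(stats)
        assert dens[0] == pytest.approx(1.0 / (1 - math.cos(math.pi / 12)))
        assert np.all(dens[1:] == 0)

    def test_normalization_factor_first_band(self):
        # band area for [0, pi/12] is 1 - cos(pi/12) ~ 0.0341
        edges = np.linspace(0, math.pi / 2, 7)
        assert 1 - math.cos(edges[1]) == pytest.approx(0.03407, rel=1e-3)

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(scale=2e-8, size=(40, 8, 3)), axis=1)
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        stats = fb.segment_orientation(net)
        edges = np.linspace(0, math.pi / 2, 7)
        dens = fb.orientation_probability(stats, edges)
        areas = np.cos(edges[:-1]) - np.cos(edges[1:])
        assert (dens * areas).sum() == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_axes_give_flat_density(self):
        """Uniform-on-sphere straight rods: equal density across bands within
        CLT error."""
        rng = np.random.default_rng(7)
        axes = rng.normal(size=(4000, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        pos = np.arange(4)[None, :, None] * 22.5e-9 * axes[:, None, :]
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        stats = fb.segment_orientation(net)
        dens = fb.orientation_probability(stats)
        # each band's count ~ Binomial(N, area); 4 sigma band on the density
        areas = np.cos(np.linspace(0, math.pi / 2, 7))[:-1] \
            - np.cos(np.linspace(0, math.pi / 2, 7))[1:]
        for d, a in zip(dens, areas):
            se = math.sqrt(a * (1 - a) / 4000) / a
            assert abs(d - 1.0) < 4 * se

    def test_empty_network_rejected(self):
        stats = fb.OrientationStats(np.empty((0, 0)), np.empty((0, 0)),
                                    np.empty(0), float("nan"))
        with pytest.raises(ValueError):
            fb.orientation_probability(stats)

    def test_z_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.normal(scale=2e-8, size=(10, 6, 3)), axis=1)
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        c, s = math.cos(1.1), math.sin(1.1)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rot = net.copy()
        rot.positions = pos @ R.T
        np.testing.assert_allclose(
            fb.segment_orientation(net).fibre_means,
            fb.segment_orientation(rot).fibre_means, rtol=1e-10)


class TestTortuosity:
    def test_straight_fibre_is_one(self):
        assert fb.tortuosity(_chain_along(1))[0] == pytest.approx(1.0)

    def test_right_angle_path(self):
        # two equal legs at a right angle: L/L0 = 2 / sqrt(2) = sqrt(2)
        pos = np.array([[[0, 0, 0], [1e-7, 0, 0], [1e-7, 1e-7, 0]]])
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        assert fb.tortuosity(net)[0] == pytest.approx(math.sqrt(2))

    def test_coincident_endpoints_flagged(self):
        pos = np.array([[[0, 0, 0], [1e-7, 0, 0], [0, 0, 0]]])
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        with pytest.warns(UserWarning):
            t = fb.tortuosity(net)
        assert np.isnan(t[0])

    def test_invariant_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(scale=2e-8, size=(6, 8, 3)), axis=1)
        net = fb.FibreNetwork(positions=pos, box_lengths=[3e-6] * 3)
        t0 = fb.tortuosity(net)
        c, s = math.cos(0.4), math.sin(0.4)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        moved = net.copy()
        moved.positions = 2.5 * (pos @ R.T) + 1e-7
        np.testing.assert_allclose(fb.tortuosity(moved), t0, rtol=1e-12)


class TestStretchedFraction:
    def test_reference_state_is_zero(self, params):
        net = _chain_along(2)
        net.freeze_reference(fb.nearest_partner_pairs(net, params))
        assert fb.stretched_fraction(net) == 0.0

    def test_uniform_extension_is_one(self, params):
        net = _chain_along(2)
        net.freeze_reference(fb.nearest_partner_pairs(net, params))
        net.positions *= 1.10
        assert fb.stretched_fraction(net) == 1.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            fb.stretched_fraction(_chain_along(2))


class TestPercolation:
    def _pairs(self, net, params):
        return fb.nearest_partner_pairs(net, params)

    def test_isolated_fibres_do_not_percolate(self, params):
        spec = fb.InitialConditionSpec(box=(2e-6,) * 3, n_fibres=4, seed=0)
        net = fb.random_straight_fibres(spec, params)
        pairs = self._pairs(net, params)
        assert not fb.percolation_axes(net, pairs).any()

    def test_z_wrapping_chain_percolates_only_in_z(self, params):
        """Two fibres bonded into a column that closes on its own periodic
        image through the z boundary."""
        r0 = params.r0_S
        L = 8 * r0  # box height equals two 4-node fibres end to end
        f0 = [[0, 0, k * r0] for k in range(4)]
        f1 = [[10e-9, 0, (k + 4) * r0] for k in range(4)]
        net = fb.FibreNetwork(positions=np.array([f0, f1]),
                              box_lengths=[1e-6, 1e-6, L])
        # bottom of fibre 0 <-> top of fibre 1 only touch across the boundary
        pairs = fb.find_pairs(net, params.a_th)
        w = fb.percolation_axes(net, pairs)
        assert bool(w[2]) and not w[0] and not w[1]

    def test_bonded_pair_without_winding(self, toys, params):
        net = toys["parallel_pair_16nm"]
        pairs = fb.find_pairs(net, params.a_th)
        assert not fb.percolation_axes(net, pairs).any()


class TestBondSurvival:
    def test_no_motion_is_full_survival(self, toys, params):
        net = toys["parallel_pair_16nm"].copy()
        ref = fb.nearest_partner_pairs(net, params)
        assert fb.bond_survival(net, ref, params.a_th) == 1.0

    def test_forced_separation_is_zero(self, toys, params):
        net = toys["parallel_pair_16nm"].copy()
        ref = fb.nearest_partner_pairs(net, params)
        net.positions[1, :, 1] += 60e-9  # all pairs beyond 45 nm
        assert fb.bond_survival(net, ref, params.a_th) == 0.0

    def test_partial_separation(self, toys, params):
        net = toys["parallel_pair_16nm"].copy()
        ref = fb.nearest_partner_pairs(net, params)
        net.positions[1, :11, 1] += 60e-9  # break 11 of 22 rungs
        assert fb.bond_survival(net, ref, params.a_th) == pytest.approx(0.5)

    def test_empty_reference_flagged(self, params):
        net = _chain_along(2)
        ref = fb.nearest_partner_pairs(net, params)  # single fibre: empty
        with pytest.warns(UserWarning):
            v = fb.bond_survival(net, ref, params.a_th)
        assert math.isnan(v)
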
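import math

import numpy as np
import pytest

import fibrinbd as fb

from conftest import (assert_forces_match, finite_difference_forces,
                       random_bent_chain)


class TestHandValues:
    """Closed-form energies of the deterministic toy configurations."""

    def test_rest_fibre_is_global_minimum(self, toys, params):
        ff = fb.total_field(toys["rest_fibre"], params)
        assert ff.energy.W_total == pytest.approx(0.0, abs=1e-30)
        # force scale of the stiffest term is ~kS*r0 ~ 1e-10 N; residues from
        # the clamped arccos at exact collinearity are < 1e-22 N
        np.testing.assert_allclose(ff.forces, 0.0, atol=1e-22)

    def test_strained_bond_energy(self, toys, params):
        # 10% over rest length: 1/2 * 0.01 * (2.25 nm)^2 = 2.53e-20 J
        w = fb.stretch_term(toys["strained_bond"], params).energy.W_S
        assert w == pytest.approx(0.5 * 0.01 * (2.25e-9) ** 2, rel=1e-12)

    def test_rest_length_bond_is_force_free(self, params):
        net = fb.FibreNetwork(
            positions=[[[0, 0, 0], [22.5e-9, 0, 0]]], box_lengths=[3e-6] * 3)
        ff = fb.stretch_term(net, params)
        assert ff.energy.W_S == 0.0
        np.testing.assert_allclose(ff.forces, 0.0)

    def test_right_angle_bend_energy(self, toys, params):
        # 1/2 * 1e-18 * (pi/2)^2 = 1.23e-18 J
        w = fb.bending_term(toys["right_angle_triple"], params).energy.W_B
        assert w == pytest.approx(0.5 * 1e-18 * (math.pi / 2) ** 2, rel=1e-12)

    def test_straight_chain_bend_free(self, toys, params):
        ff = fb.bending_term(toys["rest_fibre"], params)
        assert ff.energy.W_B == pytest.approx(0.0, abs=1e-30)
        np.testing.assert_allclose(ff.forces, 0.0, atol=1e-22)

    def test_right_angle_dihedral_energy(self, toys, params):
        w = fb.torsion_term(toys["dihedral_quad"], params).energy.W_T
        assert w == pytest.approx(0.5 * params.k_T * (math.pi / 2) ** 2,
                                  rel=1e-9)

    def test_planar_quadruple_at_reference(self, params):
        # cis-planar quadruple: both plane normals parallel -> phi = 0
        r0 = params.r0_S
        net = fb.FibreNetwork(
            positions=[[[r0, 0, 0], [0, 0, 0], [0, r0, 0], [r0, 2 * r0, 0]]],
            box_lengths=[3e-6] * 3)
        assert fb.torsion_term(net, params).energy.W_T == pytest.approx(
            0.0, abs=1e-40)

    def test_mirror_image_flips_dihedral_sign(self, toys):
        net = toys["dihedral_quad"]
        mirror = net.copy()
        mirror.positions[..., 1] *= -1.0
        phi = fb.dihedral_angles(net)[0, 0]
        phi_m = fb.dihedral_angles(mirror)[0, 0]
        assert phi == pytest.approx(-phi_m)
        assert abs(phi) == pytest.approx(math.pi / 2, rel=1e-9)

    def test_aggregation_pair_hand_value(self, params):
        # pair at 20 nm, kA = 2e-3: 1/2 * 2e-3 * (4 nm)^2 = 1.6e-20 J
        net = _two_node_fibres(20e-9, params)
        pairs = fb.find_pairs(net, params.a_th)
        w = fb.aggregation_term(net, pairs, params).energy.W_A
        assert w == pytest.approx(0.5 * 2e-3 * (4e-9) ** 2, rel=1e-12)

    def test_pair_at_rest_separation_force_free(self, toys, params):
        net = toys["parallel_pair_16nm"]
        bonds = fb.nearest_partner_pairs(net, params)
        agg = fb.aggregation_term(net, bonds, params)
        rep = fb.repulsive_term(net, fb.find_pairs(net, params.a_th), params)
        # the 22 opposing bonds sit exactly at r0A; nothing is inside r0R
        assert agg.energy.W_A + rep.energy.W_R == pytest.approx(0.0, abs=1e-40)

    def test_repulsion_pushes_overlap_apart(self, params):
        net = _two_node_fibres(10e-9, params)
        pairs = fb.find_pairs(net, params.a_th)
        ff = fb.repulsive_term(net, pairs, params)
        # separation axis is y; forces must increase the separation
        assert ff.forces[0, 0, 1] < 0 < ff.forces[1, 0, 1]

    def test_aggregation_attracts_beyond_rest(self, params):
        net = _two_node_fibres(30e-9, params)
        # single explicit pair: flat node 0 = (fibre 0, node 0),
        # flat node 2 = (fibre 1, node 0), separated 30 nm along y
        pair = fb.AggregationPairSet(np.array([0]), np.array([2]),
                                     np.array([30e-9]), 2)
        ff = fb.aggregation_term(net, pair, params)
        # attraction beyond the rest length, equal and opposite per pair
        assert ff.forces[0, 0, 1] > 0 > ff.forces[1, 0, 1]
        np.testing.assert_allclose(ff.forces[0, 0], -ff.forces[1, 0],
                                   rtol=1e-12)
        np.testing.assert_allclose(ff.forces[0, 1], 0.0)
        np.testing.assert_allclose(ff.forces[1, 1], 0.0)


def _two_node_fibres(sep, params):
    """Two short parallel fibres separated by ``sep`` along y."""
    r0 = params.r0_S
    return fb.FibreNetwork(
        positions=[[[0, 0, 0], [r0, 0, 0]], [[0, sep, 0], [r0, sep, 0]]],
        box_lengths=[3e-6] * 3)


class TestGradientOracle:
    """Analytic forces vs central finite differences (h = 1e-12 m)."""

    @pytest.mark.parametrize("term", [fb.stretch_term, fb.bending_term,
                                      fb.torsion_term])
    def test_chain_terms(self, term, params):
        rng = np.random.default_rng(42)
        for _ in range(30):
            net = random_bent_chain(rng, n_nodes=6)
            ff = term(net, params)
            fd = finite_difference_forces(term, net, params)
            assert_forces_match(ff.forces, fd)

    @pytest.mark.parametrize("which", ["aggregation", "repulsive"])
    def test_pair_terms(self, which, params):
        rng = np.random.default_rng(7)
        for _ in range(30):
            sep = rng.uniform(8e-9, 40e-9)
            net = _two_node_fibres(sep, params)
            net.positions += rng.normal(scale=2e-9, size=net.positions.shape)
            pairs = fb.find_pairs(net, params.a_th)
            if not len(pairs):
                continue
            d = net.pair_distances(pairs)
            # keep clear of the cutoff discontinuities of the piecewise terms
            if np.any(np.abs(d - params.a_th) < 1e-10) or \
               np.any(np.abs(d - params.r0_R) < 1e-10):
                continue
            term = (fb.aggregation_term if which == "aggregation"
                    else fb.repulsive_term)

            def fixed_pairs_term(n, p, _pairs=pairs, _t=term):
                return _t(n, _pairs, p)

            ff = fixed_pairs_term(net, params)
            fd = finite_difference_forces(fixed_pairs_term, net, params)
            assert_forces_match(ff.forces, fd)

    def test_zero_separation_rejected(self, params):
        net = _two_node_fibres(16e-9, params)
        net.positions[1] = net.positions[0]
        pairs = fb.AggregationPairSet(
            np.array([0]), np.array([2]), np.array([0.0]), 2)
        with pytest.raises(ValueError):
            fb.aggregation_term(net, pairs, params)

    def test_coincident_bonded_nodes_rejected(self, params):
        net = fb.FibreNetwork(positions=[[[0, 0, 0], [0, 0, 0]]],
                              box_lengths=[3e-6] * 3)
        with pytest.raises(ValueError):
            fb.stretch_term(net, params)


class TestTotalField:
    def test_additivity_and_translation_invariance(self, params):
        rng = np.random.default_rng(3)
        net = random_bent_chain(rng, n_nodes=8, n_fibres=3, box=1e-6)
        p_all = params.with_(aggregation_mode="all")
        ff = fb.total_field(net, p_all)
        pairs = fb.find_pairs(net, p_all.a_th)
        parts = (fb.stretch_term(net, p_all).energy.W_S
                 + fb.bending_term(net, p_all).energy.W_B
                 + fb.torsion_term(net, p_all).energy.W_T
                 + fb.aggregation_term(net, pairs, p_all).energy.W_A
                 + fb.repulsive_term(net, pairs, p_all).energy.W_R)
        assert ff.energy.W_total == pytest.approx(parts, rel=1e-12)
        # internal forces sum to zero over all nodes
        net_force = ff.forces.sum(axis=(0, 1))
        assert np.all(np.abs(net_force) < 1e-20)

    def test_energies_invariant_under_rigid_motion(self, params):
        rng = np.random.default_rng(5)
        net = random_bent_chain(rng, n_nodes=8, n_fibres=2, box=1e-6)
        w0 = fb.total_field(net, params).energy.W_total
        # rotation about z applied before periodic wrapping, then a shift
        c, s = math.cos(0.7), math.sin(0.7)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rot = net.copy()
        rot.positions = net.positions @ R.T + np.array([1e-7, -2e-7, 5e-8])
        w1 = fb.total_field(rot, params).energy.W_total
        assert w1 == pytest.approx(w0, rel=1e-10)


class TestPairSearch:
    def test_two_parallel_fibres_all_opposing_pairs(self, toys, params):
        pairs = fb.find_pairs(toys["parallel_pair_16nm"], 45e-9)
        # 22 opposing pairs at 16 nm, plus diagonal pairs at ~27.6/39.6 nm
        d = pairs.distances
        assert np.isclose(d, 16e-9).sum() == 22
        assert np.all(d < 45e-9)

    def test_threshold_is_exclusive(self, params):
        net = _two_node_fibres(46e-9, params)
        assert len(fb.find_pairs(net, 45e-9)) == 0
        net = _two_node_fibres(44e-9, params)
        assert len(fb.find_pairs(net, 45e-9)) == 2

    def test_same_fibre_nodes_never_paired(self, params):
        # tightly coiled single fibre: nodes close, but no pairs
        rng = np.random.default_rng(0)
        net = random_bent_chain(rng, n_nodes=12, jitter=2e-9, step=5e-9)
        assert len(fb.find_pairs(net, params.a_th)) == 0

    def test_cutoff_beyond_half_box_rejected(self, toys):
        small = toys["parallel_pair_16nm"].copy()
        small.box_lengths = np.array([80e-9, 80e-9, 80e-9])
        with pytest.raises(ValueError):
            fb.find_pairs(small, 45e-9)

    def test_cell_list_equals_brute_force(self, params):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n_f = rng.integers(3, 8)
            pos = rng.random((n_f, 5, 3)) * 0.4e-6
            net = fb.FibreNetwork(positions=pos, box_lengths=[0.4e-6] * 3)
            a = fb.find_pairs(net, 45e-9, method="cell")
            b = fb.find_pairs(net, 45e-9, method="brute")
            sa = {(int(i), int(j)) for i, j in zip(a.node_i, a.node_j)}
            sb = {(int(i), int(j)) for i, j in zip(b.node_i, b.node_j)}
            assert sa == sb

    def test_cell_list_equals_brute_force_large(self, params):
        # large enough to exercise the true cell path (>= 3 cells per axis)
        rng = np.random.default_rng(13)
        pos = rng.random((40, 8, 3)) * 1.0e-6
        net = fb.FibreNetwork(positions=pos, box_lengths=[1.0e-6] * 3)
        a = fb.find_pairs(net, 45e-9, method="cell")
        b = fb.find_pairs(net, 45e-9, method="brute")
        sa = {(int(i), int(j)) for i, j in zip(a.node_i, a.node_j)}
        sb = {(int(i), int(j)) for i, j in zip(b.node_i, b.node_j)}
        assert sa == sb and len(sa) > 0


class TestNearestPartnerRule:
    def test_mutual_nearest_matching_zips_parallel_pair(self, toys, params):
        pairs = fb.nearest_partner_pairs(toys["parallel_pair_16nm"], params)
        assert len(pairs) == 22  # one rung per opposing node pair
        np.testing.assert_allclose(pairs.distances, 16e-9)

    def test_bond_multiplicity_bounded(self, params):
        rng = np.random.default_rng(2)
        net = random_bent_chain(rng, n_nodes=8, n_fibres=8, box=0.2e-6)
        pairs = fb.nearest_partner_pairs(net, params)
        assert len(pairs) > 0
        idx, counts = np.unique(
            np.concatenate([pairs.node_i, pairs.node_j]), return_counts=True)
        assert counts.max() <= 1  # instantaneous matching: one bond per node
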
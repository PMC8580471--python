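"""Energies and analytic forces of the five potential terms.

Each ``*_term`` function returns a :class:`ForceField` holding per-node forces
(newtons) and the corresponding :class:`EnergyBreakdown` component.  The
analytic gradients (derived by chain rule for the angular terms) are certified
against a central finite-difference oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .network import AggregationPairSet, FibreNetwork
from .params import EnergyBreakdown, ModelParameters, minimum_image


@dataclass
class ForceField:
    forces: np.ndarray  # (n_fibres, nodes_per_fibre, 3), newtons
    energy: EnergyBreakdown


def _check_bonds(network: FibreNetwork):
    if np.any(network.segment_lengths() <= 0.0):
        raise ValueError("coincident bonded nodes: bond direction undefined")


def stretch_term(network: FibreNetwork, params: ModelParameters) -> ForceField:
    """W^S = sum 1/2 k^S (|r_ij| - r0^S)^2 over bonded neighbours."""
    _check_bonds(network)
    F = np.zeros_like(network.flat_positions)
    W = _k.stretch_forces(network.flat_positions, network.nodes_per_fibre,
                          params.k_S, params.r0_S, F)
    return ForceField(F.reshape(network.positions.shape), EnergyBreakdown(W_S=W))


def bending_term(network: FibreNetwork, params: ModelParameters) -> ForceField:
    """W^B = sum 1/2 k^B (theta_ijk - theta0)^2 over interior nodes."""
    _check_bonds(network)
    F = np.zeros_like(network.flat_positions)
    W = _k.bend_forces(network.flat_positions, network.nodes_per_fibre,
                       params.k_B, params.theta0, F)
    return ForceField(F.reshape(network.positions.shape), EnergyBreakdown(W_B=W))


def torsion_term(network: FibreNetwork, params: ModelParameters) -> ForceField:
    """W^T = sum 1/2 k^T phi^2 over consecutive node quadruples."""
    _check_bonds(network)
    F = np.zeros_like(network.flat_positions)
    W = _k.torsion_forces(network.flat_positions, network.nodes_per_fibre,
                          params.k_T, F)
    return ForceField(F.reshape(network.positions.shape), EnergyBreakdown(W_T=W))


def dihedral_angles(network: FibreNetwork) -> np.ndarray:
    """Signed dihedral phi in (-pi, pi] per quadruple, sign from
    sgn{r_jk . (m x n)}; NaN where a triple is collinear."""
    p = network.positions
    a = p[:, :-3] - p[:, 1:-2]   # r_ij
    b = p[:, 2:-1] - p[:, 1:-2]  # r_ik
    q = p[:, 3:] - p[:, 2:-1]    # r_kl
    m = np.cross(a, b)
    n = np.cross(-b, q)
    nm = np.linalg.norm(m, axis=-1)
    nn = np.linalg.norm(n, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.clip((m * n).sum(-1) / (nm * nn), -1.0, 1.0)
        phi = np.arccos(h)
    rjk = p[:, 2:-1] - p[:, :-3]
    sign = np.sign((rjk * np.cross(m, n)).sum(-1))
    sign[sign == 0] = 1.0
    phi = sign * phi
    # collinear triples: normals vanish relative to the segment-length scale
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    nq = np.linalg.norm(q, axis=-1)
    phi[(nm < 1e-6 * na * nb) | (nn < 1e-6 * nb * nq)] = np.nan
    return phi


def find_pairs(network: FibreNetwork, cutoff: float,
               method: str = "cell") -> AggregationPairSet:
    """All unordered inter-fibre node pairs with minimum-image distance below
    ``cutoff``.  ``method`` is "cell" (cell list, production) or "brute"
    (exhaustive O(N^2) reference)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > float(np.min(network.box_lengths)) / 2.0:
        raise ValueError("cutoff exceeds half the smallest box length "
                         "(minimum image ambiguous)")
    fn = _k.cell_list_pairs if method == "cell" else _k.brute_force_pairs
    pi, pj = fn(network.flat_positions, network.nodes_per_fibre,
                network.box_lengths, cutoff)
    p = network.flat_positions
    d = np.linalg.norm(minimum_image(p[pj] - p[pi], network.box_lengths), axis=-1) \
        if pi.size else np.empty(0)
    return AggregationPairSet(pi, pj, d, network.nodes_per_fibre)


def nearest_partner_pairs(network: FibreNetwork,
                          params: ModelParameters) -> AggregationPairSet:
    """Mutual-nearest matching of free nodes: the bond-formation rule.

    Each node selects its nearest foreign node within a_th; a pair binds when
    the selection is mutual.  This is the instantaneous matching applied to a
    network without persistent bond state; during a simulation the persistent
    ``bond_partner`` state (which this rule seeds and dissociation prunes)
    is authoritative.
    """
    cand = find_pairs(network, params.a_th)
    best_j, _ = _k.nearest_partner_select(network.flat_positions,
                                          cand.node_i, cand.node_j,
                                          network.box_lengths, params.a_th)
    ii, jj = [], []
    for i, j in enumerate(best_j):
        if j > i and best_j[j] == i:
            ii.append(i)
            jj.append(int(j))
    ii = np.asarray(ii, dtype=np.int64)
    jj = np.asarray(jj, dtype=np.int64)
    p = network.flat_positions
    d = (np.linalg.norm(minimum_image(p[jj] - p[ii], network.box_lengths), axis=-1)
         if ii.size else np.empty(0))
    return AggregationPairSet(ii, jj, d, network.nodes_per_fibre)


def active_pairs(network: FibreNetwork,
                 params: ModelParameters) -> AggregationPairSet:
    """Aggregation pair set the simulation applies under the current mode."""
    if params.aggregation_mode == "nearest":
        if network.bond_partner is not None:
            return network.bonded_pairs()
        return nearest_partner_pairs(network, params)
    return find_pairs(network, params.a_th)


def _pair_field(network, pairs, kA, r0A, a_th, kR, r0R):
    p = network.flat_positions
    if pairs.node_i.size:
        d = network.pair_distances(pairs)
        if np.any(d <= 0.0):
            raise ValueError("zero pair separation: force direction undefined")
    F = np.zeros_like(p)
    WA, WR = _k.pair_forces(p, pairs.node_i, pairs.node_j, network.box_lengths,
                            kA, r0A, a_th, kR, r0R, F)
    return F.reshape(network.positions.shape), WA, WR


def aggregation_term(network: FibreNetwork, pairs: AggregationPairSet,
                     params: ModelParameters) -> ForceField:
    """Harmonic attraction about r0^A = 2a for pairs within a_th."""
    F, WA, _ = _pair_field(network, pairs, params.k_A, params.r0_A,
                           params.a_th, 0.0, params.r0_R)
    return ForceField(F, EnergyBreakdown(W_A=WA))


def repulsive_term(network: FibreNetwork, pairs: AggregationPairSet,
                   params: ModelParameters) -> ForceField:
    """Linear repulsion active only below the fibrinogen diameter 2a."""
    F, _, WR = _pair_field(network, pairs, 0.0, params.r0_A,
                           params.a_th, params.k_R, params.r0_R)
    return ForceField(F, EnergyBreakdown(W_R=WR))


def total_field(network: FibreNetwork, params: ModelParameters,
                pairs: AggregationPairSet | None = None) -> ForceField:
    """Sum of all five contributions.

    ``pairs`` overrides the aggregation pair set (both cutoffs re-applied per
    pair, as in the integrator); by default it follows
    ``params.aggregation_mode``.  Repulsion always acts on every inter-fibre
    pair inside r0_R.
    """
    _check_bonds(network)
    p = network.flat_positions
    npf = network.nodes_per_fibre
    F = np.zeros_like(p)
    WS = _k.stretch_forces(p, npf, params.k_S, params.r0_S, F)
    WB = _k.bend_forces(p, npf, params.k_B, params.theta0, F)
    WT = _k.torsion_forces(p, npf, params.k_T, F)
    if pairs is None and params.aggregation_mode == "nearest":
        apairs = active_pairs(network, params)
        WA, _ = _k.pair_forces(p, apairs.node_i, apairs.node_j,
                               network.box_lengths, params.k_A, params.r0_A,
                               params.a_th, 0.0, params.r0_R, F)
        rpairs = find_pairs(network, params.a_th)
        _, WR = _k.pair_forces(p, rpairs.node_i, rpairs.node_j,
                               network.box_lengths, 0.0, params.r0_A,
                               params.a_th, params.k_R, params.r0_R, F)
    else:
        if pairs is None:
            pairs = find_pairs(network, params.a_th)
        WA, WR = _k.pair_forces(p, pairs.node_i, pairs.node_j,
                                network.box_lengths, params.k_A, params.r0_A,
                                params.a_th, params.k_R, params.r0_R, F)
    return ForceField(F.reshape(network.positions.shape),
                      EnergyBreakdown(W_S=WS, W_B=WB, W_T=WT, W_A=WA, W_R=WR))
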
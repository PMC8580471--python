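"""Conformation observables: orientation statistics, tortuosity,
stretched-fibre fraction and aggregation-bond survival."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .network import AggregationPairSet, FibreNetwork
from .params import minimum_image


@dataclass
class OrientationStats:
    """Segment angles against the z axis, folded into [0, pi/2].

    ``segment_angles`` is (n_fibres, n_segments); ``fibre_means`` the
    length-weighted per-fibre mean <theta_i>; ``ensemble_mean`` the unweighted
    mean of <theta_i> over fibres.
    """

    segment_angles: np.ndarray
    segment_lengths: np.ndarray
    fibre_means: np.ndarray
    ensemble_mean: float


@dataclass
class FibreMetrics:
    """Per-fibre tortuosity and strain flags."""

    tortuosity: np.ndarray
    strain: np.ndarray
    stretched: np.ndarray  # strain >= threshold


def segment_orientation(network: FibreNetwork) -> OrientationStats:
    """Axis angle of every segment: theta = arccos(|e_z . l_ij| / l_ij).

    Folding through the absolute dot product is direction-agnostic and
    guarantees theta in [0, pi/2].  Zero-length segments are excluded from the
    length-weighted fibre mean with a warning.
    """
    seg = network.segment_vectors()
    ell = np.linalg.norm(seg, axis=2)
    ok = ell > 0
    if not np.all(ok):
        warnings.warn("zero-length segments excluded from orientation stats")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.abs(seg[..., 2]) / ell
    theta = np.arccos(np.clip(cos_t, 0.0, 1.0))
    w = np.where(ok, ell, 0.0)
    fibre_means = (theta * w).sum(axis=1) / w.sum(axis=1)
    return OrientationStats(segment_angles=theta, segment_lengths=ell,
                            fibre_means=fibre_means,
                            ensemble_mean=float(fibre_means.mean()))


def orientation_probability(stats: OrientationStats,
                            edges: np.ndarray | None = None) -> np.ndarray:
    """Orientation probability density normalized by the spherical band area.

    For bands [Theta, Theta + dTheta] partitioning [0, pi/2] the density is
    count/N divided by DeltaS = cos(Theta) - cos(Theta + dTheta) (for the
    first band [0, pi/12] the factor is 1 - cos(pi/12)).  The densities times
    their band areas sum to one.
    """
    if stats.fibre_means.size == 0:
        raise ValueError("empty network")
    if edges is None:
        edges = np.linspace(0.0, math.pi / 2, 7)  # pi/12 bands
    edges = np.asarray(edges, dtype=float)
    if abs(edges[0]) > 1e-12 or abs(edges[-1] - math.pi / 2) > 1e-9:
        raise ValueError("bands must partition [0, pi/2]")
    counts, _ = np.histogram(stats.fibre_means, bins=edges)
    # histogram's last bin is closed; theta = pi/2 lands in the final band
    band_area = np.cos(edges[:-1]) - np.cos(edges[1:])
    return counts / stats.fibre_means.size / band_area


def tortuosity(network: FibreNetwork) -> np.ndarray:
    """Contour length over end-to-end distance per fibre (>= 1).

    Computed on unwrapped chains.  Fibres with coincident endpoints are
    flagged undefined (NaN) with a warning.
    """
    L = network.contour_lengths()
    L0 = network.end_to_end()
    out = np.full(L.shape, np.nan)
    ok = L0 > 0
    if not np.all(ok):
        warnings.warn("coincident fibre endpoints: tortuosity undefined")
    out[ok] = L[ok] / L0[ok]
    return out


def fibre_metrics(network: FibreNetwork, threshold: float = 0.05) -> FibreMetrics:
    strain = network.fibre_strain()
    return FibreMetrics(tortuosity=tortuosity(network), strain=strain,
                        stretched=strain >= threshold)


def stretched_fraction(network: FibreNetwork, threshold: float = 0.05) -> float:
    """n_(eps >= threshold)/N against the frozen steady-state lengths l0."""
    return float(np.mean(network.fibre_strain() >= threshold))


def percolation_axes(network: FibreNetwork, pairs: AggregationPairSet):
    """Axes around which the bonded network winds (gel criterion).

    Builds the node graph of chain bonds plus the given aggregation pairs and
    walks each connected component accumulating periodic image offsets; a
    cycle with inconsistent offset along an axis means the cluster connects
    to its own periodic image — the network percolates along that axis.
    Returns a boolean 3-vector (x, y, z).
    """
    from collections import deque

    p = network.flat_positions
    L = network.box_lengths
    N = network.n_nodes
    npf = network.nodes_per_fibre
    adj = [[] for _ in range(N)]
    for f in range(network.n_fibres):
        base = f * npf
        for m in range(npf - 1):
            i, j = base + m, base + m + 1
            zero = (0, 0, 0)
            adj[i].append((j, zero))
            adj[j].append((i, (0, 0, 0)))
    for i, j in zip(pairs.node_i, pairs.node_j):
        s = np.rint((p[j] - p[i]) / L).astype(int)
        adj[int(i)].append((int(j), tuple(s)))
        adj[int(j)].append((int(i), tuple(-s)))
    winding = np.zeros(3, dtype=bool)
    offset = np.zeros((N, 3), dtype=np.int64)
    seen = np.zeros(N, dtype=bool)
    for start in range(N):
        if seen[start]:
            continue
        seen[start] = True
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j, s in adj[i]:
                want = offset[i] + s
                if not seen[j]:
                    seen[j] = True
                    offset[j] = want
                    queue.append(j)
                else:
                    winding |= offset[j] != want
        if winding.all():
            break
    return winding


def bond_survival(network: FibreNetwork,
                  reference: AggregationPairSet | None = None,
                  a_th: float | None = None) -> float:
    """Fraction of reference aggregation pairs still within a_th (n_agg/n_agg0).

    Survival is evaluated on the reference pair set frozen at steady state so
    that pairs formed during extension do not mask dissociation.
    """
    reference = reference if reference is not None else network.reference_pairs
    if reference is None or len(reference) == 0:
        warnings.warn("empty reference pair set: bond survival undefined")
        return float("nan")
    if a_th is None:
        raise ValueError("a_th cutoff required")
    d = network.pair_distances(reference)
    return float(np.mean(d < a_th))
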
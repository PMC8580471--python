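"""The fibre-network state container and the aggregation pair set."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import minimum_image


@dataclass
class AggregationPairSet:
    """Unordered inter-fibre node pairs within a distance cutoff.

    ``node_i``/``node_j`` are flat node indices (fibre f, local node m maps to
    f * nodes_per_fibre + m); ``distances`` carries the minimum-image pair
    distance at build time.
    """

    node_i: np.ndarray
    node_j: np.ndarray
    distances: np.ndarray
    nodes_per_fibre: int

    def __len__(self) -> int:
        return self.node_i.size

    @property
    def pairs(self):
        """Pairs as ((fibre_i, node_i), (fibre_j, node_j)) tuples."""
        npf = self.nodes_per_fibre
        return [((int(i) // npf, int(i) % npf), (int(j) // npf, int(j) % npf))
                for i, j in zip(self.node_i, self.node_j)]


@dataclass
class FibreNetwork:
    """Node coordinates of ``n_fibres`` x ``nodes_per_fibre`` beads in a
    periodic box.

    Coordinates are stored unwrapped (contour-length bookkeeping stays exact);
    wrapped views are produced on demand for imaging and pair search.
    ``reference_lengths`` holds the per-fibre steady-state contour length l0,
    set when a steady state is declared, and is the denominator of the fibre
    strain epsilon = l/l0 - 1.  ``reference_pairs`` is the aggregation pair
    set frozen at the same moment (the n_agg^0 of bond-survival curves).
    """

    positions: np.ndarray  # (n_fibres, nodes_per_fibre, 3), metres
    box_lengths: np.ndarray  # (3,), metres
    time: float = 0.0
    reference_lengths: Optional[np.ndarray] = None
    reference_pairs: Optional[AggregationPairSet] = None
    #: persistent aggregation-bond state under the nearest-partner rule:
    #: (n_nodes, K) flat node indices of each node's partners, -1 = free slot
    bond_partner: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_fibres, nodes_per_fibre, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.box_lengths.shape != (3,) or np.any(self.box_lengths <= 0):
            raise ValueError("box_lengths must be three positive values")

    @property
    def n_fibres(self) -> int:
        return self.positions.shape[0]

    @property
    def nodes_per_fibre(self) -> int:
        return self.positions.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0] * self.positions.shape[1]

    @property
    def flat_positions(self) -> np.ndarray:
        """(N, 3) view shared with ``positions``."""
        return self.positions.reshape(-1, 3)

    def wrapped_positions(self) -> np.ndarray:
        """Coordinates folded into [0, L) per axis (copy)."""
        p = self.flat_positions
        L = self.box_lengths
        return p - L * np.floor(p / L)

    def segment_vectors(self) -> np.ndarray:
        """(n_fibres, nodes_per_fibre - 1, 3) bonded vectors (unwrapped)."""
        return np.diff(self.positions, axis=1)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=2)

    def contour_lengths(self) -> np.ndarray:
        """Per-fibre contour length l (sum of segment lengths)."""
        return self.segment_lengths().sum(axis=1)

    def end_to_end(self) -> np.ndarray:
        """Per-fibre Euclidean end-to-end distance (unwrapped)."""
        return np.linalg.norm(self.positions[:, -1] - self.positions[:, 0], axis=1)

    def pair_distances(self, pairs: AggregationPairSet) -> np.ndarray:
        """Current minimum-image distances of the given pair set."""
        p = self.flat_positions
        d = p[pairs.node_j] - p[pairs.node_i]
        return np.linalg.norm(minimum_image(d, self.box_lengths), axis=-1)

    def freeze_reference(self, pairs: AggregationPairSet) -> None:
        """Declare the steady state: record l0 and the reference pair set."""
        self.reference_lengths = self.contour_lengths().copy()
        self.reference_pairs = pairs

    def fibre_strain(self) -> np.ndarray:
        """epsilon = l/l0 - 1 against the frozen steady-state lengths."""
        if self.reference_lengths is None:
            raise ValueError("reference lengths not set; declare a steady state first")
        return self.contour_lengths() / self.reference_lengths - 1.0

    def bonded_pairs(self) -> AggregationPairSet:
        """Current persistent aggregation bonds as a pair set."""
        if self.bond_partner is None:
            return AggregationPairSet(np.empty(0, np.int64),
                                      np.empty(0, np.int64), np.empty(0),
                                      self.nodes_per_fibre)
        i, s = np.nonzero(self.bond_partner
                          > np.arange(self.n_nodes)[:, None])
        j = self.bond_partner[i, s]
        pairs = AggregationPairSet(i.astype(np.int64), j.astype(np.int64),
                                   np.empty(i.size), self.nodes_per_fibre)
        pairs.distances = self.pair_distances(pairs) if i.size else np.empty(0)
        return pairs

    def copy(self) -> "FibreNetwork":
        return FibreNetwork(
            positions=self.positions.copy(),
            box_lengths=self.box_lengths.copy(),
            time=self.time,
            reference_lengths=None if self.reference_lengths is None
            else self.reference_lengths.copy(),
            reference_pairs=self.reference_pairs,
            bond_partner=None if self.bond_partner is None
            else self.bond_partner.copy(),
        )
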
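"""Synthetic electrode montage on the unit disk.

Electrode layouts are quasi-uniform points placed by a sunflower (golden
angle) spiral with a small seeded jitter, mimicking an equidistant scalp
montage flattened to 2-D.  Spatial adjacency — needed by the cluster
permutation test — is the symmetrized union of k-nearest-neighbor relations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["Montage", "make_montage"]


@dataclass(frozen=True)
class Montage:
    """Electrode ids, 2-D unit-disk positions, and a symmetric adjacency."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_e, 2)
    adjacency: np.ndarray  # (n_e, n_e) bool, symmetric, irreflexive

    @property
    def n_electrodes(self) -> int:
        return len(self.names)

    def neighbors(self, e: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[e])

    def is_connected(self) -> bool:
        n, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n == 1

    def left_mask(self) -> np.ndarray:
        """Electrodes strictly left of the midline (x < 0)."""
        return self.positions[:, 0] < 0.0


def make_montage(n_e: int = 61, k: int = 4, seed: int = 0) -> Montage:
    """Quasi-uniform disk montage with union-of-kNN adjacency.

    Positions follow a sunflower spiral plus Gaussian jitter (sd 0.02),
    deterministic given the seed.  Electrode ``i`` and ``j`` are adjacent if
    either is among the other's k nearest neighbors.
    """
    if n_e < 2:
        raise ValueError("need at least 2 electrodes")
    if k < 1 or k >= n_e:
        raise ValueError("need 1 <= k < n_e")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_e + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt((i - 0.5) / n_e)
    theta = golden * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pos += rng.normal(0.0, 0.02, pos.shape)

    tree = cKDTree(pos)
    _, nn = tree.query(pos, k=k + 1)  # first neighbor is the point itself
    adj = np.zeros((n_e, n_e), dtype=bool)
    for e in range(n_e):
        for j in nn[e, 1:]:
            adj[e, j] = True
            adj[j, e] = True
    np.fill_diagonal(adj, False)

    names = tuple(f"E{idx + 1:02d}" for idx in range(n_e))
    return Montage(names=names, positions=pos, adjacency=adj)
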
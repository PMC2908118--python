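"""Patch lattice topologies and density-independent dispersal.

The experimental microcosms are four habitat patches at the corners of a
square; connecting tubes run along the edges only, so the lattice distance
between adjacent patches is 1 and between diagonally opposite patches is 2.
The simulation study additionally uses the limiting two-patch case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LatticeTopology", "pair_topology", "square4_topology", "disperse"]


@dataclass(frozen=True)
class LatticeTopology:
    """A small patch lattice with adjacency and integer lattice distances.

    Parameters
    ----------
    n_patches:
        Number of habitat patches.
    adjacency:
        Symmetric boolean (n_patches, n_patches) matrix, False on the diagonal.
        Dispersing individuals move only along adjacency edges.
    distance:
        Symmetric integer (n_patches, n_patches) matrix of lattice distances,
        zero on the diagonal.
    """

    n_patches: int
    adjacency: np.ndarray = field(repr=False)
    distance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        dist = np.asarray(self.distance)
        if adj.shape != (self.n_patches, self.n_patches):
            raise ValueError("adjacency shape does not match n_patches")
        if dist.shape != (self.n_patches, self.n_patches):
            raise ValueError("distance shape does not match n_patches")
        if not np.array_equal(adj, adj.T) or adj.diagonal().any():
            raise ValueError("adjacency must be symmetric with empty diagonal")
        if not np.array_equal(dist, dist.T) or dist.diagonal().any():
            raise ValueError("distance must be symmetric with zero diagonal")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "distance", dist)

    @property
    def degree(self) -> np.ndarray:
        """Number of neighbours of each patch."""
        return self.adjacency.sum(axis=1)

    def pairs_at_distance(self, s: int) -> list[tuple[int, int]]:
        """Unordered patch pairs (i < j) separated by lattice distance ``s``."""
        i, j = np.where(np.triu(self.distance == s, k=1))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def mixing_matrix(self) -> np.ndarray:
        """Row-stochastic matrix M with M[i, j] = share of patch i's migrants
        arriving in patch j (equal split among neighbours); diagonal zero."""
        deg = self.degree.astype(float)
        m = self.adjacency.astype(float)
        nz = deg > 0
        m[nz] = m[nz] / deg[nz, None]
        return m


def pair_topology() -> LatticeTopology:
    """The limiting two-patch metapopulation used in the simulation study."""
    adj = np.array([[False, True], [True, False]])
    dist = np.array([[0, 1], [1, 0]])
    return LatticeTopology(2, adj, dist)


def square4_topology() -> LatticeTopology:
    """Four patches at the corners of a square, edges only (no diagonals).

    Patch order is (0, 1, 2, 3) = (NW, NE, SW, SE): patches 0-1, 0-2, 1-3 and
    2-3 share an edge (distance 1); 0-3 and 1-2 are diagonal (distance 2).
    """
    adj = np.zeros((4, 4), dtype=bool)
    for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
        adj[i, j] = adj[j, i] = True
    dist = np.where(adj, 1, 2)
    np.fill_diagonal(dist, 0)
    return LatticeTopology(4, adj, dist)


def topology_from_name(name: str) -> LatticeTopology:
    """Resolve a topology by its configuration name ('pair' or 'square4')."""
    if name == "pair":
        return pair_topology()
    if name == "square4":
        return square4_topology()
    raise ValueError(f"unknown topology {name!r}; expected 'pair' or 'square4'")


def disperse(abundances: np.ndarray, d: float, topology: LatticeTopology) -> np.ndarray:
    """Redistribute a fixed proportion ``d`` of each patch's abundance.

    Each patch exports ``d`` times its own abundance, split equally among its
    lattice neighbours; total abundance is conserved exactly. For two patches
    this reduces to ``new_i = (1 - d) * x_i + d * x_j``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"dispersal proportion must be in [0, 1], got {d}")
    x = np.asarray(abundances, dtype=float)
    if x.shape[-1] != topology.n_patches:
        raise ValueError("abundance vector length does not match topology")
    if d == 0.0:
        return x.copy()
    return (1.0 - d) * x + d * (x @ topology.mixing_matrix)
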
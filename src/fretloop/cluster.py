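"""Greedy RMSD neighbor-count (GROMOS-style) conformational clustering.

Structures are compared by positional RMSD after optimal least-squares
superposition (Kabsch). Clustering repeatedly extracts the structure with
the most neighbors within a cutoff as a cluster center, assigns its
neighbors to that cluster, and removes them — yielding clusters ordered by
population. The cumulative count of distinct clusters versus time is the
usual convergence diagnostic for conformational sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import Frame

__all__ = [
    "ClusterResult",
    "pairwise_rmsd",
    "rmsd_matrix",
    "daura_cluster",
    "cumulative_cluster_curve",
]


@dataclass
class ClusterResult:
    """Partition of structures into clusters.

    ``assignments[i]`` is the 0-based cluster id of structure ``i``, with
    id 0 the most populated cluster; ``centers[k]`` is the structure index
    of cluster ``k``'s center; ``populations`` are non-increasing.
    """

    assignments: np.ndarray
    centers: np.ndarray
    populations: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD of two (n, 3) coordinate sets after optimal superposition."""
    if np.array_equal(x, y):
        return 0.0
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Optimal rotation via SVD of the covariance; reflection corrected.
    u, s, vt = np.linalg.svd(yc.T @ xc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    # Explicit residual avoids the cancellation of the E0 - 2*sum(s) form.
    diff = xc - yc @ rot
    return float(np.sqrt((diff ** 2).sum() / len(x)))


def pairwise_rmsd(a: Frame, b: Frame, atom_subset: Sequence[int] | None = None,
                  ) -> float:
    """Minimum RMSD (nm) between two frames over ``atom_subset``.

    Translation and rotation are removed by least-squares superposition, so
    a rigidly transformed copy gives 0.
    """
    idx = np.asarray(atom_subset if atom_subset is not None
                     else range(a.n_atoms), dtype=int)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    x = a.coordinates[idx]
    y = b.coordinates[idx]
    if x.shape != y.shape:
        raise ValueError("atom subsets differ in size between frames")
    return _kabsch_rmsd(x, y)


def rmsd_matrix(structures: Sequence[Frame],
                atom_subset: Sequence[int] | None = None) -> np.ndarray:
    """Symmetric all-pairs RMSD matrix (nm)."""
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_rmsd(structures[i], structures[j],
                                                  atom_subset)
    return mat


def daura_cluster(structures: Sequence[Frame], cutoff: float,
                  atom_subset: Sequence[int] | None = None) -> ClusterResult:
    """Greedy neighbor-count clustering at an RMSD ``cutoff`` (nm).

    At each iteration the unassigned structure with the largest number of
    unassigned neighbors within the cutoff (itself included) becomes the
    next cluster center; it and its neighbors are assigned and removed.
    Ties in neighbor count are broken toward the lower structure index, so
    the result is deterministic. Populations are non-increasing by
    construction and cluster ids follow extraction order.
    """
    if len(structures) < 1:
        raise ValueError("need at least one structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = rmsd_matrix(structures, atom_subset)
    return cluster_from_matrix(dist, cutoff)


def cluster_from_matrix(dist: np.ndarray, cutoff: float) -> ClusterResult:
    """Run the greedy neighbor-count pass on a precomputed RMSD matrix."""
    n = dist.shape[0]
    neighbor = dist <= cutoff
    np.fill_diagonal(neighbor, True)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    populations: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cluster_id = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbor[center] & remaining)[0]
        assignments[members] = cluster_id
        centers.append(center)
        populations.append(len(members))
        remaining[members] = False
        cluster_id += 1
    return ClusterResult(assignments, np.asarray(centers),
                         np.asarray(populations), float(cutoff))


def cumulative_cluster_curve(assignments_in_time_order: Sequence[int],
                             ) -> np.ndarray:
    """Number of distinct clusters seen up to each time point.

    Element ``t`` counts the distinct cluster ids among
    ``assignments[0..t]``; the curve is non-decreasing and plateaus once
    sampling stops discovering new conformational states.
    """
    assignments = np.asarray(assignments_in_time_order, dtype=int)
    if assignments.size == 0:
        raise ValueError("assignments must be non-empty")
    seen: set[int] = set()
    out = np.empty(assignments.size, dtype=int)
    for t, a in enumerate(assignments):
        seen.add(int(a))
        out[t] = len(seen)
    return out
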
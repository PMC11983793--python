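"""Trajectory utilities: RMSD series, pairwise RMSD matrices, and
hierarchical clustering of frames with medoid extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from phenolig.structures import Trajectory
from phenolig.waters import kabsch


def _fitted_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    rot, trans = kabsch(mobile, reference)
    moved = mobile @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))


def compute_rmsd_series(trajectory: Trajectory, selection: list[int] | None = None,
                        reference_frame: int = 0) -> np.ndarray:
    """Optimal-superposition RMSD of the selection per frame vs the reference."""
    if selection is None:
        top = trajectory.topology
        selection = [a.index for a in top.atoms_of_entity("protein")] or list(range(len(top.atoms)))
    ref = trajectory.frames[reference_frame][selection]
    return np.array([_fitted_rmsd(f[selection], ref) for f in trajectory.frames])


def rmsd_matrix(trajectory: Trajectory, selection: list[int] | None = None) -> np.ndarray:
    """Symmetric frames x frames matrix of pairwise fitted RMSDs."""
    if selection is None:
        top = trajectory.topology
        selection = [a.index for a in top.atoms_of_entity("protein")] or list(range(len(top.atoms)))
    coords = [f[selection] for f in trajectory.frames]
    n = len(coords)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _fitted_rmsd(coords[j], coords[i])
    return m


@dataclass
class FrameClustering:
    rmsd: np.ndarray
    labels: np.ndarray  # cluster index per frame, 0-based
    medoids: list[int]  # frame index per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def segments(self) -> dict[int, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in range(self.n_clusters)}


def cluster_frames(matrix: np.ndarray, n_clusters: int, method: str = "average") -> FrameClustering:
    """Agglomerative clustering of the RMSD matrix cut at ``n_clusters``.

    The medoid of each cluster is the frame with minimal summed RMSD to its
    cluster mates; ties resolve to the lower frame index.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("rmsd matrix must be square and symmetric")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    if n_clusters == n:
        labels = np.arange(n)
    else:
        z = linkage(squareform(matrix, checks=False), method=method)
        raw = fcluster(z, t=n_clusters, criterion="maxclust")
        # relabel clusters by first appearance for a deterministic ordering
        order: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, r in enumerate(raw):
            if r not in order:
                order[r] = len(order)
            labels[i] = order[r]
    medoids = []
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        sums = matrix[np.ix_(members, members)].sum(axis=1)
        medoids.append(int(members[int(np.argmin(sums))]))  # argmin takes first on ties
    return FrameClustering(rmsd=matrix, labels=labels, medoids=medoids)
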
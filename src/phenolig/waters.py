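"""Conserved-water analysis: superposition, pooling and density clustering.

Snapshots sharing one topology are rigid-body superposed onto a reference
frame (least-squares, Kabsch), water oxygen positions are pooled into one
point cloud, and density clustering (DBSCAN, default eps = 0.9 Å,
min_pts = 4) locates regions occupied across many snapshots.  A cluster's
conservation is its size divided by the number of snapshots; it can exceed
one when several waters of a single snapshot co-occupy a site, which is
logged but not capped.  Clusters with at least 16 members and conservation
above 0.26 are reported by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from phenolig.structures import Atom, Structure

logger = logging.getLogger(__name__)

DEFAULT_EPS = 0.9
DEFAULT_MIN_PTS = 4
DEFAULT_MIN_SIZE = 16
DEFAULT_MIN_CONSERVATION = 0.26


@dataclass
class WaterCloud:
    """Pooled water-oxygen positions tagged with their snapshot of origin."""

    points: np.ndarray  # (n, 3)
    snapshot_ids: np.ndarray  # (n,), values in [1, n_snapshots]
    n_snapshots: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.snapshot_ids = np.asarray(self.snapshot_ids, dtype=int)
        if len(self.snapshot_ids) != len(self.points):
            raise ValueError("one snapshot id per point required")
        if len(self.points) and not (
            (1 <= self.snapshot_ids).all() and (self.snapshot_ids <= self.n_snapshots).all()
        ):
            raise ValueError("snapshot ids outside [1, n_snapshots]")


@dataclass
class WaterCluster:
    member_points: np.ndarray  # indices into the cloud
    centroid: np.ndarray
    size: int
    conservation: float


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto reference
    in the least-squares sense: x -> R @ (x - mobile_mean) + reference_mean."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def superpose(snapshots: list[Structure], reference_index: int = 0,
              selection: list[int] | None = None) -> tuple[list[Structure], np.ndarray]:
    """Superpose each snapshot's selection onto the reference snapshot.

    ``selection`` is a list of atom indices valid in every snapshot (same
    topology); default: all protein atoms of the reference.  The fitted
    transform is applied to all atoms, waters included.  Returns the aligned
    snapshots and the per-snapshot RMSD of the selection after fitting.
    """
    ref = snapshots[reference_index]
    if selection is None:
        selection = [a.index for a in ref.atoms_of_entity("protein")] or list(range(len(ref.atoms)))
    n = len(ref.atoms)
    for i, s in enumerate(snapshots):
        if len(s.atoms) != n:
            raise ValueError(f"snapshot {i} has {len(s.atoms)} atoms, reference has {n}")
    ref_sel = ref.coordinates()[selection]
    aligned = []
    rmsds = np.zeros(len(snapshots))
    for i, s in enumerate(snapshots):
        coords = s.coordinates()
        rot, trans = kabsch(coords[selection], ref_sel)
        moved = coords @ rot.T + trans
        rmsds[i] = float(np.sqrt(np.mean(np.sum((moved[selection] - ref_sel) ** 2, axis=1))))
        aligned.append(s.with_coordinates(moved))
    return aligned, rmsds


def collect_waters(snapshots: list[Structure]) -> WaterCloud:
    """Pool all water oxygen positions of (aligned) snapshots."""
    points, ids = [], []
    for i, s in enumerate(snapshots, start=1):
        for a in s.atoms_of_entity("water"):
            if a.element.upper() == "O":
                points.append(a.coordinates)
                ids.append(i)
    return WaterCloud(
        points=np.array(points).reshape(-1, 3),
        snapshot_ids=np.array(ids, dtype=int),
        n_snapshots=len(snapshots),
    )


# ---------------------------------------------------------------------------
# density clustering


def dbscan3d(cloud: WaterCloud, eps: float = DEFAULT_EPS, min_pts: int = DEFAULT_MIN_PTS) -> list[WaterCluster]:
    """Classic density clustering of the pooled water positions.

    Core points have >= min_pts neighbors (the point itself included) within
    eps; clusters are connected core regions plus reachable border points.
    Points are processed in storage order, so a border point within eps of
    two cores joins the cluster discovered first (lowest cluster index) -
    the canonical tie-break.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = len(cloud.points)
    if n == 0:
        return []
    tree = cKDTree(cloud.points)
    neighborhoods = tree.query_ball_point(cloud.points, r=eps)
    is_core = np.array([len(nb) >= min_pts for nb in neighborhoods])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for start in range(n):
        if labels[start] != -1 or not is_core[start]:
            continue
        labels[start] = cluster
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in sorted(neighborhoods[i]):
                if labels[j] == -1:
                    labels[j] = cluster
                    if is_core[j]:
                        frontier.append(j)
        cluster += 1
    clusters = []
    for c in range(cluster):
        members = np.flatnonzero(labels == c)
        conservation = len(members) / cloud.n_snapshots
        if conservation > 1.0:
            logger.info("cluster %d conservation %.2f exceeds 1 (co-occupied site)", c, conservation)
        clusters.append(
            WaterCluster(
                member_points=members,
                centroid=cloud.points[members].mean(axis=0),
                size=len(members),
                conservation=conservation,
            )
        )
    return clusters


def conservation_filter(clusters: list[WaterCluster], n_snapshots: int,
                        min_size: int = DEFAULT_MIN_SIZE,
                        min_conservation: float = DEFAULT_MIN_CONSERVATION) -> list[WaterCluster]:
    """Keep clusters with size >= min_size and size/n_snapshots > min_conservation."""
    if n_snapshots <= 0:
        raise ValueError("n_snapshots must be positive")
    return [
        c for c in clusters
        if c.size >= min_size and c.size / n_snapshots > min_conservation
    ]


def cluster_report(clusters: list[WaterCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": i,
            "size": c.size,
            "conservation": c.conservation,
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "centroid_z": c.centroid[2],
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "size", "conservation",
                                       "centroid_x", "centroid_y", "centroid_z"])


def centroids_to_pdb(clusters: list[WaterCluster], path) -> None:
    """Pseudo-atom PDB with conservation written to the B-factor column."""
    lines = []
    for i, c in enumerate(clusters, start=1):
        x, y, z = c.centroid
        b = min(c.conservation, 9.99)
        lines.append(
            f"HETATM{i:>5d}  O   HOH W{i:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           O"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\nEND\n")
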
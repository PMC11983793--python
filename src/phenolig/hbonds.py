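"""Direct and water-mediated hydrogen-bond network graphs.

Hydrogen bonds use a donor-acceptor distance criterion (default <= 3.5 Å)
and, when hydrogen coordinates are available, an additional angle criterion:
the deviation of the D-H...A angle from linearity must not exceed 60 deg.
Water-mediated bridges connect two non-water polar groups through chains of
one to three distinct water molecules, every consecutive link itself a
hydrogen bond.  Over a trajectory each edge carries an occupancy (fraction
of frames with any qualifying path) and the mean number of bridging waters
across the frames where it is present.  Candidate donor-acceptor pairs come
from a k-d tree, so the search is sub-quadratic in the number of polar
atoms while returning exactly the all-pairs result.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from phenolig.structures import Atom, Structure, Trajectory
from phenolig.atom_types import TypedAtom, assign_types, perceive_ligand
from phenolig.interactions import DONOR_TYPES, ACCEPTOR_TYPES

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_MAX = 3.5
DEFAULT_ANGLE_MAX = 60.0
DEFAULT_MAX_WATERS = 3


@dataclass(frozen=True)
class HBondNode:
    """A donor/acceptor group: residue side chain, residue backbone,
    ligand polar group, or a single water molecule."""

    kind: str  # "protein", "ligand", "water"
    label: str

    def __str__(self) -> str:
        return self.label


@dataclass
class EdgeStatistics:
    occupancy: float
    mean_waters: float
    n_frames_present: int

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy outside [0, 1]")


@dataclass
class HBondGraph:
    """Undirected graph of direct and water-mediated hydrogen bonds."""

    edges: dict[tuple[HBondNode, HBondNode, str], EdgeStatistics] = field(default_factory=dict)
    n_frames: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_u": str(u),
                "node_v": str(v),
                "kind": kind,
                "occupancy": st.occupancy,
                "mean_waters": st.mean_waters,
            }
            for (u, v, kind), st in sorted(self.edges.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]), kv[0][2]))
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-frame machinery


class FrameHBonds:
    """Polar atoms, nodes and qualifying H-bond pairs of one structure."""

    def __init__(self, structure: Structure, typed: dict[int, TypedAtom] | None = None,
                 d_max: float = DEFAULT_DISTANCE_MAX, angle_max: float = DEFAULT_ANGLE_MAX,
                 use_angles: bool = False):
        self.structure = structure
        self.typed = typed if typed is not None else assign_types(structure)
        self.d_max = d_max
        self.angle_max = angle_max
        self.use_angles = use_angles
        self.polar: list[Atom] = []
        self._roles: dict[int, tuple[bool, bool]] = {}
        ent = structure.entity_of
        for a in structure.atoms:
            t = self.typed.get(a.index)
            if t is None or a.element.upper() == "H":
                continue
            if ent(a) == "water":
                if a.element.upper() == "O":
                    self.polar.append(a)
                    self._roles[a.index] = (True, True)
            elif ent(a) in ("protein", "ligand", "cofactor"):
                donor = t.sybyl in DONOR_TYPES
                acceptor = t.sybyl in ACCEPTOR_TYPES
                if donor or acceptor:
                    self.polar.append(a)
                    self._roles[a.index] = (donor, acceptor)
        self.hydrogens = [a for a in structure.atoms if a.element.upper() == "H"]
        if use_angles and not self.hydrogens:
            raise ValueError("use_angles requires hydrogen coordinates in the structure")
        self._ligand_group: dict[int, str] = self._ligand_groups()

    def _ligand_groups(self) -> dict[int, str]:
        """Ligand polar atoms mapped to group labels; carboxylate O pairs merge."""
        groups: dict[int, str] = {}
        by_residue: dict[tuple, list[Atom]] = {}
        for a in self.structure.atoms_of_entity("ligand"):
            by_residue.setdefault(a.residue_key, []).append(a)
        for key, atoms in by_residue.items():
            heavy = [a for a in atoms if a.element.upper() != "H"]
            p = perceive_ligand(heavy)
            for c, (o1, o2) in p.carboxylate_groups:
                label = f"{heavy[0].residue_label}:coo{c}"
                groups[p.atoms[o1].index] = label
                groups[p.atoms[o2].index] = label
            for a in heavy:
                if a.index not in groups:
                    groups[a.index] = f"{a.residue_label}:{a.name}"
        return groups

    def node_of(self, a: Atom) -> HBondNode:
        ent = self.structure.entity_of(a)
        if ent == "water":
            return HBondNode("water", a.residue_label)
        if ent == "protein":
            part = "bk" if a.name in ("N", "CA", "C", "O", "OXT") else "sc"
            return HBondNode("protein", f"{a.residue_label}:{part}")
        return HBondNode("ligand", self._ligand_group.get(a.index, f"{a.residue_label}:{a.name}"))

    # -- neighbor candidates (k-d tree contract)
    def neighbor_candidates(self, radius: float | None = None) -> list[tuple[int, int]]:
        """Superset of all polar-atom pairs within radius (indices into .polar)."""
        radius = self.d_max if radius is None else radius
        if radius <= 0 or len(self.polar) < 2:
            return []
        xyz = np.array([a.coordinates for a in self.polar])
        tree = cKDTree(xyz)
        return sorted(tree.query_pairs(r=radius))

    def _angle_ok(self, donor: Atom, acceptor: Atom) -> bool:
        hs = [
            h for h in self.hydrogens
            if np.linalg.norm(h.coordinates - donor.coordinates) < 1.25
        ]
        if not hs:
            return False  # in angle mode a donor without H cannot qualify
        for h in hs:
            v1 = donor.coordinates - h.coordinates
            v2 = acceptor.coordinates - h.coordinates
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            dha = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            if 180.0 - dha <= self.angle_max:  # deviation from linearity
                return True
        return False

    def pairs(self) -> list[tuple[Atom, Atom]]:
        """All qualifying donor-acceptor pairs (unordered, donor listed first
        when the roles are unambiguous)."""
        out = []
        for i, j in self.neighbor_candidates():
            a, b = self.polar[i], self.polar[j]
            d = float(np.linalg.norm(a.coordinates - b.coordinates))
            if d > self.d_max:
                continue
            da, aa = self._roles[a.index]
            db, ab = self._roles[b.index]
            forward = da and ab and (not self.use_angles or self._angle_ok(a, b))
            backward = db and aa and (not self.use_angles or self._angle_ok(b, a))
            if forward:
                out.append((a, b))
            elif backward:
                out.append((b, a))
        return out


def find_hbonds(structure: Structure, d_max: float = DEFAULT_DISTANCE_MAX,
                angle_max: float = DEFAULT_ANGLE_MAX, use_angles: bool = False,
                typed: dict[int, TypedAtom] | None = None) -> list[tuple[Atom, Atom]]:
    """All donor-acceptor pairs satisfying the distance (and angle) criteria."""
    return FrameHBonds(structure, typed=typed, d_max=d_max, angle_max=angle_max,
                       use_angles=use_angles).pairs()


@dataclass(frozen=True)
class Bridge:
    """Shortest water bridge between two non-water nodes."""

    n_waters: int
    waters: tuple  # residue keys of the bridging waters, in path order


def find_water_bridges(structure: Structure = None, max_waters: int = DEFAULT_MAX_WATERS,
                       d_max: float = DEFAULT_DISTANCE_MAX, angle_max: float = DEFAULT_ANGLE_MAX,
                       use_angles: bool = False,
                       typed: dict[int, TypedAtom] | None = None,
                       frame: FrameHBonds | None = None) -> dict[tuple[HBondNode, HBondNode], Bridge]:
    """Shortest water bridge per non-water node pair.

    A bridge u-w1-...-wk-v requires every consecutive link to be a hydrogen
    bond, all waters distinct, and k <= max_waters.  The reported path is
    one shortest chain of bridging waters.
    """
    fh = frame or FrameHBonds(structure, typed=typed, d_max=d_max, angle_max=angle_max,
                              use_angles=use_angles)
    pairs = fh.pairs()
    ent = fh.structure.entity_of
    # adjacency: water <-> water and water <-> non-water node
    water_adj: dict[tuple, set[tuple]] = {}
    node_waters: dict[HBondNode, set[tuple]] = {}
    for a, b in pairs:
        wa, wb = ent(a) == "water", ent(b) == "water"
        if wa and wb:
            water_adj.setdefault(a.residue_key, set()).add(b.residue_key)
            water_adj.setdefault(b.residue_key, set()).add(a.residue_key)
        elif wa or wb:
            water, other = (a, b) if wa else (b, a)
            node_waters.setdefault(fh.node_of(other), set()).add(water.residue_key)
    water_nodes: dict[tuple, set[HBondNode]] = {}
    for node, waters in node_waters.items():
        for w in waters:
            water_nodes.setdefault(w, set()).add(node)
    bridges: dict[tuple[HBondNode, HBondNode], Bridge] = {}
    for u, first_waters in node_waters.items():
        # BFS through the water graph from u; depth = number of waters used
        seen: dict[tuple, int] = {}
        parent: dict[tuple, tuple | None] = {}
        queue: deque[tuple[tuple, int]] = deque()
        for w in sorted(first_waters):
            seen[w] = 1
            parent[w] = None
            queue.append((w, 1))
        while queue:
            w, depth = queue.popleft()
            for v in water_nodes.get(w, ()):  # water touches a non-water node
                if v == u:
                    continue
                key = tuple(sorted((u, v), key=str))
                if key not in bridges or depth < bridges[key].n_waters:
                    path = []
                    step = w
                    while step is not None:
                        path.append(step)
                        step = parent[step]
                    bridges[key] = Bridge(n_waters=depth, waters=tuple(reversed(path)))
            if depth < max_waters:
                for w2 in sorted(water_adj.get(w, ())):
                    if w2 not in seen:
                        seen[w2] = depth + 1
                        parent[w2] = w
                        queue.append((w2, depth + 1))
    return bridges


def build_graph(trajectory: Trajectory, d_max: float = DEFAULT_DISTANCE_MAX,
                angle_max: float = DEFAULT_ANGLE_MAX, use_angles: bool = False,
                max_waters: int = DEFAULT_MAX_WATERS,
                occupancy_threshold: float = 0.5,
                restrict_to_ligand: bool = False) -> HBondGraph:
    """Per-edge occupancy and mean bridging-water count over a trajectory.

    Direct edges (kind="direct", 0 waters) and water-mediated edges
    (kind="water_mediated") are tracked separately; edges below
    ``occupancy_threshold`` are dropped (set 0 to keep all).  With
    ``restrict_to_ligand`` only edges touching a ligand node are kept.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    typed = assign_types(trajectory.topology)
    direct_presence: dict[tuple[HBondNode, HBondNode], np.ndarray] = {}
    bridge_waters: dict[tuple[HBondNode, HBondNode], dict[int, int]] = {}
    n = trajectory.n_frames
    for f in range(n):
        st = trajectory.frame_structure(f)
        fh = FrameHBonds(st, typed=typed, d_max=d_max, angle_max=angle_max, use_angles=use_angles)
        ent = st.entity_of
        for a, b in fh.pairs():
            if ent(a) == "water" or ent(b) == "water":
                continue
            u, v = fh.node_of(a), fh.node_of(b)
            if u == v:
                continue
            key = tuple(sorted((u, v), key=str))
            direct_presence.setdefault(key, np.zeros(n, dtype=bool))[f] = True
        for key, bridge in find_water_bridges(frame=fh, max_waters=max_waters).items():
            entry = bridge_waters.setdefault(key, {})
            entry[f] = min(bridge.n_waters, entry.get(f, bridge.n_waters))
    graph = HBondGraph(n_frames=n)
    for (u, v), present in direct_presence.items():
        occ = float(present.mean())
        if occ >= occupancy_threshold and (not restrict_to_ligand or "ligand" in (u.kind, v.kind)):
            graph.edges[(u, v, "direct")] = EdgeStatistics(occ, 0.0, int(present.sum()))
    for (u, v), per_frame in bridge_waters.items():
        occ = len(per_frame) / n
        if occ >= occupancy_threshold and (not restrict_to_ligand or "ligand" in (u.kind, v.kind)):
            mean_w = float(np.mean(list(per_frame.values())))
            graph.edges[(u, v, "water_mediated")] = EdgeStatistics(occ, mean_w, len(per_frame))
    return graph
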
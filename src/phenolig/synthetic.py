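"""Seeded generators with planted ground truth for every pipeline stage.

The generators build minimal but chemically sensible fragments (idealized
benzene rings at 1.39 Å bond length, carboxylates, lone side chains on
bare residues) at exactly controlled geometry, so each planted interaction,
bridge or cluster is recoverable by construction.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from phenolig.structures import Atom, Structure, Trajectory, classify_entities
from phenolig.waters import WaterCloud
from phenolig import catalog


@dataclass
class PlantedTruth:
    """What a generator planted, in a JSON-serializable form."""

    seed: int
    interactions: list[dict] = field(default_factory=list)
    bridges: list[dict] = field(default_factory=list)
    clusters: list[dict] = field(default_factory=list)
    matches: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=lambda o: np.asarray(o).tolist())
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


class _Builder:
    """Sequentially numbered atom records."""

    def __init__(self):
        self.atoms: list[Atom] = []

    def add(self, name, element, resname, resnum, chain, xyz, het=False):
        self.atoms.append(
            Atom(
                serial=len(self.atoms) + 1,
                name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                insertion_code="",
                chain_id=chain,
                altloc="",
                occupancy=1.0,
                coordinates=np.asarray(xyz, float),
                is_hetatm=het,
                index=len(self.atoms),
            )
        )
        return self.atoms[-1]

    def structure(self) -> Structure:
        return classify_entities(Structure(atoms=self.atoms))


def _hexagon(center, radius=1.39, tilt_x_deg=0.0):
    """Six ring positions in the xy-plane, optionally tilted about x."""
    t = np.radians(tilt_x_deg)
    rot = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    pts = []
    for k in range(6):
        ang = k * np.pi / 3
        pts.append(np.asarray(center) + rot @ np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0]))
    return pts


def _add_ligand_ring(b: _Builder, center, counter, resnum=100, chain="L", tilt=0.0, hydroxyls=()):
    """Benzene fragment of the ligand; optional hydroxyls on ring positions.

    Returns (ring atoms, hydroxyl atoms).  Hydroxyl oxygens sit 1.36 Å
    radially outward from their ring carbon.
    """
    pts = _hexagon(center, tilt_x_deg=tilt)
    ring = [b.add(f"C{counter + k:02d}", "C", "UNL", resnum, chain, p, het=True) for k, p in enumerate(pts)]
    oxygens = []
    for k in hydroxyls:
        direction = (pts[k] - np.asarray(center)) / 1.39
        o = b.add(f"O{counter + k:02d}", "O", "UNL", resnum, chain, pts[k] + 1.36 * direction, het=True)
        oxygens.append(o)
    return ring, oxygens


def make_interaction_zoo(seed: int = 0) -> tuple[Structure, PlantedTruth]:
    """A pocket with exactly one planted instance of each interaction kind.

    Eight stations, 20 Å apart along x, each pairing one ligand fragment
    with one minimal protein partner at canonical geometry: H-bond 2.8 Å,
    hydrophobic 3.7 Å, parallel stack 3.8 Å / 5 deg, T-stack 5.0 Å / 78 deg,
    pi-cation 4.0 Å, salt bridge 3.9 Å (charge centers), metal-O 2.1 Å, and
    a single-water bridge at 2.8 / 2.9 Å.  Expect 8 interaction records
    (pi-stacking contributes both a P and a T instance).
    """
    b = _Builder()
    truth = PlantedTruth(seed=seed)

    # station 1: hydrogen bond - ligand phenol to Ser OG at 2.8 Å
    _, (d1,) = _add_ligand_ring(b, (0.0, 0.0, 0.0), counter=0, hydroxyls=(0,))
    b.add("OG", "O", "SER", 1, "A", (5.55, 0.0, 0.0))
    b.add("CB", "C", "SER", 1, "A", (6.96, 0.0, 0.0))
    truth.interactions.append({"kind": "hbond", "residue": "SER1A", "distance": 2.8})

    # station 2: hydrophobic - ligand propane terminal C to Leu CD1 at 3.7 Å
    b.add("C10", "C", "UNL", 100, "L", (16.94, 0.0, 0.0), het=True)
    b.add("C11", "C", "UNL", 100, "L", (18.47, 0.0, 0.0), het=True)
    b.add("C12", "C", "UNL", 100, "L", (20.0, 0.0, 0.0), het=True)
    b.add("CD1", "C", "LEU", 2, "A", (23.7, 0.0, 0.0))
    b.add("CG", "C", "LEU", 2, "A", (25.23, 0.0, 0.0))
    b.add("CB", "C", "LEU", 2, "A", (26.76, 0.0, 0.0))
    truth.interactions.append({"kind": "hydrophobic", "residue": "LEU2A", "distance": 3.7})

    # station 3: parallel pi-stack - ligand benzene under a Phe ring, 3.8 Å / 5 deg
    _add_ligand_ring(b, (40.0, 0.0, 0.0), counter=20)
    for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _hexagon((40.0, 0.0, 3.8), tilt_x_deg=5.0)):
        b.add(name, "C", "PHE", 3, "A", p)
    truth.interactions.append({"kind": "pi_stack", "subtype": "P", "residue": "PHE3A", "distance": 3.8})

    # station 4: T-shaped pi-stack - 5.0 Å / 78 deg
    _add_ligand_ring(b, (60.0, 0.0, 0.0), counter=30)
    for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _hexagon((60.0, 0.0, 5.0), tilt_x_deg=78.0)):
        b.add(name, "C", "PHE", 4, "A", p)
    truth.interactions.append({"kind": "pi_stack", "subtype": "T", "residue": "PHE4A", "distance": 5.0})

    # station 5: pi-cation - Lys NZ 4.0 Å above a ligand benzene centroid
    _add_ligand_ring(b, (80.0, 0.0, 0.0), counter=40)
    b.add("NZ", "N", "LYS", 5, "A", (80.0, 0.0, 4.0))
    b.add("CE", "C", "LYS", 5, "A", (80.0, 0.0, 5.49))
    truth.interactions.append({"kind": "pi_cation", "residue": "LYS5A", "distance": 4.0})

    # station 6: salt bridge - acetate midpoint to Arg guanidinium centroid 3.9 Å
    b.add("C50", "C", "UNL", 100, "L", (97.85, 0.0, 0.0), het=True)
    b.add("C51", "C", "UNL", 100, "L", (99.37, 0.0, 0.0), het=True)
    b.add("O52", "O", "UNL", 100, "L", (100.0, 1.06, 0.0), het=True)
    b.add("O53", "O", "UNL", 100, "L", (100.0, -1.06, 0.0), het=True)
    b.add("NE", "N", "ARG", 6, "A", (102.80, -1.16, 0.0))
    b.add("CZ", "C", "ARG", 6, "A", (103.47, 0.0, 0.0))
    b.add("NH1", "N", "ARG", 6, "A", (104.12, 1.17, 0.0))
    b.add("NH2", "N", "ARG", 6, "A", (104.12, -1.17, 0.0))
    truth.interactions.append({"kind": "salt_bridge", "residue": "ARG6A", "distance": 3.9})

    # station 7: metal coordination - Fe to one catechol oxygen at 2.1 Å
    _add_ligand_ring(b, (120.0, 0.0, 0.0), counter=60, hydroxyls=(0, 1))
    b.add("FE", "FE", "FE", 8, "A", (124.85, 0.0, 0.0), het=True)
    truth.interactions.append({"kind": "metal_coordination", "residue": "FE8A", "distance": 2.1})

    # station 8: single-water bridge - phenol O ... HOH ... Glu OE1 (2.8 / 2.9 Å)
    _, (d8,) = _add_ligand_ring(b, (140.0, 0.0, 0.0), counter=70, hydroxyls=(0,))
    b.add("O", "O", "HOH", 9, "W", (145.55, 0.0, 0.0), het=True)
    b.add("OE1", "O", "GLU", 7, "A", (148.06, 1.45, 0.0))
    b.add("CD", "C", "GLU", 7, "A", (149.06, 2.20, 0.0))
    b.add("OE2", "O", "GLU", 7, "A", (149.26, 3.42, 0.0))
    truth.interactions.append({"kind": "water_bridge", "residue": "GLU7A", "distance": 2.8})

    return b.structure(), truth


def make_bridge_trajectory(n_frames: int = 200, occupancy: float = 0.7,
                           n_bridge_waters: int = 2, seed: int = 0,
                           d_link: float = 2.8) -> tuple[Trajectory, PlantedTruth]:
    """A donor/acceptor pair bridged by a k-water chain in a random subset
    of frames.

    The ligand hydroxyl and a Ser OG sit ``(k+1) * d_link`` apart (always
    beyond direct H-bond range); in ``round(occupancy * n_frames)`` randomly
    chosen frames the chain waters sit on the line between them at
    ``d_link`` spacing, otherwise they are displaced far outside the cutoff.
    Two decoy waters never bridge anything.
    """
    rng = np.random.default_rng(seed)
    k = n_bridge_waters
    b = _Builder()
    _, (donor,) = _add_ligand_ring(b, (0.0, 0.0, 0.0), counter=0, hydroxyls=(0,))
    d0 = donor.coordinates
    chain_positions = [d0 + np.array([d_link * (i + 1), 0.0, 0.0]) for i in range(k)]
    acceptor_xyz = d0 + np.array([d_link * (k + 1), 0.0, 0.0])
    waters = [b.add("O", "O", "HOH", 10 + i, "W", p, het=True) for i, p in enumerate(chain_positions)]
    b.add("OG", "O", "SER", 1, "A", acceptor_xyz)
    b.add("CB", "C", "SER", 1, "A", acceptor_xyz + np.array([1.41, 0.0, 0.0]))
    b.add("O", "O", "HOH", 50, "W", (0.0, 15.0, 0.0), het=True)
    b.add("O", "O", "HOH", 51, "W", (6.0, 15.0, 0.0), het=True)
    topology = b.structure()

    n_present = int(round(occupancy * n_frames))
    present = np.zeros(n_frames, dtype=bool)
    present[rng.choice(n_frames, size=n_present, replace=False)] = True
    base = topology.coordinates()
    water_rows = [w.index for w in waters]
    frames = []
    for f in range(n_frames):
        coords = base.copy()
        if not present[f]:
            coords[water_rows] += np.array([0.0, 0.0, 50.0])
        frames.append(coords)
    truth = PlantedTruth(
        seed=seed,
        bridges=[
            {
                "ligand_node": f"{donor.residue_label}:{donor.name}",
                "protein_node": "SER1A:sc",
                "n_waters": k,
                "occupancy": n_present / n_frames,
                "present_frames": np.flatnonzero(present).tolist(),
            }
        ],
    )
    return Trajectory(topology=topology, frames=frames), truth


def make_water_cloud(blob_specs=((np.zeros(3), 0.3, 40),), noise_n: int = 100,
                     box: float = 20.0, seed: int = 0,
                     n_snapshots: int | None = None) -> tuple[WaterCloud, PlantedTruth]:
    """Gaussian blobs plus uniform noise inside a cubic box.

    ``blob_specs`` is a sequence of (center, sigma, n_points).  Snapshot ids
    cycle 1..n_snapshots over all points (default: one point of each blob
    per snapshot, i.e. n_snapshots = max blob size).
    """
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for bi, (center, sigma, n) in enumerate(blob_specs):
        points.append(rng.normal(loc=np.asarray(center, float), scale=sigma, size=(n, 3)))
        labels += [bi] * n
    if noise_n:
        points.append(rng.uniform(-box / 2, box / 2, size=(noise_n, 3)))
        labels += [-1] * noise_n
    pts = np.vstack(points)
    if n_snapshots is None:
        n_snapshots = max((n for _, _, n in blob_specs), default=1)
    ids = (np.arange(len(pts)) % n_snapshots) + 1
    truth = PlantedTruth(
        seed=seed,
        clusters=[
            {"centroid": np.asarray(c, float).tolist(), "sigma": s, "size": n}
            for c, s, n in blob_specs
        ],
    )
    truth.matches["point_labels"] = [int(l) for l in labels]
    return WaterCloud(points=pts, snapshot_ids=ids, n_snapshots=n_snapshots), truth


def make_uniform_pairs(n: int = 50, box: float = 30.0, seed: int = 0,
                       ligand_type: str = "C.3", site_type: str = "C.3"):
    """Uniform random typed atoms as the null model for the pair RDF.

    Returns (ligand_typed, site_typed): n//2 ligand-context atoms and
    n - n//2 protein-context atoms uniformly placed in a cubic box.
    """
    from phenolig.atom_types import TypedAtom

    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, box, size=(n, 3))
    b = _Builder()
    typed_lig, typed_site = [], []
    for i in range(n // 2):
        a = b.add(f"C{i}", "C", "UNL", 100, "L", xyz[i], het=True)
        typed_lig.append(TypedAtom(a, ligand_type, "lig"))
    for i in range(n // 2, n):
        a = b.add("CB", "C", "ALA", i, "A", xyz[i])
        typed_site.append(TypedAtom(a, site_type, "sc"))
    return typed_lig, typed_site


def reference_ligands():
    """The packaged reference table (name, smiles, class); one prototypical
    member per class plus a few frequently observed polyphenols."""
    return catalog.load_reference()
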
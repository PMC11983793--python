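"""Structures, trajectories and binding sites.

PDB is the only coordinate dialect: single structures are plain PDB files,
trajectories are multi-model PDB files sharing one topology.  Parsing is
delegated to gemmi; this module flattens the hierarchy into simple atom
records, resolves alternate locations, classifies residues into entity
classes (protein / water / metal ion / cofactor / ligand / other) and
extracts ligand binding sites by a distance cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Three-letter codes of the twenty standard amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue names treated as water.
WATER_RESIDUES = frozenset({"HOH", "WAT", "TIP", "TIP3", "TP3", "SPC", "SOL", "DOD"})

#: Residue names that denote a metal ion when the residue has a single atom.
METAL_ION_RESIDUES = frozenset({"NA", "MG", "ZN", "FE", "MN", "NI", "CA", "CU", "K", "FE2", "CO", "CD"})

ENTITY_CLASSES = ("protein", "water", "metal_ion", "cofactor", "ligand", "other")


@dataclass(frozen=True)
class Atom:
    """One atom record of a structure."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    altloc: str
    occupancy: float
    coordinates: np.ndarray
    is_hetatm: bool = False
    index: int = -1  # position within the parent Structure

    def __post_init__(self):
        object.__setattr__(self, "coordinates", np.asarray(self.coordinates, dtype=float))
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")

    @property
    def residue_key(self) -> tuple:
        """Identity of the parent residue (chain, number, insertion code, name)."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.residue_name)

    @property
    def residue_label(self) -> str:
        """Compact residue label, e.g. ``SER117A``."""
        icode = self.insertion_code.strip()
        return f"{self.residue_name}{self.residue_number}{icode}{self.chain_id}"


@dataclass
class Structure:
    """An ordered list of atoms plus a per-residue entity table."""

    atoms: list[Atom]
    entity_table: dict[tuple, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def entity_of(self, atom: Atom) -> str:
        return self.entity_table.get(atom.residue_key, "other")

    def atoms_of_entity(self, entity: str) -> list[Atom]:
        return [a for a in self.atoms if self.entity_of(a) == entity]

    def residues(self) -> dict[tuple, list[Atom]]:
        """Atoms grouped by residue, preserving file order."""
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with every atom moved to ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms")
        atoms = [replace(a, coordinates=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, entity_table=dict(self.entity_table))


@dataclass
class Trajectory:
    """An ordered frame sequence sharing one topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_interval: float | None = None

    def __post_init__(self):
        n = len(self.topology.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: {f.shape[0]} coordinate triplets for {n} topology atoms")
            self.frames[i] = f

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frames[i])


@dataclass
class BindingSite:
    """A ligand and every non-ligand atom within ``radius`` of it."""

    ligand_atoms: list[Atom]
    site_atoms: list[Atom]
    radius: float
    structure: Structure | None = None


# ---------------------------------------------------------------------------
# reading and writing


def _infer_element(name: str, residue_name: str) -> str:
    """Element symbol from an atom label when the element columns are absent."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if residue_name.strip() in METAL_ION_RESIDUES and stripped.upper() == residue_name.strip():
        return stripped.capitalize()
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CU", "NI", "CL", "BR", "SE", "NA"} and len(name.strip()) == len(stripped):
        # two-letter elements are left-justified differently, but for inference
        # we only trust unambiguous metal/halogen prefixes
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _atoms_from_model(model: gemmi.Model, altloc_policy: str) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            picked: dict[str, list[gemmi.Atom]] = {}
            for at in residue:
                picked.setdefault(at.name, []).append(at)
            for name, variants in picked.items():
                if len(variants) > 1 and altloc_policy == "highest_occupancy":
                    # highest occupancy wins; ties go to the lexicographically
                    # first altloc label
                    variants = sorted(variants, key=lambda a: (-a.occ, a.altloc or "~"))
                    keep = variants[:1]
                elif len(variants) > 1 and altloc_policy == "first":
                    keep = variants[:1]
                else:  # "all" or single variant
                    keep = variants
                for at in keep:
                    element = at.element.name if at.element and at.element.name != "X" else ""
                    if not element:
                        element = _infer_element(at.name, residue.name)
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=element,
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            insertion_code=residue.seqid.icode.strip() or "",
                            chain_id=chain.name,
                            altloc=at.altloc or "",
                            occupancy=float(at.occ),
                            coordinates=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            is_hetatm=residue.het_flag == "H",
                            index=len(atoms),
                        )
                    )
    return atoms


def _read_gemmi(path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    st.setup_entities()
    return st


def read_structure(path, model_index: int = 1, altloc_policy: str = "highest_occupancy",
                   cofactor_ids: Iterable[str] = ()) -> Structure:
    """Read one model of a PDB file.

    Parameters
    ----------
    path : str or Path
        PDB file (ATOM/HETATM/MODEL records, wwPDB v3.3 columns).
    model_index : int
        1-based MODEL block to read.
    altloc_policy : {"highest_occupancy", "first", "all"}
        How alternate locations of the same atom are resolved.
    cofactor_ids : iterable of str
        Component identifiers classified as cofactors rather than ligands.
    """
    if altloc_policy not in ("highest_occupancy", "first", "all"):
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    st = _read_gemmi(path)
    if not 1 <= model_index <= len(st):
        raise IndexError(f"model {model_index} not in {path}: file has {len(st)} model(s)")
    atoms = _atoms_from_model(st[model_index - 1], altloc_policy)
    return classify_entities(Structure(atoms=atoms), cofactor_ids=set(cofactor_ids))


def read_trajectory(path, altloc_policy: str = "highest_occupancy",
                    cofactor_ids: Iterable[str] = ()) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one frame per MODEL)."""
    st = _read_gemmi(path)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    topology_atoms = _atoms_from_model(st[0], altloc_policy)
    topology = classify_entities(Structure(atoms=topology_atoms), cofactor_ids=set(cofactor_ids))
    frames = []
    n = len(topology_atoms)
    for i in range(len(st)):
        atoms = _atoms_from_model(st[i], altloc_policy)
        if len(atoms) != n:
            raise ValueError(
                f"{path}: model {i + 1} has {len(atoms)} atoms but the first model has {n}"
            )
        frames.append(np.array([a.coordinates for a in atoms]))
    return Trajectory(topology=topology, frames=frames)


def _format_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.is_hetatm else "ATOM  "
    name = a.name
    # column rules: element symbols of one letter start in column 14
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coordinates
    return (
        f"{record}{serial:>5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:>3s} "
        f"{a.chain_id[:1]:1s}{a.residue_number:>4d}{a.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
        f"{a.element.upper():>2s}"
    )


def write_structure(structure: Structure, path) -> None:
    """Write a structure as a single-model PDB file."""
    lines = [_format_atom_line(a, i + 1) for i, a in enumerate(structure.atoms)]
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    out = []
    for m, frame in enumerate(trajectory.frames, start=1):
        out.append(f"MODEL     {m:>4d}")
        st = trajectory.topology.with_coordinates(frame)
        out.extend(_format_atom_line(a, i + 1) for i, a in enumerate(st.atoms))
        out.append("ENDMDL")
    Path(path).write_text("\n".join(out) + "\nEND\n")


# ---------------------------------------------------------------------------
# entity classification and binding sites


def classify_entities(structure: Structure, cofactor_ids: Iterable[str] = ()) -> Structure:
    """Assign each residue to one entity class.

    Waters (HOH/WAT/TIP...) -> water; single-atom residues named after a
    metal -> metal_ion; the twenty standard amino acids -> protein; residues
    on ``cofactor_ids`` -> cofactor; every remaining HETATM residue ->
    ligand.  Anything else falls through to "other" and is logged.
    """
    cofactor_ids = {c.upper() for c in cofactor_ids}
    table: dict[tuple, str] = {}
    for key, atoms in structure.residues().items():
        name = key[3].upper()
        if name in WATER_RESIDUES:
            table[key] = "water"
        elif name in METAL_ION_RESIDUES and len(atoms) == 1:
            table[key] = "metal_ion"
        elif name in STANDARD_AMINO_ACIDS:
            table[key] = "protein"
        elif name in cofactor_ids:
            table[key] = "cofactor"
        elif any(a.is_hetatm for a in atoms):
            table[key] = "ligand"
        else:
            table[key] = "other"
            logger.info("residue %s classified as 'other'", key)
    structure.entity_table = table
    return structure


def extract_binding_site(structure: Structure, ligand_id: str, chain_id: str | None = None,
                         radius: float = 7.5) -> BindingSite:
    """All non-ligand atoms within ``radius`` (inclusive) of any ligand atom.

    ``ligand_id`` is the PDB component identifier of the ligand; waters and
    ions inside the cutoff are part of the site.
    """
    ligand_atoms = [
        a
        for a in structure.atoms
        if a.residue_name.upper() == ligand_id.upper()
        and structure.entity_of(a) == "ligand"
        and (chain_id is None or a.chain_id == chain_id)
    ]
    if not ligand_atoms:
        raise LookupError(f"ligand {ligand_id!r} (chain {chain_id!r}) not found in structure")
    others = [a for a in structure.atoms if a.residue_key not in {la.residue_key for la in ligand_atoms}]
    if radius <= 0 or not others:
        return BindingSite(ligand_atoms=ligand_atoms, site_atoms=[], radius=radius, structure=structure)
    tree = cKDTree(np.array([a.coordinates for a in others]))
    lig_xyz = np.array([a.coordinates for a in ligand_atoms])
    hit = set()
    for neighbors in tree.query_ball_point(lig_xyz, r=radius):
        hit.update(neighbors)
    site_atoms = [others[i] for i in sorted(hit)]
    return BindingSite(ligand_atoms=ligand_atoms, site_atoms=site_atoms, radius=radius, structure=structure)
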
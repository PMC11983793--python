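"""SYBYL-style atom typing with binding-site location context.

Every heavy atom (and polar hydrogen, when present) is assigned a Tripos
SYBYL mol2 chemical type plus a context flag describing where it sits:
protein backbone (``bk``), protein side chain (``sc``), water (``w``),
metal ion (``ion``), cofactor (``cof``) or ligand (``lig``).  Protein atoms
are typed from per-residue templates shipped as an editable text table;
ligand and cofactor atoms are typed from perceived connectivity (covalent
radii) and ring geometry, so the module works on bare heavy-atom PDB input
without chemical dictionaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from phenolig.structures import Atom, Structure

logger = logging.getLogger(__name__)

SYBYL_TYPES = frozenset(
    "C.3 C.2 C.ar C.1 N.4 N.3 N.2 N.1 N.ar N.am N.pl3 O.3 O.2 O.co2 S.3 S.2 S.o P.3 H.don M".split()
)
CONTEXTS = ("bk", "sc", "w", "ion", "cof", "lig")

#: Single-bond covalent radii (Å) for bond perception.
_COVALENT_RADII = {
    "H": 0.37, "C": 0.77, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.64, "CL": 0.99, "BR": 1.14, "I": 1.33, "SE": 1.17, "B": 0.82,
}
_BOND_TOLERANCE = 0.40


@dataclass(frozen=True)
class TypedAtom:
    """An atom with its SYBYL chemical type and location context."""

    atom: Atom
    sybyl: str
    context: str

    @property
    def label(self) -> str:
        """Pair-distribution label, e.g. ``O.3_sc`` or ``M_ion``."""
        return f"{self.sybyl}_{self.context}"


def _load_protein_templates(path=None) -> dict[tuple[str, str], tuple[str, str]]:
    if path is None:
        text = resources.files("phenolig.data").joinpath("protein_atom_types.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[str, str], tuple[str, str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, name, sybyl, context = line.split("\t")
        table[(residue, name)] = (sybyl, context)
    return table


_PROTEIN_TEMPLATES = _load_protein_templates()


# ---------------------------------------------------------------------------
# connectivity perception for ligands / cofactors


def _bond_graph(atoms: list[Atom]) -> nx.Graph:
    """Heavy-atom connectivity from covalent radii."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    if len(atoms) < 2:
        return g
    xyz = np.array([a.coordinates for a in atoms])
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(r=2.2):
        ri = _COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
        rj = _COVALENT_RADII.get(atoms[j].element.upper(), 0.77)
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d <= ri + rj + _BOND_TOLERANCE:
            g.add_edge(i, j, length=d)
    return g


def _ring_is_aromatic(atoms: list[Atom], ring: list[int], graph: nx.Graph) -> bool:
    """Planarity plus bond-length heuristics for 5/6-membered C/N/O/S rings."""
    if len(ring) not in (5, 6):
        return False
    elements = {atoms[i].element.upper() for i in ring}
    if not elements <= {"C", "N", "O", "S"}:
        return False
    # every ring atom must have at most 3 heavy neighbors (sp2-compatible)
    if any(graph.degree(i) > 3 for i in ring):
        return False
    xyz = np.array([atoms[i].coordinates for i in ring])
    centered = xyz - xyz.mean(axis=0)
    rms_out_of_plane = np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(ring))
    if rms_out_of_plane > 0.15:
        return False
    # aromatic C-C bonds sit near 1.39 Å; saturated rings near 1.53 Å
    lengths = [
        graph.edges[ring[k], ring[(k + 1) % len(ring)]]["length"]
        for k in range(len(ring))
        if graph.has_edge(ring[k], ring[(k + 1) % len(ring)])
    ]
    return bool(lengths) and float(np.mean(lengths)) < 1.45


@dataclass
class LigandPerception:
    """Connectivity, aromatic rings and carboxylate groups of a ligand."""

    atoms: list[Atom]
    graph: nx.Graph
    aromatic_rings: list[list[int]]
    aromatic_atoms: set[int]
    carboxylate_groups: list[tuple[int, tuple[int, int]]]  # (carbon, (O, O))

    def ring_coordinates(self) -> list[np.ndarray]:
        return [np.array([self.atoms[i].coordinates for i in ring]) for ring in self.aromatic_rings]


def perceive_ligand(atoms: list[Atom]) -> LigandPerception:
    """Perceive bonds, aromatic rings and carboxylates from geometry alone."""
    heavy = [a for a in atoms if a.element.upper() != "H"]
    graph = _bond_graph(heavy)
    rings = [r for r in nx.cycle_basis(graph) if _ring_is_aromatic(heavy, r, graph)]
    aromatic = {i for ring in rings for i in ring}
    carboxylates = []
    for i, a in enumerate(heavy):
        if a.element.upper() != "C":
            continue
        terminal_o = [
            j
            for j in graph.neighbors(i)
            if heavy[j].element.upper() == "O" and graph.degree(j) == 1
        ]
        if len(terminal_o) == 2:
            carboxylates.append((i, (terminal_o[0], terminal_o[1])))
    return LigandPerception(
        atoms=heavy,
        graph=graph,
        aromatic_rings=rings,
        aromatic_atoms=aromatic,
        carboxylate_groups=carboxylates,
    )


def _type_perceived_atom(i: int, p: LigandPerception) -> str:
    a = p.atoms[i]
    el = a.element.upper()
    g = p.graph
    carboxylate_oxygens = {o for _, (o1, o2) in p.carboxylate_groups for o in (o1, o2)}
    if el == "C":
        if i in p.aromatic_atoms:
            return "C.ar"
        if any(c == i for c, _ in p.carboxylate_groups):
            return "C.2"
        for j in g.neighbors(i):
            d = g.edges[i, j]["length"]
            nel = p.atoms[j].element.upper()
            if (nel == "C" and d < 1.38 and j not in p.aromatic_atoms) or (nel in ("O", "N") and d < 1.30):
                return "C.2"
        return "C.3"
    if el == "O":
        if i in carboxylate_oxygens:
            return "O.co2"
        if i in p.aromatic_atoms:
            return "O.3"  # furan-type ring oxygen; closest available core type
        if g.degree(i) >= 2:
            return "O.3"  # ether / ester bridge / hydroxyl with H present
        neighbors = list(g.neighbors(i))
        if neighbors and g.edges[i, neighbors[0]]["length"] < 1.30:
            return "O.2"
        return "O.3"
    if el == "N":
        if i in p.aromatic_atoms:
            return "N.ar"
        if g.degree(i) >= 4:
            return "N.4"
        # amide: bonded to a carbon that carries a short (double-bond) C=O
        for j in g.neighbors(i):
            if p.atoms[j].element.upper() == "C":
                for k in g.neighbors(j):
                    if k != i and p.atoms[k].element.upper() == "O" and g.edges[j, k]["length"] < 1.30:
                        return "N.am"
        if g.degree(i) == 3:
            xyz = np.array([p.atoms[i].coordinates] + [p.atoms[j].coordinates for j in g.neighbors(i)])
            centered = xyz - xyz.mean(axis=0)
            if np.linalg.svd(centered, compute_uv=False)[-1] / 2.0 < 0.1:
                return "N.pl3"
        return "N.3"
    if el == "S":
        return "S.3" if g.degree(i) >= 2 else "S.2"
    if el == "P":
        return "P.3"
    return el.capitalize()


# ---------------------------------------------------------------------------
# public typing operations


def assign_protein_types(structure: Structure, templates=None) -> list[TypedAtom]:
    """Template-driven typing of all protein atoms."""
    templates = templates or _PROTEIN_TEMPLATES
    typed = []
    for a in structure.atoms_of_entity("protein"):
        if a.element.upper() == "H":
            typed.append(TypedAtom(a, "H.don", "sc"))
            continue
        key = (a.residue_name.upper(), a.name)
        if key in templates:
            sybyl, context = templates[key]
            typed.append(TypedAtom(a, sybyl, context))
        else:
            fallback = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3"}.get(a.element.upper(), a.element.capitalize())
            logger.info("no template for %s %s; element fallback %s", a.residue_name, a.name, fallback)
            typed.append(TypedAtom(a, fallback, "sc"))
    return typed


def assign_ligand_types(structure: Structure, entity: str = "ligand") -> list[TypedAtom]:
    """Perception-driven typing of ligand (or cofactor) atoms, per residue."""
    context = {"ligand": "lig", "cofactor": "cof"}[entity]
    typed = []
    by_residue: dict[tuple, list[Atom]] = {}
    for a in structure.atoms_of_entity(entity):
        by_residue.setdefault(a.residue_key, []).append(a)
    for atoms in by_residue.values():
        try:
            p = perceive_ligand(atoms)
            per_atom = {id(p.atoms[i]): _type_perceived_atom(i, p) for i in range(len(p.atoms))}
        except Exception as exc:  # degenerate input: fall back to elements
            logger.warning("ligand perception failed (%s); element fallback", exc)
            per_atom = {}
        for a in atoms:
            if a.element.upper() == "H":
                typed.append(TypedAtom(a, "H.don", context))
            else:
                sybyl = per_atom.get(id(a)) or {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3"}.get(
                    a.element.upper(), a.element.capitalize()
                )
                typed.append(TypedAtom(a, sybyl, context))
    return typed


def assign_env_types(structure: Structure) -> list[TypedAtom]:
    """Waters -> (O.3, w); metal ions -> (M, ion)."""
    typed = []
    for a in structure.atoms_of_entity("water"):
        if a.element.upper() == "O":
            typed.append(TypedAtom(a, "O.3", "w"))
        elif a.element.upper() == "H":
            typed.append(TypedAtom(a, "H.don", "w"))
    for a in structure.atoms_of_entity("metal_ion"):
        typed.append(TypedAtom(a, "M", "ion"))
    return typed


def assign_types(structure: Structure) -> dict[int, TypedAtom]:
    """Type every atom of a classified structure; keyed by atom index."""
    typed = (
        assign_protein_types(structure)
        + assign_ligand_types(structure, "ligand")
        + assign_ligand_types(structure, "cofactor")
        + assign_env_types(structure)
    )
    return {t.atom.index: t for t in typed}
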
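"""Geometric detection of the seven noncovalent interaction types.

Detectors operate on a ligand binding site with typed atoms and mirror the
published default geometric criteria of single-structure interaction
profilers: hydrogen bonds (donor-acceptor <= 4.1 Å, donor angle >= 100 deg
when hydrogens are present), hydrophobic contacts (apolar carbons <= 4.0 Å,
closest contact kept per residue and ligand atom), pi-stacking (centroid
distance <= 5.5 Å, offset <= 2.0 Å, parallel <= 30 deg / T-shaped
60-90 deg), pi-cation (<= 6.0 Å), salt bridges (charge centers <= 5.5 Å,
opposite signs), metal coordination (metal to O/N <= 3.0 Å) and
single-water bridges (water H-bond-compatible with both sides, 2.5-4.1 Å).
All thresholds are exposed on :class:`ProfilerConfig`.

Two refinement rules keep planted and real geometries from being counted
twice: hydrophobic contacts between two rings already engaged in a detected
pi-stack are dropped, and hydrogen bonds whose partners both belong to the
charged groups of a detected salt bridge are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from phenolig.structures import Atom, BindingSite, Structure, Trajectory, extract_binding_site
from phenolig.atom_types import TypedAtom, assign_types, perceive_ligand

logger = logging.getLogger(__name__)

INTERACTION_KINDS = (
    "hbond",
    "hydrophobic",
    "pi_stack",
    "pi_cation",
    "salt_bridge",
    "metal_coordination",
    "water_bridge",
)

#: Donor-capable and acceptor-capable SYBYL types (heavy-atom convention:
#: hydroxyl and amine heteroatoms are assumed protonated when H is absent).
DONOR_TYPES = frozenset({"O.3", "N.3", "N.4", "N.am", "N.pl3"})
ACCEPTOR_TYPES = frozenset({"O.2", "O.3", "O.co2", "N.ar"})

#: Protein aromatic-ring atom names.
_PROTEIN_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CD2", "CE2"), ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}


@dataclass
class ProfilerConfig:
    """Geometric thresholds (Å / degrees) for all detectors."""

    hbond_dist_max: float = 4.1
    hbond_dist_min: float = 2.5
    hbond_donor_angle_min: float = 100.0
    hydrophobic_dist_max: float = 4.0
    pistack_dist_max: float = 5.5
    pistack_offset_max: float = 2.0
    pistack_angle_parallel_max: float = 30.0
    pistack_angle_tshape_min: float = 60.0
    pistack_angle_tshape_max: float = 90.0
    pication_dist_max: float = 6.0
    saltbridge_dist_max: float = 5.5
    metal_dist_max: float = 3.0
    waterbridge_dist_min: float = 2.5
    waterbridge_dist_max: float = 4.1
    histidine_cationic: bool = False
    refine: bool = True

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, float) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected noncovalent contact."""

    kind: str
    ligand_atoms: tuple[Atom, ...]
    protein_atoms: tuple[Atom, ...]
    residue: str
    distance: float
    angle: float | None = None
    subtype: str | None = None
    water: Atom | None = None

    def sort_key(self) -> tuple:
        return (self.residue, self.kind, round(self.distance, 6), self.subtype or "")


@dataclass
class InteractionProfile:
    records: list[InteractionRecord]
    complex_id: str = ""
    polyphenol_class: str = ""

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.kind] = out.get(r.kind, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "complex_id": self.complex_id,
                "class": self.polyphenol_class,
                "kind": r.kind,
                "residue": r.residue,
                "ligand_atoms": "+".join(a.name for a in r.ligand_atoms),
                "protein_atoms": "+".join(a.name for a in r.protein_atoms),
                "distance": r.distance,
                "angle": r.angle,
                "subtype": r.subtype,
                "water": r.water.residue_label if r.water else None,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site context: typed atoms, rings and charge centers computed once


def _ring_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 2 or s[1] < 0.1 * s[0]:
        raise ValueError("degenerate ring: atoms nearly collinear")
    return centroid, vt[-1]


class SiteContext:
    """Precomputed typing, rings and charge centers for one binding site."""

    def __init__(self, site: BindingSite, typed: dict[int, TypedAtom] | None = None,
                 config: ProfilerConfig | None = None):
        self.site = site
        self.config = config or ProfilerConfig()
        self.config.validate()
        structure = site.structure
        if structure is None:
            raise ValueError("binding site must reference its parent structure")
        self.typed = typed if typed is not None else assign_types(structure)
        ent = structure.entity_of
        self.ligand_atoms = site.ligand_atoms
        self.protein_atoms = [a for a in site.site_atoms if ent(a) == "protein"]
        self.water_oxygens = [
            a for a in site.site_atoms if ent(a) == "water" and a.element.upper() == "O"
        ]
        self.metals = [a for a in site.site_atoms if ent(a) == "metal_ion"]
        self.hydrogens = {
            e: [a for a in atoms if a.element.upper() == "H"]
            for e, atoms in (("ligand", site.ligand_atoms), ("protein", site.site_atoms))
        }
        self._build_rings()
        self._build_charges()

    # -- typing helpers
    def sybyl(self, a: Atom) -> str:
        t = self.typed.get(a.index)
        return t.sybyl if t else a.element.capitalize()

    def is_donor(self, a: Atom) -> bool:
        return self.sybyl(a) in DONOR_TYPES

    def is_acceptor(self, a: Atom) -> bool:
        return self.sybyl(a) in ACCEPTOR_TYPES

    def is_polar(self, a: Atom) -> bool:
        return self.is_donor(a) or self.is_acceptor(a)

    def is_apolar_carbon(self, a: Atom, pool: list[Atom]) -> bool:
        """Carbon not bonded to any N/O (bond = within 1.9 Å)."""
        if self.sybyl(a) not in ("C.3", "C.ar", "C.2"):
            return False
        for b in pool:
            if b.element.upper() in ("N", "O") and b.residue_key == a.residue_key:
                if np.linalg.norm(a.coordinates - b.coordinates) < 1.9:
                    return False
        return True

    # -- rings
    def _build_rings(self) -> None:
        self.ligand_rings: list[tuple[np.ndarray, np.ndarray, tuple[Atom, ...]]] = []
        heavy_ligand = [a for a in self.ligand_atoms if a.element.upper() != "H"]
        perception = perceive_ligand(heavy_ligand)
        for ring in perception.aromatic_rings:
            atoms = tuple(perception.atoms[i] for i in ring)
            coords = np.array([a.coordinates for a in atoms])
            try:
                centroid, normal = _ring_normal(coords)
            except ValueError as exc:
                logger.warning("skipping ligand ring: %s", exc)
                continue
            self.ligand_rings.append((centroid, normal, atoms))
        self.protein_rings: list[tuple[np.ndarray, np.ndarray, tuple[Atom, ...]]] = []
        by_residue: dict[tuple, dict[str, Atom]] = {}
        for a in self.protein_atoms:
            by_residue.setdefault(a.residue_key, {})[a.name] = a
        for key, names in by_residue.items():
            for ring_names in _PROTEIN_RINGS.get(key[3].upper(), []):
                if all(n in names for n in ring_names):
                    atoms = tuple(names[n] for n in ring_names)
                    coords = np.array([a.coordinates for a in atoms])
                    try:
                        centroid, normal = _ring_normal(coords)
                    except ValueError as exc:
                        logger.warning("skipping %s ring: %s", key, exc)
                        continue
                    self.protein_rings.append((centroid, normal, atoms))

    # -- charge centers: (sign, center, atoms, label)
    def _build_charges(self) -> None:
        self.protein_charges: list[tuple[int, np.ndarray, tuple[Atom, ...]]] = []
        by_residue: dict[tuple, dict[str, Atom]] = {}
        for a in self.protein_atoms:
            by_residue.setdefault(a.residue_key, {})[a.name] = a
        for key, names in by_residue.items():
            res = key[3].upper()
            if res == "LYS" and "NZ" in names:
                self.protein_charges.append((+1, names["NZ"].coordinates, (names["NZ"],)))
            elif res == "ARG":
                group = [names[n] for n in ("CZ", "NH1", "NH2", "NE") if n in names]
                center_atoms = [names[n] for n in ("CZ", "NH1", "NH2") if n in names]
                if center_atoms:
                    center = np.mean([a.coordinates for a in center_atoms], axis=0)
                    self.protein_charges.append((+1, center, tuple(group)))
            elif res == "HIS" and self.config.histidine_cationic:
                ring = [names[n] for n in ("CG", "ND1", "CD2", "CE1", "NE2") if n in names]
                if len(ring) == 5:
                    center = np.mean([a.coordinates for a in ring], axis=0)
                    self.protein_charges.append((+1, center, tuple(ring)))
            elif res == "ASP":
                group = [names[n] for n in ("OD1", "OD2") if n in names]
                if len(group) == 2:
                    center = np.mean([a.coordinates for a in group], axis=0)
                    self.protein_charges.append((-1, center, tuple(group)))
            elif res == "GLU":
                group = [names[n] for n in ("OE1", "OE2") if n in names]
                if len(group) == 2:
                    center = np.mean([a.coordinates for a in group], axis=0)
                    self.protein_charges.append((-1, center, tuple(group)))
        # ligand charges: carboxylate oxygens (negative), quaternary N (positive)
        self.ligand_charges: list[tuple[int, np.ndarray, tuple[Atom, ...]]] = []
        heavy = [a for a in self.ligand_atoms if a.element.upper() != "H"]
        perception = perceive_ligand(heavy)
        for c, (o1, o2) in perception.carboxylate_groups:
            a1, a2 = perception.atoms[o1], perception.atoms[o2]
            center = 0.5 * (a1.coordinates + a2.coordinates)
            self.ligand_charges.append((-1, center, (a1, a2)))
        for a in heavy:
            if self.sybyl(a) == "N.4":
                self.ligand_charges.append((+1, a.coordinates, (a,)))


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coordinates - b.coordinates))


def _donor_angle_ok(ctx: SiteContext, donor: Atom, acceptor: Atom, all_atoms: list[Atom]) -> bool:
    """When the donor carries hydrogens, require a D-H...A angle >= threshold."""
    hs = [
        h
        for h in all_atoms
        if h.element.upper() == "H" and np.linalg.norm(h.coordinates - donor.coordinates) < 1.25
    ]
    if not hs:
        return True  # heavy-atom mode: distance criterion alone
    for h in hs:
        v1 = donor.coordinates - h.coordinates
        v2 = acceptor.coordinates - h.coordinates
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
        if ang >= ctx.config.hbond_donor_angle_min:
            return True
    return False


# ---------------------------------------------------------------------------
# detectors


def detect_hbonds(ctx: SiteContext) -> list[InteractionRecord]:
    """Direct ligand-protein hydrogen bonds (heavy-atom distance criterion)."""
    cfg = ctx.config
    records = []
    all_atoms = ctx.ligand_atoms + ctx.site.site_atoms
    for la in ctx.ligand_atoms:
        if not ctx.is_polar(la):
            continue
        for pa in ctx.protein_atoms:
            if not ctx.is_polar(pa):
                continue
            d = _dist(la, pa)
            if not (cfg.hbond_dist_min <= d <= cfg.hbond_dist_max):
                continue
            if ctx.is_donor(la) and ctx.is_acceptor(pa) and _donor_angle_ok(ctx, la, pa, all_atoms):
                subtype = "donor"
            elif ctx.is_donor(pa) and ctx.is_acceptor(la) and _donor_angle_ok(ctx, pa, la, all_atoms):
                subtype = "acceptor"
            else:
                continue
            records.append(
                InteractionRecord(
                    kind="hbond",
                    ligand_atoms=(la,),
                    protein_atoms=(pa,),
                    residue=pa.residue_label,
                    distance=d,
                    subtype=subtype,
                )
            )
    return records


def detect_hydrophobic(ctx: SiteContext) -> list[InteractionRecord]:
    """Apolar carbon contacts; closest protein atom kept per (residue, ligand atom)."""
    cfg = ctx.config
    best: dict[tuple, InteractionRecord] = {}
    lig_pool = ctx.ligand_atoms
    for la in ctx.ligand_atoms:
        if not ctx.is_apolar_carbon(la, lig_pool):
            continue
        for pa in ctx.protein_atoms:
            if not ctx.is_apolar_carbon(pa, ctx.protein_atoms):
                continue
            d = _dist(la, pa)
            if d > cfg.hydrophobic_dist_max:
                continue
            key = (pa.residue_key, la.index)
            rec = InteractionRecord(
                kind="hydrophobic",
                ligand_atoms=(la,),
                protein_atoms=(pa,),
                residue=pa.residue_label,
                distance=d,
            )
            if key not in best or d < best[key].distance:
                best[key] = rec
    return list(best.values())


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(np.clip(cosang, 0, 1)))


def detect_pi_stacking(ctx: SiteContext) -> list[InteractionRecord]:
    cfg = ctx.config
    records = []
    for lc, ln, latoms in ctx.ligand_rings:
        for pc, pn, patoms in ctx.protein_rings:
            v = pc - lc
            d = float(np.linalg.norm(v))
            if d > cfg.pistack_dist_max or d == 0:
                continue
            # lateral offset: in-plane displacement of one centroid seen from
            # the other ring; the smaller of the two projections is used
            off1 = float(np.linalg.norm(v - np.dot(v, ln) * ln))
            off2 = float(np.linalg.norm(v - np.dot(v, pn) * pn))
            if min(off1, off2) > cfg.pistack_offset_max:
                continue
            ang = _interplanar_angle(ln, pn)
            if ang <= cfg.pistack_angle_parallel_max:
                subtype = "P"
            elif cfg.pistack_angle_tshape_min <= ang <= cfg.pistack_angle_tshape_max:
                subtype = "T"
            else:
                continue
            records.append(
                InteractionRecord(
                    kind="pi_stack",
                    ligand_atoms=latoms,
                    protein_atoms=patoms,
                    residue=patoms[0].residue_label,
                    distance=d,
                    angle=ang,
                    subtype=subtype,
                )
            )
    return records


def detect_pi_cation(ctx: SiteContext) -> list[InteractionRecord]:
    cfg = ctx.config
    records = []
    for lc, ln, latoms in ctx.ligand_rings:
        for sign, center, atoms in ctx.protein_charges:
            if sign <= 0:
                continue
            d = float(np.linalg.norm(center - lc))
            if d <= cfg.pication_dist_max:
                records.append(
                    InteractionRecord(
                        kind="pi_cation",
                        ligand_atoms=latoms,
                        protein_atoms=atoms,
                        residue=atoms[0].residue_label,
                        distance=d,
                    )
                )
    return records


def detect_salt_bridges(ctx: SiteContext) -> list[InteractionRecord]:
    cfg = ctx.config
    records = []
    for lsign, lcenter, latoms in ctx.ligand_charges:
        for psign, pcenter, patoms in ctx.protein_charges:
            if lsign * psign >= 0:
                continue  # same sign: no bridge
            d = float(np.linalg.norm(lcenter - pcenter))
            if d <= cfg.saltbridge_dist_max:
                records.append(
                    InteractionRecord(
                        kind="salt_bridge",
                        ligand_atoms=latoms,
                        protein_atoms=patoms,
                        residue=patoms[0].residue_label,
                        distance=d,
                    )
                )
    return records


def detect_metal_coordination(ctx: SiteContext) -> tuple[list[InteractionRecord], dict[int, dict]]:
    """Metal-to-O/N contacts plus per-metal coordination number and geometry label."""
    cfg = ctx.config
    records = []
    coordination: dict[int, dict] = {}
    geometry_names = {4: "tetrahedral-like", 5: "trigonal-bipyramidal-like", 6: "octahedral-like"}
    for metal in ctx.metals:
        partners = []
        for a in ctx.ligand_atoms + ctx.protein_atoms + ctx.water_oxygens:
            if a.element.upper() not in ("O", "N"):
                continue
            d = _dist(metal, a)
            if d <= cfg.metal_dist_max:
                partners.append((a, d))
        coordination[metal.index] = {
            "metal": metal.residue_label,
            "coordination_number": len(partners),
            "geometry": geometry_names.get(len(partners), "irregular"),
        }
        for a, d in partners:
            is_ligand = a in ctx.ligand_atoms
            records.append(
                InteractionRecord(
                    kind="metal_coordination",
                    ligand_atoms=(a,) if is_ligand else (),
                    protein_atoms=(a,) if not is_ligand else (),
                    residue=metal.residue_label,
                    distance=d,
                    subtype=f"CN{len(partners)}",
                )
            )
    return records, coordination


def detect_water_bridges_single(ctx: SiteContext) -> list[InteractionRecord]:
    """One-water bridges: water O H-bond-compatible with both sides."""
    cfg = ctx.config
    lo, hi = cfg.waterbridge_dist_min, cfg.waterbridge_dist_max
    records = []
    for w in ctx.water_oxygens:
        lig_partners = [
            la for la in ctx.ligand_atoms if ctx.is_polar(la) and lo <= _dist(w, la) <= hi
        ]
        prot_partners = [
            pa for pa in ctx.protein_atoms if ctx.is_polar(pa) and lo <= _dist(w, pa) <= hi
        ]
        for la in lig_partners:
            for pa in prot_partners:
                records.append(
                    InteractionRecord(
                        kind="water_bridge",
                        ligand_atoms=(la,),
                        protein_atoms=(pa,),
                        residue=pa.residue_label,
                        distance=_dist(w, la),
                        water=w,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# refinement and profiles


def _refine(records: list[InteractionRecord]) -> list[InteractionRecord]:
    stacked_atoms: set[int] = set()
    saltbridge_atoms: set[int] = set()
    for r in records:
        if r.kind == "pi_stack":
            stacked_atoms.update(a.index for a in r.ligand_atoms + r.protein_atoms)
        elif r.kind == "salt_bridge":
            saltbridge_atoms.update(a.index for a in r.ligand_atoms + r.protein_atoms)
    out = []
    for r in records:
        if r.kind == "hydrophobic":
            idx = {a.index for a in r.ligand_atoms + r.protein_atoms}
            if idx <= stacked_atoms:
                continue  # ring-ring contact already counted as a stack
        if r.kind == "hbond":
            idx = {a.index for a in r.ligand_atoms + r.protein_atoms}
            if idx <= saltbridge_atoms:
                continue  # polar contact already counted as a salt bridge
        out.append(r)
    return out


def profile_complex(site: BindingSite, config: ProfilerConfig | None = None,
                    typed: dict[int, TypedAtom] | None = None,
                    complex_id: str = "", polyphenol_class: str = "") -> InteractionProfile:
    """Run all detectors on one binding site; deterministic record order."""
    ctx = SiteContext(site, typed=typed, config=config)
    records = (
        detect_hbonds(ctx)
        + detect_hydrophobic(ctx)
        + detect_pi_stacking(ctx)
        + detect_pi_cation(ctx)
        + detect_salt_bridges(ctx)
        + detect_metal_coordination(ctx)[0]
        + detect_water_bridges_single(ctx)
    )
    if ctx.config.refine:
        records = _refine(records)
    records.sort(key=InteractionRecord.sort_key)
    return InteractionProfile(records=records, complex_id=complex_id, polyphenol_class=polyphenol_class)


def summarize_by_class(profiles: list[InteractionProfile]) -> pd.DataFrame:
    """Per (polyphenol class, interaction kind): count, mean/sd of distance
    and angle, and relative frequency within the class."""
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append(
                {
                    "class": p.polyphenol_class,
                    "kind": r.kind,
                    "distance": r.distance,
                    "angle": r.angle,
                }
            )
    if not rows:
        logger.info("no interaction records to summarize")
        return pd.DataFrame(
            columns=["class", "kind", "count", "mean_distance", "sd_distance",
                     "mean_angle", "sd_angle", "relative_frequency"]
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby(["class", "kind"]).agg(
        count=("distance", "size"),
        mean_distance=("distance", "mean"),
        sd_distance=("distance", lambda s: s.std(ddof=0)),
        mean_angle=("angle", "mean"),
        sd_angle=("angle", lambda s: s.std(ddof=0)),
    ).reset_index()
    totals = grouped.groupby("class")["count"].transform("sum")
    grouped["relative_frequency"] = grouped["count"] / totals
    return grouped


@dataclass
class ContactMap:
    """Per (residue, kind) presence over trajectory frames."""

    presence: pd.DataFrame  # boolean, index (residue, kind), columns = frames
    occupancy: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.presence.astype(int).copy()
        out["occupancy"] = self.occupancy
        return out


def profile_trajectory(trajectory: Trajectory, ligand_id: str, chain_id: str | None = None,
                       config: ProfilerConfig | None = None, radius: float = 7.5) -> ContactMap:
    """Profile each frame and assemble a time-resolved contact map."""
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    presence: dict[tuple[str, str], np.ndarray] = {}
    for f in range(trajectory.n_frames):
        st = trajectory.frame_structure(f)
        site = extract_binding_site(st, ligand_id, chain_id=chain_id, radius=radius)
        profile = profile_complex(site, config=config)
        for r in profile.records:
            key = (r.residue, r.kind)
            if key not in presence:
                presence[key] = np.zeros(trajectory.n_frames, dtype=bool)
            presence[key][f] = True
    index = pd.MultiIndex.from_tuples(sorted(presence), names=["residue", "kind"])
    data = np.array([presence[k] for k in sorted(presence)], dtype=bool)
    df = pd.DataFrame(data, index=index, columns=range(trajectory.n_frames))
    return ContactMap(presence=df, occupancy=df.mean(axis=1))
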
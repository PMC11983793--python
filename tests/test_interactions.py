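import numpy as np
import pytest

from phenolig.atom_types import assign_types
from phenolig.interactions import (
    ProfilerConfig,
    SiteContext,
    detect_hbonds,
    detect_hydrophobic,
    detect_metal_coordination,
    detect_pi_cation,
    detect_pi_stacking,
    detect_salt_bridges,
    detect_water_bridges_single,
    profile_complex,
    profile_trajectory,
    summarize_by_class,
    InteractionProfile,
    InteractionRecord,
)
from phenolig.structures import Trajectory, extract_binding_site
from phenolig.synthetic import _Builder, _add_ligand_ring, _hexagon, make_interaction_zoo


def _ctx(structure, **cfg):
    site = extract_binding_site(structure, "UNL", radius=7.5)
    return SiteContext(site, config=ProfilerConfig(**cfg))


def _hbond_pocket(d, with_h=False, h_angle=160.0, acceptor_only=False):
    b = _Builder()
    _add_ligand_ring(b, (0, 0, 0), counter=0, hydroxyls=(0,))
    og = np.array([2.75 + d, 0.0, 0.0])
    if acceptor_only:
        # Gln carbonyl oxygen (O.2): pure acceptor, so only the
        # ligand-as-donor direction can qualify
        b.add("OE1", "O", "GLN", 1, "A", og)
        b.add("CD", "C", "GLN", 1, "A", og + np.array([1.23, 0.0, 0.0]))
    else:
        b.add("OG", "O", "SER", 1, "A", og)
        b.add("CB", "C", "SER", 1, "A", og + np.array([1.41, 0.0, 0.0]))
    if with_h:
        # ligand hydroxyl hydrogen placed to give the requested D-H...A angle
        ang = np.radians(180.0 - h_angle)
        h = np.array([2.75, 0, 0]) + 0.97 * np.array([np.cos(ang), np.sin(ang), 0.0])
        b.add("H01", "H", "UNL", 100, "L", h, het=True)
    return b.structure()


class TestHBonds:
    def test_detected_at_28(self):
        assert [r.kind for r in detect_hbonds(_ctx(_hbond_pocket(2.8)))] == ["hbond"]

    def test_rejected_beyond_41(self):
        assert detect_hbonds(_ctx(_hbond_pocket(4.2))) == []
        assert len(detect_hbonds(_ctx(_hbond_pocket(4.1)))) == 1

    def test_angle_criterion_with_explicit_hydrogen(self):
        good = _hbond_pocket(2.8, with_h=True, h_angle=160.0, acceptor_only=True)
        bad = _hbond_pocket(2.8, with_h=True, h_angle=80.0, acceptor_only=True)
        assert len(detect_hbonds(_ctx(good))) == 1
        assert detect_hbonds(_ctx(bad)) == []


class TestHydrophobic:
    def test_boundary(self):
        for d, n in ((3.7, 1), (4.0, 1), (4.1, 0)):
            b = _Builder()
            b.add("C10", "C", "UNL", 100, "L", (0, 0, 0), het=True)
            b.add("CD1", "C", "LEU", 1, "A", (d, 0, 0))
            recs = detect_hydrophobic(_ctx(b.structure()))
            assert len(recs) == n, d

    def test_closest_contact_kept_per_residue_and_ligand_atom(self):
        b = _Builder()
        b.add("C10", "C", "UNL", 100, "L", (0, 0, 0), het=True)
        b.add("CD1", "C", "LEU", 1, "A", (3.9, 0, 0))
        b.add("CD2", "C", "LEU", 1, "A", (3.4, 0, 1.0))  # 3.54 Å: closer
        recs = detect_hydrophobic(_ctx(b.structure()))
        assert len(recs) == 1
        assert recs[0].protein_atoms[0].name == "CD2"

    def test_polar_bonded_carbons_excluded(self):
        b = _Builder()
        b.add("C10", "C", "UNL", 100, "L", (0, 0, 0), het=True)
        b.add("O11", "O", "UNL", 100, "L", (1.36, 0, 0), het=True)  # makes C10 polar-bonded
        b.add("CD1", "C", "LEU", 1, "A", (0, 3.7, 0))
        assert detect_hydrophobic(_ctx(b.structure())) == []


def _stack_pocket(dist, tilt):
    b = _Builder()
    _add_ligand_ring(b, (0, 0, 0), counter=0)
    for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _hexagon((0, 0, dist), tilt_x_deg=tilt)):
        b.add(name, "C", "PHE", 1, "A", p)
    return b.structure()


class TestPiStacking:
    @pytest.mark.parametrize("dist,tilt,subtype", [(3.8, 5.0, "P"), (5.0, 78.0, "T")])
    def test_subtypes(self, dist, tilt, subtype):
        recs = detect_pi_stacking(_ctx(_stack_pocket(dist, tilt)))
        assert len(recs) == 1 and recs[0].subtype == subtype
        assert recs[0].angle == pytest.approx(tilt, abs=1e-6)

    def test_angle_between_windows_rejected(self):
        assert detect_pi_stacking(_ctx(_stack_pocket(4.5, 45.0))) == []

    def test_distance_and_offset_limits(self):
        assert detect_pi_stacking(_ctx(_stack_pocket(5.6, 5.0))) == []
        b = _Builder()
        _add_ligand_ring(b, (0, 0, 0), counter=0)
        for name, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
                           _hexagon((2.5, 0, 3.8), tilt_x_deg=0.0)):  # offset 2.5 > 2.0
            b.add(name, "C", "PHE", 1, "A", p)
        assert detect_pi_stacking(_ctx(b.structure())) == []


class TestPiCation:
    @pytest.mark.parametrize("d,n", [(4.0, 1), (6.0, 1), (6.1, 0)])
    def test_distance_window(self, d, n):
        b = _Builder()
        _add_ligand_ring(b, (0, 0, 0), counter=0)
        b.add("NZ", "N", "LYS", 1, "A", (0, 0, d))
        b.add("CE", "C", "LYS", 1, "A", (0, 0, d + 1.49))
        assert len(detect_pi_cation(_ctx(b.structure()))) == n


class TestSaltBridges:
    def test_opposite_signs_required(self):
        b = _Builder()
        # ligand carboxylate near a Glu carboxylate: two anions -> no bridge
        b.add("C50", "C", "UNL", 100, "L", (-2.15, 0, 0), het=True)
        b.add("C51", "C", "UNL", 100, "L", (-0.63, 0, 0), het=True)
        b.add("O52", "O", "UNL", 100, "L", (0, 1.06, 0), het=True)
        b.add("O53", "O", "UNL", 100, "L", (0, -1.06, 0), het=True)
        b.add("OE1", "O", "GLU", 1, "A", (3.0, 1.06, 0))
        b.add("OE2", "O", "GLU", 1, "A", (3.0, -1.06, 0))
        b.add("CD", "C", "GLU", 1, "A", (3.63, 0, 0))
        assert detect_salt_bridges(_ctx(b.structure())) == []

    def test_planted_bridge_detected(self, zoo):
        st, _ = zoo
        recs = detect_salt_bridges(_ctx(st))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.9, abs=0.01)


class TestMetalCoordination:
    def test_six_partners_octahedral(self):
        b = _Builder()
        b.add("FE", "FE", "FE", 1, "A", (0, 0, 0), het=True)
        for i, v in enumerate([(2.1, 0, 0), (-2.1, 0, 0), (0, 2.1, 0), (0, -2.1, 0), (0, 0, 2.1), (0, 0, -2.1)]):
            b.add(f"O{50+i}", "O", "UNL", 100, "L", v, het=True)
        recs, info = detect_metal_coordination(_ctx(b.structure()))
        assert len(recs) == 6
        meta = next(iter(info.values()))
        assert meta["coordination_number"] == 6 and meta["geometry"] == "octahedral-like"

    def test_beyond_cutoff_not_coordinating(self):
        b = _Builder()
        b.add("FE", "FE", "FE", 1, "A", (0, 0, 0), het=True)
        b.add("O50", "O", "UNL", 100, "L", (3.2, 0, 0), het=True)
        recs, info = detect_metal_coordination(_ctx(b.structure()))
        assert recs == [] and next(iter(info.values()))["coordination_number"] == 0


class TestWaterBridges:
    def test_requires_both_sides(self):
        b = _Builder()
        _add_ligand_ring(b, (0, 0, 0), counter=0, hydroxyls=(0,))
        b.add("O", "O", "HOH", 1, "W", (5.55, 0, 0), het=True)  # 2.8 from ligand O only
        assert detect_water_bridges_single(_ctx(b.structure())) == []

    def test_two_planted_bridging_waters(self):
        b = _Builder()
        _add_ligand_ring(b, (0, 0, 0), counter=0, hydroxyls=(0,))
        for i, y in enumerate((2.0, -2.0)):
            w = np.array([4.7, y, 0.0])
            b.add("O", "O", "HOH", 10 + i, "W", w, het=True)
        b.add("OG", "O", "SER", 1, "A", (6.66, 0, 0))
        b.add("CB", "C", "SER", 1, "A", (8.07, 0, 0))
        recs = detect_water_bridges_single(_ctx(b.structure()))
        assert len(recs) == 2
        assert {r.water.residue_number for r in recs} == {10, 11}


class TestProfile:
    def test_zoo_yields_exactly_planted_records(self, zoo):
        st, truth = zoo
        prof = profile_complex(extract_binding_site(st, "UNL"))
        assert len(prof.records) == 8
        got = sorted((r.kind, r.residue) for r in prof.records)
        expected = sorted((t["kind"], t["residue"]) for t in truth.interactions)
        assert got == expected
        subtypes = {r.residue: r.subtype for r in prof.records if r.kind == "pi_stack"}
        assert subtypes == {"PHE3A": "P", "PHE4A": "T"}

    def test_removing_hydrophobic_partner_drops_one_record(self, zoo):
        st, _ = zoo
        coords = st.coordinates()
        idx = next(a.index for a in st.atoms if a.residue_label == "LEU2A" and a.name == "CD1")
        coords[idx, 0] += 0.8  # 3.7 -> 4.5 Å
        moved = st.with_coordinates(coords)
        prof = profile_complex(extract_binding_site(moved, "UNL"))
        assert len(prof.records) == 7
        assert "hydrophobic" not in prof.counts()

    def test_rigid_motion_invariance(self, zoo):
        from scipy.spatial.transform import Rotation

        st, _ = zoo
        rot = Rotation.from_euler("zyx", [31.0, -54.0, 12.0], degrees=True).as_matrix()
        moved = st.with_coordinates(st.coordinates() @ rot.T + np.array([11.0, -3.0, 42.0]))
        a = profile_complex(extract_binding_site(st, "UNL"))
        b = profile_complex(extract_binding_site(moved, "UNL"))
        assert [r.sort_key()[:3] for r in a.records] == [
            (k, kk, pytest.approx(dd, abs=1e-6)) for k, kk, dd, _ in (r.sort_key() for r in b.records)
        ]

    def test_detectors_match_exhaustive_enumeration(self, zoo):
        """Independent brute-force oracle for H-bond and hydrophobic pairs."""
        st, _ = zoo
        site = extract_binding_site(st, "UNL")
        typed = assign_types(st)
        donors = {"O.3", "N.3", "N.4", "N.am", "N.pl3"}
        acceptors = {"O.2", "O.3", "O.co2", "N.ar"}
        prot = [a for a in site.site_atoms if st.entity_of(a) == "protein"]
        expected_hb = set()
        for la in site.ligand_atoms:
            for pa in prot:
                d = np.linalg.norm(la.coordinates - pa.coordinates)
                tl, tp = typed[la.index].sybyl, typed[pa.index].sybyl
                if 2.5 <= d <= 4.1 and (
                    (tl in donors and tp in acceptors) or (tp in donors and tl in acceptors)
                ):
                    expected_hb.add((la.index, pa.index))
        ctx = SiteContext(site)
        got_hb = {(r.ligand_atoms[0].index, r.protein_atoms[0].index) for r in detect_hbonds(ctx)}
        assert got_hb == expected_hb


class TestSummaries:
    def _profile(self, cls, records):
        return InteractionProfile(records=records, complex_id=cls, polyphenol_class=cls)

    def _rec(self, kind, d, residue="ALA1A"):
        return InteractionRecord(kind=kind, ligand_atoms=(), protein_atoms=(),
                                 residue=residue, distance=d)

    def test_single_record_stats(self):
        df = summarize_by_class([self._profile("flavonoid", [self._rec("hbond", 2.8)])])
        row = df.iloc[0]
        assert row["mean_distance"] == 2.8 and row["sd_distance"] == 0.0
        assert row["relative_frequency"] == 1.0

    def test_frequencies_match_planted_proportions(self):
        recs = [self._rec("hbond", 3.0)] * 3 + [self._rec("hydrophobic", 3.7)] * 1
        df = summarize_by_class([self._profile("stilbene", recs)])
        freq = dict(zip(df["kind"], df["relative_frequency"]))
        assert freq == {"hbond": 0.75, "hydrophobic": 0.25}
        assert df.groupby(df["class"])["relative_frequency"].sum().iloc[0] == pytest.approx(1.0)

    def test_empty_input_gives_empty_frame(self):
        assert summarize_by_class([]).empty


class TestTrajectoryProfiles:
    def test_planted_on_off_occupancy(self):
        rng = np.random.default_rng(21)
        b = _Builder()
        b.add("C10", "C", "UNL", 100, "L", (0, 0, 0), het=True)
        b.add("CD1", "C", "LEU", 1, "A", (3.7, 0, 0))
        top = b.structure()
        base = top.coordinates()
        n = 200
        on = np.zeros(n, dtype=bool)
        on[rng.choice(n, size=140, replace=False)] = True
        frames = []
        for f in range(n):
            c = base.copy()
            if not on[f]:
                c[1, 0] = 5.0
            frames.append(c)
        cmap = profile_trajectory(Trajectory(topology=top, frames=frames), "UNL")
        assert cmap.occupancy[("LEU1A", "hydrophobic")] == pytest.approx(0.70)

    def test_always_present_gives_occupancy_one(self, zoo):
        st, _ = zoo
        traj = Trajectory(topology=st, frames=[st.coordinates()] * 3)
        cmap = profile_trajectory(traj, "UNL")
        assert (cmap.occupancy == 1.0).all()

    def test_empty_trajectory_rejected(self, zoo):
        st, _ = zoo
        with pytest.raises(ValueError):
            profile_trajectory(Trajectory(topology=st, frames=[]), "UNL")
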
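import numpy as np
import pytest

from phenolig.structures import write_structure
from phenolig.synthetic import make_interaction_zoo, make_bridge_trajectory


def _pdb_line(record, serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {nm:<4s}{altloc}{resname:>3s} {chain}{resnum:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


@pytest.fixture(scope="session")
def toy_pdb_text():
    """Hand-written three-residue peptide (ALA-SER-TYR, 23 atoms) plus two
    waters: 25 atoms total."""
    lines = []
    serial = 0

    def add(name, resname, chain, resnum, xyz, record="ATOM", element=None):
        nonlocal serial
        serial += 1
        lines.append(_pdb_line(record, serial, name, resname, chain, resnum, *xyz, element=element))

    # idealized local geometry; only counts and classes matter here
    ala = [("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)), ("C", (2.0, 1.4, 0.0)),
           ("O", (1.3, 2.4, 0.0)), ("CB", (2.0, -0.7, 1.2))]
    ser = [("N", (3.3, 1.5, 0.0)), ("CA", (4.0, 2.8, 0.0)), ("C", (5.5, 2.6, 0.0)),
           ("O", (6.1, 1.5, 0.0)), ("CB", (3.6, 3.7, 1.2)), ("OG", (2.2, 3.9, 1.2))]
    tyr = [("N", (6.2, 3.7, 0.0)), ("CA", (7.6, 3.7, 0.3)), ("C", (8.4, 4.9, -0.2)),
           ("O", (7.9, 6.0, -0.4)), ("CB", (8.3, 2.4, -0.2)), ("CG", (9.7, 2.3, 0.3)),
           ("CD1", (10.8, 2.6, -0.5)), ("CD2", (9.9, 1.9, 1.6)), ("CE1", (12.1, 2.5, 0.0)),
           ("CE2", (11.2, 1.8, 2.1)), ("CZ", (12.3, 2.1, 1.3)), ("OH", (13.6, 2.0, 1.8))]
    for name, xyz in ala:
        add(name, "ALA", "A", 1, xyz)
    for name, xyz in ser:
        add(name, "SER", "A", 2, xyz)
    for name, xyz in tyr:
        add(name, "TYR", "A", 3, xyz)
    add("O", "HOH", "W", 101, (5.0, 8.0, 3.0), record="HETATM")
    add("O", "HOH", "W", 102, (9.0, 8.0, 3.0), record="HETATM")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb(tmp_path, toy_pdb_text):
    p = tmp_path / "toy.pdb"
    p.write_text(toy_pdb_text)
    return p


@pytest.fixture(scope="session")
def zoo():
    return make_interaction_zoo(seed=1)


@pytest.fixture
def zoo_pdb(tmp_path, zoo):
    st, _ = zoo
    p = tmp_path / "zoo.pdb"
    write_structure(st, p)
    return p


@pytest.fixture(scope="session")
def bridge_traj():
    return make_bridge_trajectory(n_frames=200, occupancy=0.7, n_bridge_waters=2, seed=7)
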
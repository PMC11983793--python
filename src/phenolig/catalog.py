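"""Polyphenol identification, similarity screening and classification.

Ligands given as SMILES are matched against a reference list of polyphenols
by Tanimoto similarity of linear-path fingerprints (all bond paths of length
1-7 hashed to 1024 bits - the classic path-fingerprint construction).  A
ligand whose best reference similarity reaches the screening threshold
(default 0.90) is accepted and then classified into one of twelve structural
classes by an ordered list of substructure rules; a curation step removes
trivially simple hits and keeps named borderline compounds.

The exact bit layout of the fingerprint is toolkit-specific, so similarity
values are reproducible within this package; the screening behaviour depends
only on the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.DataStructs import ExplicitBitVect

RDLogger.DisableLog("rdApp.warning")

logger = logging.getLogger(__name__)

POLYPHENOL_CLASSES = (
    "phenolic_acid",
    "flavonoid",
    "hydroxycinnamic_acid_derivative",
    "hydroxybenzene",
    "stilbene",
    "coumarin",
    "coumestan",
    "lignan",
    "naphthoquinone",
    "curcuminoid",
    "chalcone",
    "other",
)

DEFAULT_N_BITS = 1024
DEFAULT_MAX_PATH = 7
DEFAULT_THRESHOLD = 0.90

#: Ordered classification rules.  Each rule is (class, list of SMARTS); every
#: pattern in the list must match.  The first matching rule wins, which
#: resolves scaffold overlaps (a coumestan contains a coumarin-like lactone,
#: every polyphenol contains a phenol, ...).  Patterns are written against
#: RDKit's perceived aromaticity (fused pyranones come out aromatic).
CLASSIFICATION_RULES: list[tuple[str, list[str]]] = [
    # ring lactone + aromatic five-ring oxygen = benzofuranochromenone core
    ("coumestan", ["[#6;R](=O)[#8;R]", "[o;r5]"]),
    ("naphthoquinone", ["O=C1C=CC(=O)c2ccccc21"]),
    ("coumarin", ["O=c1ccc2ccccc2o1"]),
    ("flavonoid", ["O=c1cc(-c2ccccc2)oc2ccccc12"]),  # flavone / flavonol
    ("flavonoid", ["O=c1c(-c2ccccc2)coc2ccccc12"]),  # isoflavone
    ("flavonoid", ["[#6]1(-c2ccccc2)[#8]c2ccccc2[#6][#6]1"]),  # flavan(one/ol)
    ("curcuminoid", ["cC=CC(=O)CC(=O)C=Cc"]),
    ("chalcone", ["cC(=O)C=Cc"]),
    ("stilbene", ["cC=Cc"]),
    ("hydroxycinnamic_acid_derivative", ["cC=CC(=O)[OX2,OX1-]"]),  # acid/ester
    ("hydroxycinnamic_acid_derivative", ["cC=C[CH1]=O"]),  # e.g. coniferaldehyde
    ("hydroxycinnamic_acid_derivative", ["c[CH2][CH2]C(=O)[OX2,OX1-]"]),  # reduced
    ("lignan", ["c[CH2][CH][CH][CH2]c"]),  # dibenzylbutane core
    ("phenolic_acid", ["[OX2,OX1-]C(=O)c1ccccc1"]),
    ("hydroxybenzene", ["[OX2]c"]),  # phenols and aromatic ethers
]

_COMPILED_RULES = [
    (cls, [Chem.MolFromSmarts(s) for s in patterns]) for cls, patterns in CLASSIFICATION_RULES
]
assert all(p is not None for _, ps in _COMPILED_RULES for p in ps)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Sanitized molecular graph with aromaticity perceived."""
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def fingerprint(mol: Chem.Mol, n_bits: int = DEFAULT_N_BITS, max_path: int = DEFAULT_MAX_PATH) -> ExplicitBitVect:
    """Linear-path fingerprint hashing all bond paths of length 1..max_path."""
    return Chem.RDKFingerprint(mol, minPath=1, maxPath=max_path, fpSize=n_bits)


def tanimoto(a: ExplicitBitVect, b: ExplicitBitVect) -> float:
    """|A n B| / |A u B|; defined as 0 when both bit sets are empty."""
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}")
    na, nb = a.GetNumOnBits(), b.GetNumOnBits()
    if na == 0 and nb == 0:
        return 0.0
    common = len(set(a.GetOnBits()) & set(b.GetOnBits()))
    return common / (na + nb - common)


def classify_polyphenol(mol: Chem.Mol, rules=None) -> str:
    """First matching rule wins; no match -> "other"."""
    rules = rules if rules is not None else _COMPILED_RULES
    for cls, patterns in rules:
        if all(mol.HasSubstructMatch(p) for p in patterns):
            return cls
    return "other"


def load_reference(path=None) -> pd.DataFrame:
    """Reference polyphenol list: columns name, smiles, class.

    The packaged default holds one prototypical member of each of the twelve
    classes plus a few frequent compounds; it is a compact stand-in for a
    full polyphenol catalogue and can be replaced by any tab-separated file
    with the same columns.
    """
    if path is None:
        text = resources.files("phenolig.data").joinpath("reference_polyphenols.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smiles, cls = line.split("\t")
        rows.append({"name": name, "smiles": smiles, "class": cls})
    return pd.DataFrame(rows)


def match_ligands(ligands: dict[str, Chem.Mol] | list[tuple[str, Chem.Mol]],
                  reference: pd.DataFrame,
                  threshold: float = DEFAULT_THRESHOLD,
                  n_bits: int = DEFAULT_N_BITS) -> pd.DataFrame:
    """Best-scoring reference per ligand; ligands below threshold excluded.

    Ties go to the reference that appears first in the list.  Returns a
    table with columns ligand_id, reference_name, similarity, class.
    """
    if reference.empty:
        raise ValueError("reference list is empty")
    items = list(ligands.items()) if isinstance(ligands, dict) else list(ligands)
    ref_fps = []
    for _, row in reference.iterrows():
        mol = parse_smiles(row["smiles"])
        ref_fps.append((row["name"], row.get("class", "other"), fingerprint(mol, n_bits=n_bits)))
    rows = []
    for ligand_id, mol in items:
        fp = fingerprint(mol, n_bits=n_bits)
        best = None
        for name, cls, rfp in ref_fps:
            sim = tanimoto(fp, rfp)
            if best is None or sim > best[2]:
                best = (name, cls, sim)
        if best is not None and best[2] >= threshold:
            rows.append(
                {
                    "ligand_id": ligand_id,
                    "reference_name": best[0],
                    "similarity": best[2],
                    "class": classify_polyphenol(mol),
                }
            )
        else:
            logger.info("ligand %s below threshold (best %.3f)", ligand_id, best[2] if best else 0.0)
    return pd.DataFrame(rows, columns=["ligand_id", "reference_name", "similarity", "class"])


def curate(matches: pd.DataFrame, exclude: list[str] = (), retain: list[str] = ()) -> pd.DataFrame:
    """Remove entries on the exclusion list; the retain list wins on conflict.

    Mirrors manual curation of screening hits: trivially simple structures
    (e.g. phenol, benzoic acid) are excluded, while named borderline
    compounds (e.g. cinnamic acid, thymol) are kept regardless of a strict
    polyphenol definition.
    """
    exclude = {e.lower() for e in exclude}
    retain = {r.lower() for r in retain}
    drop = exclude - retain
    keep = ~matches["ligand_id"].str.lower().isin(drop)
    removed = int((~keep).sum())
    if removed:
        logger.info("curation removed %d of %d entries", removed, len(matches))
    return matches[keep].reset_index(drop=True)
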
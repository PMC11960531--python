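"""Residue naming and atom inventories for parent and 2'-modified nucleotides.

Residue names: A/C/G/U parent ribonucleotides, AM/CM/GM/UM 2'-O-methyl,
AF/CF/GF/UF 2'-fluoro, DT DNA thymidine.  Atom names follow PDB
conventions; the 2'-O-methyl carbon is CM2.
"""

from __future__ import annotations

from .dataset import Nucleotide, Sugar

__all__ = [
    "resname_for",
    "base_atoms",
    "sugar_atoms",
    "residue_atoms",
    "element_of",
    "is_polar_h",
    "BASE_RING_ATOMS",
    "GLYCOSIDIC_N",
    "CHI_REF_ATOM",
    "PURINES",
    "PYRIMIDINES",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U", "T"}

_SUGAR_SUFFIX = {Sugar.OH: "", Sugar.OME: "M", Sugar.F: "F", Sugar.DEOXY: None}

#: base (non-sugar) atoms per nucleobase
BASE_ATOMS = {
    "A": ["N9", "C8", "H8", "N7", "C5", "C6", "N6", "H61", "H62", "N1", "C2", "H2", "N3", "C4"],
    "G": ["N9", "C8", "H8", "N7", "C5", "C6", "O6", "N1", "H1", "C2", "N2", "H21", "H22", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "H41", "H42", "C5", "H5", "C6", "H6"],
    "U": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "H5", "C6", "H6"],
    "T": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "C7", "H71", "H72", "H73", "C6", "H6"],
}

#: aromatic ring atoms used for stacking centroids/normals
BASE_RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1", "T": "N1"}
#: fourth atom of the glycosidic torsion chi (O4'-C1'-N-ref)
CHI_REF_ATOM = {"A": "C4", "G": "C4", "C": "C2", "U": "C2", "T": "C2"}

_RING = ["C1'", "H1'", "C2'", "H2'", "C3'", "H3'", "C4'", "H4'", "O4'"]
_BACKBONE_53 = ["P", "OP1", "OP2", "O5'", "C5'", "H5'", "H5''", "O3'"]

_C2_SUBSTITUENT = {
    Sugar.OH: ["O2'", "HO2'"],
    Sugar.OME: ["O2'", "CM2", "HM21", "HM22", "HM23"],
    Sugar.F: ["F2'"],
    Sugar.DEOXY: ["H2''"],
}

POLAR_H = {
    "H1", "H3", "H21", "H22", "H41", "H42", "H61", "H62",
    "HO2'", "HO3'", "HO5'",
}


def resname_for(nt: Nucleotide) -> str:
    if nt.sugar is Sugar.DEOXY:
        return "DT"
    return nt.base + _SUGAR_SUFFIX[nt.sugar]


def base_letter(resname: str) -> str:
    return "T" if resname == "DT" else resname[0]


def base_atoms(resname: str) -> list[str]:
    return list(BASE_ATOMS[base_letter(resname)])


def sugar_atoms(resname: str, five_prime: bool = False, three_prime: bool = False) -> list[str]:
    if resname == "DT":
        sub = _C2_SUBSTITUENT[Sugar.DEOXY]
    else:
        suffix = resname[1:]
        sugar = {"": Sugar.OH, "M": Sugar.OME, "F": Sugar.F}[suffix]
        sub = _C2_SUBSTITUENT[sugar]
    atoms = list(_BACKBONE_53) + list(_RING) + list(sub)
    if five_prime:
        # 5'-terminal residue has a hydroxyl instead of a phosphate
        atoms = [a for a in atoms if a not in ("P", "OP1", "OP2")] + ["HO5'"]
    if three_prime:
        atoms = atoms + ["HO3'"]
    return atoms


def residue_atoms(resname: str, five_prime: bool = False, three_prime: bool = False) -> list[str]:
    return sugar_atoms(resname, five_prime, three_prime) + base_atoms(resname)


def element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def is_polar_h(name: str) -> bool:
    return name in POLAR_H
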
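"""Bundled united-atom residue template library (reduced 54A7-style).

Templates follow the GROMOS united-atom convention: aliphatic hydrogens are
merged into their carbon as CHn pseudo-atoms, while polar and aromatic
hydrogens are explicit atoms (and are later absorbed by graph condensation).
Each template lists atoms with element, atom type name, partial charge,
charge group, formal charge and chirality, plus internal bonds with orders.

Protonation states follow common physiological defaults: Asp and Glu are
deprotonated (-1), Lys and Arg protonated (+1), His is neutral with the
proton on NE2.  Non-natural building blocks needed for lipopeptides are
included: Dab (2,4-diaminobutyric acid, side chain protonated), the
octanoyl N-terminal cap, and D-amino acids via chirality inversion.

The partial charges and bonded parameters here form a reduced fixture
table in the style of GROMOS 54A7 — internally consistent and chemically
sensible, but not the published force field, which is not redistributed.
Bonded type codes are derived deterministically from the atom type codes
of the participating atoms (see :func:`bond_code` and friends), so
independently built molecules always agree on codes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Optional

from .chem_io import ForceFieldTable
from .graph_core import AROMATIC, MolecularGraph

# ---------------------------------------------------------------------------
# atom types (54A7-style names and codes)
# ---------------------------------------------------------------------------

ATOM_TYPES: dict[str, tuple[int, float]] = {  # name -> (code, mass)
    "O": (1, 15.9994),    # carbonyl oxygen
    "OM": (2, 15.9994),   # carboxylate oxygen
    "OA": (3, 15.9994),   # hydroxyl oxygen
    "OE": (4, 15.9994),   # ester oxygen
    "OW": (5, 15.9994),   # water oxygen
    "N": (6, 14.0067),    # amide nitrogen
    "NT": (7, 14.0067),   # terminal amide nitrogen
    "NL": (8, 14.0067),   # protonated amine nitrogen
    "NR": (9, 14.0067),   # aromatic ring nitrogen
    "NZ": (10, 14.0067),  # guanidinium nitrogen
    "NE": (11, 14.0067),  # guanidinium NE
    "C": (12, 12.011),    # bare carbon
    "CH0": (13, 12.011),
    "CH1": (14, 13.019),
    "CH2": (15, 14.027),
    "CH3": (16, 15.035),
    "CH4": (17, 16.043),
    "CH2R": (18, 14.027),  # ring CH2
    "CR1": (19, 13.019),   # aromatic united CH
    "HC": (20, 1.008),     # carbon-bound hydrogen
    "H": (21, 1.008),      # polar hydrogen
    "DUM": (22, 0.0),
    "S": (23, 32.06),
}

TYPE_CODE = {name: code for name, (code, _m) in ATOM_TYPES.items()}
TYPE_NAME = {code: name for name, (code, _m) in ATOM_TYPES.items()}


# ---------------------------------------------------------------------------
# deterministic bonded type-code scheme
# ---------------------------------------------------------------------------
# Codes are composed from the atom type codes of the participating atoms so
# that any two molecules built from this library agree on bonded codes
# without a shared lookup table.  Categories have independent code spaces.

def bond_code(ta: int, tb: int) -> int:
    lo, hi = sorted((ta, tb))
    return lo * 100 + hi


def angle_code(ta: int, tb: int, tc: int) -> int:
    """``tb`` is the central atom type."""
    lo, hi = sorted((ta, tc))
    return tb * 10000 + lo * 100 + hi


def dihedral_code(tb: int, tc: int) -> int:
    """Proper torsions are typed by the central bond's atom types."""
    lo, hi = sorted((tb, tc))
    return lo * 100 + hi


IMPROPER_PLANAR = 1
IMPROPER_TETRAHEDRAL = 2


# reference bond lengths (nm) by element pair / order, for the fixture table
_BOND_LENGTH = {
    (6, 6, 1): 0.153, (6, 6, AROMATIC): 0.139, (6, 6, 2): 0.133,
    (6, 7, 1): 0.147, (6, 7, 2): 0.132, (6, 7, AROMATIC): 0.133,
    (6, 8, 1): 0.143, (6, 8, 2): 0.123,
    (6, 16, 1): 0.178, (16, 16, 1): 0.204,
    (1, 7, 1): 0.100, (1, 8, 1): 0.0972, (1, 16, 1): 0.133, (1, 6, 1): 0.109,
}

_TYPE_ELEMENT = {
    "O": 8, "OM": 8, "OA": 8, "OE": 8, "OW": 8,
    "N": 7, "NT": 7, "NL": 7, "NR": 7, "NZ": 7, "NE": 7,
    "C": 6, "CH0": 6, "CH1": 6, "CH2": 6, "CH3": 6, "CH4": 6, "CH2R": 6, "CR1": 6,
    "HC": 1, "H": 1, "S": 16, "DUM": 1,
}

_SP2_TYPES = {"C", "CR1", "NR", "NZ", "NE", "N", "NT"}


def collect_forcefield(mols, name: str = "reduced-54A7-style") -> ForceFieldTable:
    """Build a force-field table covering exactly the codes used by ``mols``."""
    ff = ForceFieldTable(name=name)
    for tname, (code, mass) in ATOM_TYPES.items():
        # fixture Lennard-Jones parameters: loosely element-scaled
        z = _TYPE_ELEMENT[tname]
        c6 = round(0.002 + 0.0004 * z, 6)
        c12 = round((1.0 + 0.2 * z) * 1e-6, 9)
        ff.atom_types[code] = (tname, mass, c6, c12)
    for mol in mols:
        g = mol.graph
        for (i, j), code in mol.bonds:
            if code is None or code in ff.bond_types:
                continue
            ei, ej = sorted((g.atoms[i].element, g.atoms[j].element))
            order = g.bond_between(i, j).order
            b0 = _BOND_LENGTH.get((ei, ej, order), 0.150)
            ff.bond_types[code] = (3.7e5, b0)
        for (i, j, k), code in mol.angles:
            if code is None or code in ff.angle_types:
                continue
            central = TYPE_NAME.get(mol.atom_types[j], "C")
            theta = 120.0 if central in _SP2_TYPES else 109.5
            ff.angle_types[code] = (450.0, theta)
        for tup, code in mol.dihedrals:
            if code is not None and code not in ff.dihedral_types:
                ff.dihedral_types[code] = (1.0, 0.0, 3)
        for tup, code in mol.impropers:
            if code is not None and code not in ff.improper_types:
                ff.improper_types[code] = (
                    (0.051, 0.0) if code == IMPROPER_PLANAR else (0.102, 35.264))
    return ff


# ---------------------------------------------------------------------------
# residue templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    type_name: str
    charge: float
    group: int
    formal_charge: int = 0
    chirality: Optional[str] = None


@dataclass
class ResidueTemplate:
    """One amino-acid (or cap) building block."""

    name: str
    atoms: list[TemplateAtom]
    bonds: list[tuple[str, str, int]]          # (atom, atom, order code)
    link_n: Optional[str] = "N"                # atom bonding to previous residue
    link_c: Optional[str] = "C"                # atom bonding to next residue

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no atom {name!r}")

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def bond_order(self, a: str, b: str) -> Optional[int]:
        for x, y, o in self.bonds:
            if {x, y} == {a, b}:
                return o
        return None


def _A(name, elem, typ, q, grp, fc=0, chir=None) -> TemplateAtom:
    return TemplateAtom(name, elem, typ, q, grp, fc, chir)


def _backbone(last_group: int, gly: bool = False) -> tuple[list, list]:
    ca_type = "CH2" if gly else "CH1"
    ca_chir = None if gly else "S"
    atoms = [
        _A("N", "N", "N", -0.310, 0),
        _A("H", "H", "H", 0.310, 0),
        _A("CA", "C", ca_type, 0.000, 0, chir=ca_chir),
        _A("C", "C", "C", 0.450, last_group),
        _A("O", "O", "O", -0.450, last_group),
    ]
    bonds = [("N", "H", 1), ("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2)]
    return atoms, bonds


def _residue(name: str, side_atoms, side_bonds, n_groups: int, gly=False) -> ResidueTemplate:
    atoms, bonds = _backbone(n_groups - 1, gly)
    # insert side chain after CA
    atoms = atoms[:3] + list(side_atoms) + atoms[3:]
    if side_atoms:
        bonds = bonds + [("CA", side_atoms[0].name, 1)] + list(side_bonds)
    return ResidueTemplate(name=name, atoms=atoms, bonds=bonds)


def _aromatic_ring(names: list[str]) -> list[tuple[str, str, int]]:
    return [(a, b, AROMATIC) for a, b in zip(names, names[1:] + names[:1])]


def _build_library() -> dict[str, ResidueTemplate]:
    lib: dict[str, ResidueTemplate] = {}

    lib["GLY"] = _residue("GLY", [], [], 2, gly=True)
    lib["ALA"] = _residue("ALA", [_A("CB", "C", "CH3", 0.0, 1)], [], 3)
    lib["VAL"] = _residue(
        "VAL",
        [_A("CB", "C", "CH1", 0.0, 1), _A("CG1", "C", "CH3", 0.0, 1),
         _A("CG2", "C", "CH3", 0.0, 1)],
        [("CB", "CG1", 1), ("CB", "CG2", 1)], 3)
    lib["LEU"] = _residue(
        "LEU",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH1", 0.0, 1),
         _A("CD1", "C", "CH3", 0.0, 1), _A("CD2", "C", "CH3", 0.0, 1)],
        [("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)], 3)
    lib["ILE"] = _residue(
        "ILE",
        [_A("CB", "C", "CH1", 0.0, 1, chir="S"), _A("CG1", "C", "CH2", 0.0, 1),
         _A("CG2", "C", "CH3", 0.0, 1), _A("CD", "C", "CH3", 0.0, 1)],
        [("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD", 1)], 3)
    lib["SER"] = _residue(
        "SER",
        [_A("CB", "C", "CH2", 0.150, 1), _A("OG", "O", "OA", -0.548, 1),
         _A("HG", "H", "H", 0.398, 1)],
        [("CB", "OG", 1), ("OG", "HG", 1)], 3)
    lib["THR"] = _residue(
        "THR",
        [_A("CB", "C", "CH1", 0.150, 1, chir="R"), _A("OG1", "O", "OA", -0.548, 1),
         _A("HG1", "H", "H", 0.398, 1), _A("CG2", "C", "CH3", 0.0, 1)],
        [("CB", "OG1", 1), ("OG1", "HG1", 1), ("CB", "CG2", 1)], 3)
    lib["CYS"] = _residue(
        "CYS",
        [_A("CB", "C", "CH2", 0.150, 1), _A("SG", "S", "S", -0.510, 1),
         _A("HG", "H", "H", 0.360, 1)],
        [("CB", "SG", 1), ("SG", "HG", 1)], 3)
    lib["MET"] = _residue(
        "MET",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.090, 2),
         _A("SD", "S", "S", -0.270, 2), _A("CE", "C", "CH3", 0.180, 2)],
        [("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)], 4)

    phe_ring = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    lib["PHE"] = _residue(
        "PHE",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.0, 1),
         _A("CD1", "C", "C", -0.140, 2), _A("HD1", "H", "HC", 0.140, 2),
         _A("CD2", "C", "C", -0.140, 3), _A("HD2", "H", "HC", 0.140, 3),
         _A("CE1", "C", "C", -0.140, 4), _A("HE1", "H", "HC", 0.140, 4),
         _A("CE2", "C", "C", -0.140, 5), _A("HE2", "H", "HC", 0.140, 5),
         _A("CZ", "C", "C", -0.140, 6), _A("HZ", "H", "HC", 0.140, 6)],
        [("CB", "CG", 1),
         ("CD1", "HD1", 1), ("CD2", "HD2", 1), ("CE1", "HE1", 1),
         ("CE2", "HE2", 1), ("CZ", "HZ", 1)] + _aromatic_ring(phe_ring), 8)
    lib["TYR"] = _residue(
        "TYR",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.0, 1),
         _A("CD1", "C", "C", -0.140, 2), _A("HD1", "H", "HC", 0.140, 2),
         _A("CD2", "C", "C", -0.140, 3), _A("HD2", "H", "HC", 0.140, 3),
         _A("CE1", "C", "C", -0.140, 4), _A("HE1", "H", "HC", 0.140, 4),
         _A("CE2", "C", "C", -0.140, 5), _A("HE2", "H", "HC", 0.140, 5),
         _A("CZ", "C", "C", 0.203, 6), _A("OH", "O", "OA", -0.611, 6),
         _A("HH", "H", "H", 0.408, 6)],
        [("CB", "CG", 1),
         ("CD1", "HD1", 1), ("CD2", "HD2", 1), ("CE1", "HE1", 1),
         ("CE2", "HE2", 1), ("CZ", "OH", 1), ("OH", "HH", 1)]
        + _aromatic_ring(phe_ring), 8)
    lib["TRP"] = _residue(
        "TRP",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.0, 1),
         _A("CD1", "C", "C", -0.140, 2), _A("HD1", "H", "HC", 0.140, 2),
         _A("NE1", "N", "NR", -0.310, 3), _A("HE1", "H", "H", 0.310, 3),
         _A("CE2", "C", "C", 0.0, 3), _A("CD2", "C", "C", 0.0, 3),
         _A("CE3", "C", "C", -0.140, 4), _A("HE3", "H", "HC", 0.140, 4),
         _A("CZ3", "C", "C", -0.140, 5), _A("HZ3", "H", "HC", 0.140, 5),
         _A("CH2", "C", "C", -0.140, 6), _A("HH2", "H", "HC", 0.140, 6),
         _A("CZ2", "C", "C", -0.140, 7), _A("HZ2", "H", "HC", 0.140, 7)],
        [("CB", "CG", 1),
         ("CD1", "HD1", 1), ("NE1", "HE1", 1), ("CE3", "HE3", 1),
         ("CZ3", "HZ3", 1), ("CH2", "HH2", 1), ("CZ2", "HZ2", 1),
         ("CG", "CD1", AROMATIC), ("CD1", "NE1", AROMATIC),
         ("NE1", "CE2", AROMATIC), ("CE2", "CD2", AROMATIC),
         ("CD2", "CG", AROMATIC),
         ("CD2", "CE3", AROMATIC), ("CE3", "CZ3", AROMATIC),
         ("CZ3", "CH2", AROMATIC), ("CH2", "CZ2", AROMATIC),
         ("CZ2", "CE2", AROMATIC)], 9)

    lib["ASP"] = _residue(
        "ASP",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.270, 2),
         _A("OD1", "O", "O", -0.635, 2), _A("OD2", "O", "OM", -0.635, 2, fc=-1)],
        [("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)], 4)
    lib["GLU"] = _residue(
        "GLU",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.0, 1),
         _A("CD", "C", "C", 0.270, 2), _A("OE1", "O", "O", -0.635, 2),
         _A("OE2", "O", "OM", -0.635, 2, fc=-1)],
        [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "OE2", 1)], 4)
    lib["ASN"] = _residue(
        "ASN",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.380, 2),
         _A("OD1", "O", "O", -0.380, 2), _A("ND2", "N", "NT", -0.830, 3),
         _A("HD21", "H", "H", 0.415, 3), _A("HD22", "H", "H", 0.415, 3)],
        [("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1),
         ("ND2", "HD21", 1), ("ND2", "HD22", 1)], 5)
    lib["GLN"] = _residue(
        "GLN",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.0, 1),
         _A("CD", "C", "C", 0.380, 2), _A("OE1", "O", "O", -0.380, 2),
         _A("NE2", "N", "NT", -0.830, 3), _A("HE21", "H", "H", 0.415, 3),
         _A("HE22", "H", "H", 0.415, 3)],
        [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "NE2", 1),
         ("NE2", "HE21", 1), ("NE2", "HE22", 1)], 5)

    his_ring = ["CG", "ND1", "CE1", "NE2", "CD2"]
    lib["HIS"] = _residue(
        "HIS",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "C", 0.0, 2),
         _A("ND1", "N", "NR", -0.540, 2), _A("CE1", "C", "C", 0.380, 2),
         _A("HE1", "H", "HC", 0.160, 2), _A("NE2", "N", "NR", -0.540, 3),
         _A("HE2", "H", "H", 0.300, 3), _A("CD2", "C", "C", 0.100, 3),
         _A("HD2", "H", "HC", 0.140, 3)],
        [("CB", "CG", 1), ("CE1", "HE1", 1), ("NE2", "HE2", 1), ("CD2", "HD2", 1)]
        + _aromatic_ring(his_ring), 5)

    lib["LYS"] = _residue(
        "LYS",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.0, 1),
         _A("CD", "C", "CH2", 0.0, 1), _A("CE", "C", "CH2", 0.127, 2),
         _A("NZ", "N", "NL", 0.129, 2, fc=1), _A("HZ1", "H", "H", 0.248, 2),
         _A("HZ2", "H", "H", 0.248, 2), _A("HZ3", "H", "H", 0.248, 2)],
        [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "CE", 1), ("CE", "NZ", 1),
         ("NZ", "HZ1", 1), ("NZ", "HZ2", 1), ("NZ", "HZ3", 1)], 4)
    lib["ARG"] = _residue(
        "ARG",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.0, 1),
         _A("CD", "C", "CH2", 0.090, 2), _A("NE", "N", "NE", -0.110, 2),
         _A("HE", "H", "H", 0.240, 2), _A("CZ", "C", "C", 0.340, 2),
         _A("NH1", "N", "NZ", -0.260, 2), _A("HH11", "H", "H", 0.240, 2),
         _A("HH12", "H", "H", 0.240, 2), _A("NH2", "N", "NZ", -0.260, 2, fc=1),
         _A("HH21", "H", "H", 0.240, 2), _A("HH22", "H", "H", 0.240, 2)],
        [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "NE", 1), ("NE", "HE", 1),
         ("NE", "CZ", 1), ("CZ", "NH1", 1), ("NH1", "HH11", 1), ("NH1", "HH12", 1),
         ("CZ", "NH2", 2), ("NH2", "HH21", 1), ("NH2", "HH22", 1)], 4)

    # proline: tertiary backbone nitrogen, no amide hydrogen
    lib["PRO"] = ResidueTemplate(
        name="PRO",
        atoms=[
            _A("N", "N", "N", 0.000, 0),
            _A("CA", "C", "CH1", 0.000, 0, chir="S"),
            _A("CB", "C", "CH2R", 0.0, 1),
            _A("CG", "C", "CH2R", 0.0, 1),
            _A("CD", "C", "CH2R", 0.0, 0),
            _A("C", "C", "C", 0.450, 2),
            _A("O", "O", "O", -0.450, 2),
        ],
        bonds=[("N", "CA", 1), ("CA", "CB", 1), ("CB", "CG", 1),
               ("CG", "CD", 1), ("CD", "N", 1), ("CA", "C", 1), ("C", "O", 2)])

    # 2,4-diaminobutyric acid, side-chain amine protonated
    lib["DAB"] = _residue(
        "DAB",
        [_A("CB", "C", "CH2", 0.0, 1), _A("CG", "C", "CH2", 0.127, 2),
         _A("ND", "N", "NL", 0.129, 2, fc=1), _A("HD1", "H", "H", 0.248, 2),
         _A("HD2", "H", "H", 0.248, 2), _A("HD3", "H", "H", 0.248, 2)],
        [("CB", "CG", 1), ("CG", "ND", 1),
         ("ND", "HD1", 1), ("ND", "HD2", 1), ("ND", "HD3", 1)], 4)

    # octanoyl cap: CH3-(CH2)6-C(=O)- acylating the next residue's nitrogen
    lib["OCT"] = ResidueTemplate(
        name="OCT",
        atoms=[_A("C1", "C", "C", 0.450, 0), _A("O1", "O", "O", -0.450, 0)]
              + [_A(f"C{i}", "C", "CH2", 0.0, 1) for i in range(2, 8)]
              + [_A("C8", "C", "CH3", 0.0, 1)],
        bonds=[("C1", "O1", 2)] + [(f"C{i}", f"C{i+1}", 1) for i in range(1, 8)],
        link_n=None, link_c="C1")

    return lib


LIBRARY: dict[str, ResidueTemplate] = _build_library()

THREE_LETTER = {
    "Gly": "GLY", "Ala": "ALA", "Val": "VAL", "Leu": "LEU", "Ile": "ILE",
    "Ser": "SER", "Thr": "THR", "Cys": "CYS", "Met": "MET", "Phe": "PHE",
    "Tyr": "TYR", "Trp": "TRP", "Asp": "ASP", "Glu": "GLU", "Asn": "ASN",
    "Gln": "GLN", "His": "HIS", "Lys": "LYS", "Arg": "ARG", "Pro": "PRO",
    "Dab": "DAB",
}


# ---------------------------------------------------------------------------
# terminal and linkage variants
# ---------------------------------------------------------------------------

def nterm_charged(tpl: ResidueTemplate) -> ResidueTemplate:
    """Protonated N-terminus: NH3+ (NH2+ for proline)."""
    tpl = copy.deepcopy(tpl)
    if tpl.name == "PRO":
        extra = [_A("H1", "H", "H", 0.248, 0), _A("H2", "H", "H", 0.248, 0)]
        new_atoms = []
        for a in tpl.atoms:
            if a.name == "N":
                new_atoms.append(replace(a, type_name="NL", charge=0.104, formal_charge=1))
                new_atoms.extend(extra)
            elif a.name in ("CA", "CD"):
                new_atoms.append(replace(a, charge=0.200))
            else:
                new_atoms.append(a)
        tpl.atoms = new_atoms
        tpl.bonds = tpl.bonds + [("N", "H1", 1), ("N", "H2", 1)]
        return tpl
    extra = [_A(f"H{i}", "H", "H", 0.248, 0) for i in (1, 2, 3)]
    new_atoms = []
    for a in tpl.atoms:
        if a.name == "H":
            continue
        if a.name == "N":
            new_atoms.append(replace(a, type_name="NL", charge=0.129, formal_charge=1))
            new_atoms.extend(extra)
        elif a.name == "CA":
            new_atoms.append(replace(a, charge=0.127))
        else:
            new_atoms.append(a)
    tpl.atoms = new_atoms
    tpl.bonds = [(x, y, o) for x, y, o in tpl.bonds if "H" not in (x, y)] + \
        [("N", f"H{i}", 1) for i in (1, 2, 3)]
    return tpl


def cterm_charged(tpl: ResidueTemplate) -> ResidueTemplate:
    """Deprotonated carboxylate C-terminus (adds OXT)."""
    tpl = copy.deepcopy(tpl)
    new_atoms = []
    for a in tpl.atoms:
        if a.name == "C":
            new_atoms.append(replace(a, charge=0.270))
        elif a.name == "O":
            new_atoms.append(replace(a, type_name="OM", charge=-0.635))
        else:
            new_atoms.append(a)
    grp = tpl.atom("C").group
    new_atoms.append(_A("OXT", "O", "OM", -0.635, grp, fc=-1))
    tpl.atoms = new_atoms
    tpl.bonds = tpl.bonds + [("C", "OXT", 1)]
    return tpl


def sidechain_amide(tpl: ResidueTemplate) -> ResidueTemplate:
    """Dab variant whose side-chain nitrogen forms an amide cross-link."""
    if tpl.name != "DAB":
        raise ValueError(f"side-chain amide variant only defined for DAB, not {tpl.name}")
    tpl = copy.deepcopy(tpl)
    new_atoms = []
    for a in tpl.atoms:
        if a.name in ("HD2", "HD3"):
            continue
        if a.name == "ND":
            new_atoms.append(replace(a, type_name="NT", charge=-0.310, formal_charge=0))
        elif a.name == "HD1":
            new_atoms.append(replace(a, charge=0.310))
        elif a.name == "CG":
            new_atoms.append(replace(a, charge=0.0))
        else:
            new_atoms.append(a)
    tpl.atoms = new_atoms
    tpl.bonds = [(x, y, o) for x, y, o in tpl.bonds if not {x, y} & {"HD2", "HD3"}]
    return tpl


def dextro(tpl: ResidueTemplate) -> ResidueTemplate:
    """D-amino acid: invert the backbone Calpha chirality flag."""
    tpl = copy.deepcopy(tpl)
    tpl.atoms = [replace(a, chirality={"S": "R", "R": "S"}.get(a.chirality))
                 if a.name == "CA" else a for a in tpl.atoms]
    return tpl


# ---------------------------------------------------------------------------
# annotation of bare graphs (PDB input)
# ---------------------------------------------------------------------------

def annotate(mol: MolecularGraph, library: Optional[dict] = None) -> MolecularGraph:
    """Fill in formal charges, chirality and bond orders from templates.

    PDB files carry neither; each atom is looked up by (residue name, atom
    name) and each intra-residue bond by its template order.  Terminal
    variants are detected from atom presence (H1/H2/H3 -> protonated
    N-terminus, OXT -> carboxylate C-terminus).  Inter-residue bonds keep
    order one.  Atoms or residues without a template are left untouched.
    """
    library = library or LIBRARY
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(mol.atoms):
        by_res.setdefault(a.residue_id, []).append(i)
    for (resname, _seq), idxs in by_res.items():
        tpl = library.get(resname.upper())
        if tpl is None:
            continue
        names = {mol.atoms[i].atom_name for i in idxs}
        if {"H1", "H2"} <= names:
            tpl = nterm_charged(tpl)
        if "OXT" in names:
            tpl = cterm_charged(tpl)
        if tpl.name == "DAB" and "HD2" not in names:
            tpl = sidechain_amide(tpl)
        name_to_idx = {mol.atoms[i].atom_name: i for i in idxs}
        for i in idxs:
            try:
                ta = tpl.atom(mol.atoms[i].atom_name)
            except KeyError:
                continue
            mol.atoms[i].formal_charge = ta.formal_charge
            mol.atoms[i].chirality = ta.chirality
        for x, y, order in tpl.bonds:
            if x in name_to_idx and y in name_to_idx:
                bond = mol.bond_between(name_to_idx[x], name_to_idx[y])
                if bond is not None:
                    bond.order = order
    return mol
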
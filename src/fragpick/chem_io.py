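"""File I/O for chemical structures and GROMOS-family parameter sets.

Formats handled:

* PDB (ATOM/HETATM + CONECT) — target molecules.  CONECT records are
  mandatory: without them there is no bond graph to match against.
* GRO — coordinate output.
* GROMOS-style MTB building-block files (``MTBUILDBLSOLUTE`` blocks) —
  already-parameterized source molecules.  The dialect written here carries
  two extra per-atom columns (element, formal charge, chirality) and a bond
  order column so that molecules round-trip without a separate perception
  step; readers of the standard format simply ignore unknown columns.
* GROMOS IFP force-field parameter files (reduced fixture tables).
* GROMACS ITP topology files in the GROMOS dialect (integer type codes).

All graph indices are 0-based in memory; every file format above is
1-based, converted at this boundary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .graph_core import (
    ATOMIC_NUMBER,
    SYMBOL,
    AtomNode,
    BondEdge,
    CondensedMolecularGraph,
    MolecularGraph,
    condense,
)

#: token emitted in output files for parameters the picker could not assign
PLACEHOLDER = "XXX"


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class MissingTypeCodeError(KeyError):
    """A topology references a type code absent from the force-field table."""


# ---------------------------------------------------------------------------
# force-field table
# ---------------------------------------------------------------------------

@dataclass
class ForceFieldTable:
    """Parameter values keyed by integer type code, per term category."""

    name: str = "reduced-54A7-style"
    atom_types: dict[int, tuple] = field(default_factory=dict)      # code -> (name, mass, c6, c12)
    bond_types: dict[int, tuple] = field(default_factory=dict)      # code -> (kb, b0 nm)
    angle_types: dict[int, tuple] = field(default_factory=dict)     # code -> (ka, theta0 deg)
    dihedral_types: dict[int, tuple] = field(default_factory=dict)  # code -> (k, phase deg, mult)
    improper_types: dict[int, tuple] = field(default_factory=dict)  # code -> (k, xi0 deg)

    _CATEGORIES = ("atom", "bond", "angle", "dihedral", "improper")

    def _table(self, category: str) -> dict[int, tuple]:
        return {
            "atom": self.atom_types, "bond": self.bond_types,
            "angle": self.angle_types, "dihedral": self.dihedral_types,
            "improper": self.improper_types,
        }[category]

    def require(self, category: str, code: int) -> tuple:
        table = self._table(category)
        if code not in table:
            raise MissingTypeCodeError(
                f"{category} type code {code} not in force field {self.name!r}"
            )
        return table[code]

    def atom_type_name(self, code: int) -> str:
        return self.require("atom", code)[0]

    def atom_type_mass(self, code: int) -> float:
        return self.require("atom", code)[1]


# ---------------------------------------------------------------------------
# parameterized molecule
# ---------------------------------------------------------------------------

@dataclass
class ParameterizedMolecule:
    """A molecular graph plus per-atom and per-term force-field assignments.

    Bonded terms are stored as ``(atom_tuple, type_code)`` with 0-based
    atom indices; improper tuples put the central atom first.
    """

    graph: MolecularGraph
    atom_types: list[int] = field(default_factory=list)
    charges: list[float] = field(default_factory=list)
    charge_groups: list[int] = field(default_factory=list)
    bonds: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    angles: list[tuple[tuple[int, int, int], int]] = field(default_factory=list)
    dihedrals: list[tuple[tuple[int, int, int, int], int]] = field(default_factory=list)
    impropers: list[tuple[tuple[int, int, int, int], int]] = field(default_factory=list)
    _condensed: Optional[CondensedMolecularGraph] = field(default=None, repr=False)

    @property
    def name(self) -> str:
        return self.graph.name

    def validate(self) -> None:
        n = len(self.graph)
        if not (len(self.atom_types) == len(self.charges) == n):
            raise ValueError(f"{self.name}: per-atom arrays do not match atom count")
        for terms in (self.bonds, self.angles, self.dihedrals, self.impropers):
            for tup, _code in terms:
                for a in tup:
                    if not 0 <= a < n:
                        raise ValueError(f"{self.name}: term {tup} references missing atom")
        total = sum(self.charges)
        if abs(total - round(total)) > 1e-6:
            raise ValueError(f"{self.name}: total charge {total:.6f} is not an integer")

    @property
    def condensed(self) -> CondensedMolecularGraph:
        if self._condensed is None:
            self._condensed = condense(self.graph)
        return self._condensed

    # -- plain-dict serialization (used by athenaeum archives) --------------
    def to_dict(self) -> dict:
        g = self.graph
        return {
            "name": g.name,
            "atoms": [
                [a.atom_name, SYMBOL[a.element], a.formal_charge,
                 a.chirality or "", a.residue_id[0], a.residue_id[1],
                 self.atom_types[i], round(self.charges[i], 5),
                 self.charge_groups[i] if self.charge_groups else 0]
                for i, a in enumerate(g.atoms)
            ],
            "bonds": [[b.i, b.j, b.order, b.stereo or ""] for b in g.bonds],
            "terms": {
                "bond": [[list(t), c] for t, c in self.bonds],
                "angle": [[list(t), c] for t, c in self.angles],
                "dihedral": [[list(t), c] for t, c in self.dihedrals],
                "improper": [[list(t), c] for t, c in self.impropers],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterizedMolecule":
        g = MolecularGraph(name=d["name"])
        types, charges, groups = [], [], []
        for nm, sym, fc, chir, rnm, rsq, tc, q, cg in d["atoms"]:
            g.add_atom(AtomNode(element=ATOMIC_NUMBER[sym.upper()], formal_charge=fc,
                                chirality=chir or None, atom_name=nm,
                                residue_id=(rnm, rsq)))
            types.append(tc)
            charges.append(q)
            groups.append(cg)
        for i, j, order, stereo in d["bonds"]:
            g.add_bond(BondEdge(i, j, order, stereo or None))
        t = d["terms"]
        return cls(
            graph=g, atom_types=types, charges=charges, charge_groups=groups,
            bonds=[(tuple(a), c) for a, c in t["bond"]],
            angles=[(tuple(a), c) for a, c in t["angle"]],
            dihedrals=[(tuple(a), c) for a, c in t["dihedral"]],
            impropers=[(tuple(a), c) for a, c in t["improper"]],
        )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_NAME_ELEMENT = re.compile(r"[A-Z][a-z]?")


def _element_from_name(name: str) -> Optional[int]:
    """PDB atom-name heuristic: try the leading two characters, then one."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return None
    two = stripped[:2].upper()
    # two-letter symbols only when unambiguous (avoid reading CA as calcium)
    if two in ATOMIC_NUMBER and two in ("CL", "BR", "SE", "FE", "ZN", "MG", "NA"):
        return ATOMIC_NUMBER[two]
    one = stripped[0].upper()
    return ATOMIC_NUMBER.get(one)


def read_pdb(path) -> MolecularGraph:
    """Parse ATOM/HETATM and CONECT records into a molecular graph.

    One vertex per atom, one edge per unique CONECT pair (reciprocal and
    duplicate records collapse to a single edge).  Element is taken from
    columns 77-78, falling back to an atom-name heuristic.  Bond orders,
    formal charges and chirality are not stored in PDB files; apply
    :func:`fragpick.templates.annotate` afterwards to fill them in from the
    residue template library.
    """
    path = Path(path)
    mol = MolecularGraph(name=path.stem)
    serial_to_index: dict[int, int] = {}
    pairs: set[tuple[int, int]] = set()
    saw_conect = False
    altloc_seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    altloc = line[16:17].strip()
                    resname = line[17:21].strip()
                    resseq = int(line[22:26])
                    xyz = np.array([float(line[30:38]), float(line[38:46]),
                                    float(line[46:54])]) / 10.0  # A -> nm
                except ValueError as exc:
                    raise ParseError(path, lineno, f"malformed {rec} record: {exc}")
                key = (resname, resseq, name)
                if altloc not in ("", "A"):
                    continue  # first conformer only
                if key in altloc_seen:
                    continue
                altloc_seen.add(key)
                elem_field = line[76:78].strip()
                if elem_field:
                    element = ATOMIC_NUMBER.get(elem_field.upper())
                else:
                    element = _element_from_name(name)
                if element is None:
                    raise ParseError(path, lineno,
                                     f"cannot determine element of atom {name!r}")
                serial_to_index[serial] = mol.add_atom(AtomNode(
                    element=element, atom_name=name,
                    residue_id=(resname, resseq), coordinates=xyz))
            elif rec == "CONECT":
                saw_conect = True
                fields = line[6:].split()
                try:
                    serials = [int(f) for f in fields]
                except ValueError as exc:
                    raise ParseError(path, lineno, f"malformed CONECT record: {exc}")
                if not serials:
                    continue
                a = serials[0]
                for b in serials[1:]:
                    pairs.add((min(a, b), max(a, b)))
    if not saw_conect:
        raise ParseError(path, 0,
                         "no CONECT records: target PDB files must include "
                         "explicit connectivity (CONECT) for every bond")
    for a, b in sorted(pairs):
        if a not in serial_to_index or b not in serial_to_index:
            raise ParseError(path, 0, f"CONECT references unknown serial {a} or {b}")
        mol.add_bond(BondEdge(serial_to_index[a], serial_to_index[b]))
    return mol


def read_bond_orders(path) -> dict[tuple[int, int], int]:
    """Sidecar bond-order file: whitespace table ``serial serial order``."""
    orders: dict[tuple[int, int], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            try:
                a, b, o = line.split()
                orders[(min(int(a), int(b)), max(int(a), int(b)))] = int(o)
            except ValueError as exc:
                raise ParseError(path, lineno, f"malformed bond-order line: {exc}")
    return orders


def apply_bond_orders(mol: MolecularGraph, orders: dict[tuple[int, int], int]) -> None:
    """Apply a sidecar order table (1-based serials) to a freshly read graph."""
    for (a, b), order in orders.items():
        bond = mol.bond_between(a - 1, b - 1)
        if bond is None:
            raise ValueError(f"bond-order override for non-bonded pair {a}-{b}")
        bond.order = order


def write_pdb(mol: MolecularGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"TITLE     {mol.name}\n")
        for i, a in enumerate(mol.atoms):
            xyz = (a.coordinates if a.coordinates is not None else np.zeros(3)) * 10.0
            name = a.atom_name or SYMBOL[a.element]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
            fh.write(
                "ATOM  {serial:5d} {name:4s} {res:<4s}A{seq:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                "{elem:>2s}\n".format(
                    serial=i + 1, name=pdb_name, res=a.residue_id[0][:4],
                    seq=a.residue_id[1], x=xyz[0], y=xyz[1], z=xyz[2],
                    occ=1.0, b=0.0, elem=SYMBOL[a.element][:2].upper()))
        for i in range(len(mol)):
            nbrs = mol.neighbors(i)
            for chunk in range(0, len(nbrs), 4):
                fh.write("CONECT{:5d}".format(i + 1))
                for n in nbrs[chunk:chunk + 4]:
                    fh.write("{:5d}".format(n + 1))
                fh.write("\n")
        fh.write("END\n")


def write_gro(mol: MolecularGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mol.name}\n{len(mol):5d}\n")
        for i, a in enumerate(mol.atoms):
            xyz = a.coordinates if a.coordinates is not None else np.zeros(3)
            fh.write("{:5d}{:<5s}{:>5s}{:5d}{:8.3f}{:8.3f}{:8.3f}\n".format(
                a.residue_id[1] % 100000, a.residue_id[0][:5],
                (a.atom_name or SYMBOL[a.element])[:5], (i + 1) % 100000,
                xyz[0], xyz[1], xyz[2]))
        fh.write("{:10.5f}{:10.5f}{:10.5f}\n".format(5.0, 5.0, 5.0))


# ---------------------------------------------------------------------------
# IFP (force-field parameter tables)
# ---------------------------------------------------------------------------

_IFP_BLOCKS = {
    "ATOMTYPENAME": ("atom_types", 4),
    "BONDSTRETCHTYPECODE": ("bond_types", 3),
    "BONDANGLEBENDTYPECODE": ("angle_types", 3),
    "TORSDIHEDRALTYPECODE": ("dihedral_types", 4),
    "IMPDIHEDRALTYPECODE": ("improper_types", 3),
}


def write_ifp(ff: ForceFieldTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"TITLE\n{ff.name}\nEND\n")
        fh.write("FORCEFIELD\n%s\nEND\n" % ff.name)
        fh.write("ATOMTYPENAME\n# code name mass c6 c12\n")
        for code in sorted(ff.atom_types):
            name, mass, c6, c12 = ff.atom_types[code]
            fh.write(f"{code:6d} {name:<6s} {mass:10.4f} {c6:12.5e} {c12:12.5e}\n")
        fh.write("END\n")
        fh.write("BONDSTRETCHTYPECODE\n# code kb b0\n")
        for code in sorted(ff.bond_types):
            kb, b0 = ff.bond_types[code]
            fh.write(f"{code:8d} {kb:12.5e} {b0:10.5f}\n")
        fh.write("END\n")
        fh.write("BONDANGLEBENDTYPECODE\n# code ka theta0\n")
        for code in sorted(ff.angle_types):
            ka, t0 = ff.angle_types[code]
            fh.write(f"{code:10d} {ka:12.5e} {t0:10.3f}\n")
        fh.write("END\n")
        fh.write("TORSDIHEDRALTYPECODE\n# code k phase multiplicity\n")
        for code in sorted(ff.dihedral_types):
            k, phase, mult = ff.dihedral_types[code]
            fh.write(f"{code:8d} {k:10.4f} {phase:8.2f} {mult:3d}\n")
        fh.write("END\n")
        fh.write("IMPDIHEDRALTYPECODE\n# code k xi0\n")
        for code in sorted(ff.improper_types):
            k, xi0 = ff.improper_types[code]
            fh.write(f"{code:8d} {k:10.4f} {xi0:8.3f}\n")
        fh.write("END\n")


def read_ifp(path) -> ForceFieldTable:
    ff = ForceFieldTable(name=Path(path).stem)
    block = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.split("#")[0].strip()
            if not text:
                continue
            if block is None:
                block = text
                if block not in _IFP_BLOCKS and block not in ("TITLE", "FORCEFIELD"):
                    # tolerate unknown blocks: skip until END
                    pass
                continue
            if text == "END":
                block = None
                continue
            if block == "TITLE":
                continue
            if block == "FORCEFIELD":
                ff.name = text
                continue
            if block not in _IFP_BLOCKS:
                continue
            attr, nfields = _IFP_BLOCKS[block]
            fields = text.split()
            if len(fields) < nfields:
                raise ParseError(path, lineno,
                                 f"{block}: expected {nfields} fields, got {len(fields)}")
            code = int(fields[0])
            if attr == "atom_types":
                ff.atom_types[code] = (fields[1], float(fields[2]),
                                       float(fields[3]), float(fields[4]))
            elif attr == "dihedral_types":
                ff.dihedral_types[code] = (float(fields[1]), float(fields[2]),
                                           int(fields[3]))
            else:
                getattr(ff, attr)[code] = tuple(float(f) for f in fields[1:nfields])
    return ff


# ---------------------------------------------------------------------------
# MTB (building blocks)
# ---------------------------------------------------------------------------

def write_mtb(mols: Sequence[ParameterizedMolecule], path, pool=None) -> None:
    """Write GROMOS-style MTBUILDBLSOLUTE blocks.

    When ``pool`` (a :class:`fragpick.picker.ParameterPool`) is given, the
    full per-element parameter pool is written as comment lines next to
    each assigned value.
    """
    with open(path, "w") as fh:
        fh.write("TITLE\nunited-atom building blocks (reduced 54A7-style fixture)\nEND\n")
        for mol in mols:
            _write_mtb_block(fh, mol, pool)


def _fmt_code(code) -> str:
    return PLACEHOLDER if code is None else str(code)


def _pool_atom_comments(pool, i: int) -> list[str]:
    lines = []
    ap = pool.atoms[i]
    if ap.charges:
        lines.append("# pool charges: " + " ".join(f"{q:.5f}" for q in ap.charges))
        lines.append("# pool types: " + " ".join(
            f"{c}x{n}" for c, n in sorted(ap.types.items())))
    return lines


def _pool_term_comment(pool, category: str, key) -> Optional[str]:
    counter = pool.term_pool(category).get(key)
    if counter:
        return "# pool: " + " ".join(f"{c}x{n}" for c, n in sorted(counter.items()))
    return None


def _write_mtb_block(fh, mol: ParameterizedMolecule, pool=None) -> None:
    g = mol.graph
    fh.write("MTBUILDBLSOLUTE\n# RNME\n%s\n" % (g.name or "MOL"))
    fh.write("# NATOM\n%d\n" % len(g))
    fh.write("# ATOM ANM ELEM FC CHIR RES RSEQ IACM CHARGE CGRP\n")
    for i, a in enumerate(g.atoms):
        code = mol.atom_types[i] if i < len(mol.atom_types) else None
        q = mol.charges[i] if i < len(mol.charges) else None
        cg = mol.charge_groups[i] if mol.charge_groups else i + 1
        fh.write("{:5d} {:<5s} {:<2s} {:3d} {:1s} {:<5s} {:4d} {:>6s} {:>9s} {:4d}\n".format(
            i + 1, a.atom_name or SYMBOL[a.element], SYMBOL[a.element],
            a.formal_charge, a.chirality or "-", a.residue_id[0] or "MOL",
            a.residue_id[1], _fmt_code(code),
            PLACEHOLDER if q is None else f"{q:.5f}", cg))
        if pool is not None:
            for line in _pool_atom_comments(pool, i):
                fh.write(line + "\n")
    fh.write("# NB\n%d\n# IB JB ORDER MCB\n" % len(mol.bonds))
    for (i, j), code in mol.bonds:
        order = g.bond_between(i, j).order if g.bond_between(i, j) else 1
        fh.write("{:5d}{:5d}{:3d} {:>8s}\n".format(i + 1, j + 1, order, _fmt_code(code)))
        if pool is not None:
            c = _pool_term_comment(pool, "bond", (min(i, j), max(i, j)))
            if c:
                fh.write(c + "\n")
    fh.write("# NBA\n%d\n# IB JB KB MCB\n" % len(mol.angles))
    for (i, j, k), code in mol.angles:
        fh.write("{:5d}{:5d}{:5d} {:>10s}\n".format(i + 1, j + 1, k + 1, _fmt_code(code)))
        if pool is not None:
            c = _pool_term_comment(pool, "angle", (j, min(i, k), max(i, k)))
            if c:
                fh.write(c + "\n")
    fh.write("# NIDA\n%d\n# IB JB KB LB MCB\n" % len(mol.impropers))
    for tup, code in mol.impropers:
        fh.write("{:5d}{:5d}{:5d}{:5d} {:>8s}\n".format(*[t + 1 for t in tup],
                                                        _fmt_code(code)))
        if pool is not None:
            c = _pool_term_comment(pool, "improper", (tup[0], frozenset(tup[1:])))
            if c:
                fh.write(c + "\n")
    fh.write("# NDA\n%d\n# IB JB KB LB MCB\n" % len(mol.dihedrals))
    for tup, code in mol.dihedrals:
        fh.write("{:5d}{:5d}{:5d}{:5d} {:>8s}\n".format(*[t + 1 for t in tup],
                                                        _fmt_code(code)))
        if pool is not None:
            b, c_ = tup[1], tup[2]
            c = _pool_term_comment(pool, "dihedral", (min(b, c_), max(b, c_)))
            if c:
                fh.write(c + "\n")
    fh.write("END\n")


def read_mtb(path, ff: Optional[ForceFieldTable] = None) -> list[ParameterizedMolecule]:
    """Parse MTBUILDBLSOLUTE blocks; resolve type codes against ``ff`` if given."""
    mols: list[ParameterizedMolecule] = []
    lines = Path(path).read_text().splitlines()
    i = 0

    def skip_comments(i: int) -> int:
        while i < len(lines) and (not lines[i].strip() or lines[i].lstrip().startswith("#")):
            i += 1
        return i

    while i < len(lines):
        if lines[i].strip() != "MTBUILDBLSOLUTE":
            i += 1
            continue
        i = skip_comments(i + 1)
        name = lines[i].strip()
        i = skip_comments(i + 1)
        try:
            natom = int(lines[i].strip())
        except ValueError:
            raise ParseError(path, i + 1, "expected atom count")
        g = MolecularGraph(name=name)
        mol = ParameterizedMolecule(graph=g)
        i += 1
        for _ in range(natom):
            i = skip_comments(i)
            f = lines[i].split()
            if len(f) < 10:
                raise ParseError(path, i + 1, f"short atom line: {lines[i]!r}")
            _, anm, elem, fc, chir, res, rseq, iacm, q, cg = f[:10]
            g.add_atom(AtomNode(element=ATOMIC_NUMBER[elem.upper()], formal_charge=int(fc),
                                chirality=None if chir == "-" else chir,
                                atom_name=anm, residue_id=(res, int(rseq))))
            code = None if iacm == PLACEHOLDER else int(iacm)
            if code is not None and ff is not None:
                ff.require("atom", code)
            mol.atom_types.append(code)
            mol.charges.append(math.nan if q == PLACEHOLDER else float(q))
            mol.charge_groups.append(int(cg))
            i += 1

        def read_terms(i: int, width: int, category: str):
            i = skip_comments(i)
            try:
                nterm = int(lines[i].strip())
            except ValueError:
                raise ParseError(path, i + 1, f"expected {category} count")
            i += 1
            out = []
            for _ in range(nterm):
                i = skip_comments(i)
                f = lines[i].split()
                idx = tuple(int(x) - 1 for x in f[:width])
                extra = f[width:]
                code_tok = extra[-1]
                code = None if code_tok == PLACEHOLDER else int(code_tok)
                if code is not None and ff is not None:
                    ff.require(category, code)
                out.append((idx, extra, code))
                i += 1
            return i, out

        i, bonds = read_terms(i, 2, "bond")
        for (a, b), extra, code in bonds:
            order = int(extra[0]) if len(extra) > 1 else 1
            g.add_bond(BondEdge(a, b, order=order))
            mol.bonds.append(((a, b), code))
        i, angles = read_terms(i, 3, "angle")
        mol.angles = [(t, c) for t, _x, c in angles]
        i, imps = read_terms(i, 4, "improper")
        mol.impropers = [(t, c) for t, _x, c in imps]
        i, dihs = read_terms(i, 4, "dihedral")
        mol.dihedrals = [(t, c) for t, _x, c in dihs]
        mols.append(mol)
    return mols


# ---------------------------------------------------------------------------
# ITP (GROMACS, GROMOS dialect)
# ---------------------------------------------------------------------------

def write_itp(mol: ParameterizedMolecule, path, ff: Optional[ForceFieldTable] = None,
              pool=None) -> None:
    """Write a GROMACS include topology in the GROMOS dialect.

    Type codes are written as ``gb_N`` / ``ga_N`` / ``gd_N`` / ``gi_N``
    macros; atoms carry the integer atom type code (or its name when a
    force-field table is supplied).  Unassigned parameters are written as
    the placeholder token so the file is visibly incomplete.
    """
    g = mol.graph

    def type_repr(code) -> str:
        if code is None:
            return PLACEHOLDER
        if ff is not None and code in ff.atom_types:
            return ff.atom_type_name(code)
        return str(code)

    with open(path, "w") as fh:
        fh.write("; generated by fragpick\n[ moleculetype ]\n; name nrexcl\n")
        fh.write(f"{g.name or 'MOL'}  3\n\n[ atoms ]\n")
        fh.write(";  nr type resnr residue atom cgnr   charge     mass\n")
        for i, a in enumerate(g.atoms):
            code = mol.atom_types[i]
            q = mol.charges[i]
            mass = ff.atom_type_mass(code) if (ff is not None and code is not None) else 0.0
            qtxt = PLACEHOLDER if q is None or (isinstance(q, float) and math.isnan(q)) \
                else f"{q:9.5f}"
            cg = mol.charge_groups[i] if mol.charge_groups else i + 1
            fh.write("{:5d} {:>5s} {:5d} {:<5s} {:<5s} {:4d} {:>9s} {:9.4f}\n".format(
                i + 1, type_repr(code), a.residue_id[1], a.residue_id[0] or "MOL",
                a.atom_name or SYMBOL[a.element], cg, qtxt, mass))
            if pool is not None:
                for line in _pool_atom_comments(pool, i):
                    fh.write(line.replace("#", ";", 1) + "\n")
        fh.write("\n[ bonds ]\n;  ai   aj funct  type\n")
        for (i, j), code in mol.bonds:
            fh.write("{:5d}{:5d}    2  {}\n".format(
                i + 1, j + 1, PLACEHOLDER if code is None else f"gb_{code}"))
            if pool is not None:
                c = _pool_term_comment(pool, "bond", (min(i, j), max(i, j)))
                if c:
                    fh.write(c.replace("#", ";", 1) + "\n")
        fh.write("\n[ angles ]\n;  ai   aj   ak funct  type\n")
        for (i, j, k), code in mol.angles:
            fh.write("{:5d}{:5d}{:5d}    2  {}\n".format(
                i + 1, j + 1, k + 1, PLACEHOLDER if code is None else f"ga_{code}"))
            if pool is not None:
                c = _pool_term_comment(pool, "angle", (j, min(i, k), max(i, k)))
                if c:
                    fh.write(c.replace("#", ";", 1) + "\n")
        fh.write("\n[ dihedrals ]\n; impropers\n;  ai   aj   ak   al funct  type\n")
        for tup, code in mol.impropers:
            fh.write("{:5d}{:5d}{:5d}{:5d}    2  {}\n".format(
                *[t + 1 for t in tup], PLACEHOLDER if code is None else f"gi_{code}"))
            if pool is not None:
                c = _pool_term_comment(pool, "improper", (tup[0], frozenset(tup[1:])))
                if c:
                    fh.write(c.replace("#", ";", 1) + "\n")
        fh.write("\n[ dihedrals ]\n; propers\n;  ai   aj   ak   al funct  type\n")
        for tup, code in mol.dihedrals:
            fh.write("{:5d}{:5d}{:5d}{:5d}    1  {}\n".format(
                *[t + 1 for t in tup], PLACEHOLDER if code is None else f"gd_{code}"))
            if pool is not None:
                c = _pool_term_comment(pool, "dihedral",
                                       (min(tup[1], tup[2]), max(tup[1], tup[2])))
                if c:
                    fh.write(c.replace("#", ";", 1) + "\n")


_ITP_TYPE_ELEMENT = {
    "O": 8, "OM": 8, "OA": 8, "OE": 8, "OW": 8,
    "N": 7, "NT": 7, "NL": 7, "NR": 7, "NZ": 7, "NE": 7,
    "C": 6, "CH0": 6, "CH1": 6, "CH2": 6, "CH3": 6, "CH4": 6, "CH2R": 6, "CR1": 6,
    "HC": 1, "H": 1, "S": 16,
}


def read_itp(path, ff: Optional[ForceFieldTable] = None) -> ParameterizedMolecule:
    """Parse a GROMOS-dialect ITP file written by :func:`write_itp`.

    ITP files carry parameters, not chemistry: elements are inferred from
    type names and all bond orders default to one.  For full structural
    fidelity read the MTB form instead.
    """
    path = Path(path)
    g = MolecularGraph(name=path.stem)
    mol = ParameterizedMolecule(graph=g)
    section = None
    dihedral_block = 0
    name_to_code = {}
    if ff is not None:
        name_to_code = {v[0].upper(): k for k, v in ff.atom_types.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.split(";")[0].strip()
            if not text:
                continue
            if text.startswith("["):
                m = re.match(r"\[\s*([a-z]+)\s*\]", text)
                if not m:
                    raise ParseError(path, lineno, f"malformed section header {text!r}")
                section = m.group(1)
                if section == "dihedrals":
                    dihedral_block += 1
                continue
            f = text.split()
            if section == "moleculetype":
                g.name = f[0]
            elif section == "atoms":
                _nr, typ, _resnr, res, anm, cg, q = f[:7]
                if typ == PLACEHOLDER:
                    code = None
                elif typ.upper() in name_to_code:
                    code = name_to_code[typ.upper()]
                elif typ.lstrip("-").isdigit():
                    code = int(typ)
                else:
                    code = None
                elem = _ITP_TYPE_ELEMENT.get(typ.upper())
                if elem is None:
                    sym = re.match(r"[A-Za-z]+", anm)
                    elem = ATOMIC_NUMBER.get((sym.group(0)[0] if sym else "C").upper(), 6)
                g.add_atom(AtomNode(element=elem, atom_name=anm,
                                    residue_id=(res, int(f[2]))))
                mol.atom_types.append(code)
                mol.charges.append(math.nan if q == PLACEHOLDER else float(q))
                mol.charge_groups.append(int(cg))
            elif section in ("bonds", "angles", "dihedrals"):
                width = {"bonds": 2, "angles": 3, "dihedrals": 4}[section]
                idx = tuple(int(x) - 1 for x in f[:width])
                tok = f[width + 1] if len(f) > width + 1 else PLACEHOLDER
                code = None if tok == PLACEHOLDER else int(tok.split("_")[-1])
                if section == "bonds":
                    g.add_bond(BondEdge(idx[0], idx[1]))
                    mol.bonds.append((idx, code))
                elif section == "angles":
                    mol.angles.append((idx, code))
                else:
                    funct = int(f[width])
                    if funct == 2:
                        mol.impropers.append((idx, code))
                    else:
                        mol.dihedrals.append((idx, code))
    if ff is not None:
        for cat, terms in (("bond", mol.bonds), ("angle", mol.angles),
                           ("dihedral", mol.dihedrals), ("improper", mol.impropers)):
            for _t, code in terms:
                if code is not None:
                    ff.require(cat, code)
    return mol
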
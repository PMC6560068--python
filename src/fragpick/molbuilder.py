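"""Build parameterized united-atom molecules from peptide sequences.

This is the fixture generator: it assembles molecular graphs and full
GROMOS-style topologies (atoms, bonds, angles, propers, impropers with
deterministic type codes) from the bundled residue template library, so
the whole test corpus — twenty-one fragment-source molecules and three
target peptides — can be reconstructed from sequences alone, with no
external files.

Sequence notation:

* ``Val-Gly-Ser`` — linear peptide, charged termini by default;
* ``cyclo(Asn-Pro-Phe-...)`` — head-to-tail cyclic peptide, no termini;
* ``octanoyl-`` prefix — fatty-acyl N-terminal cap (residue 1 keeps its
  amide hydrogen; no charged N-terminus);
* ``D-Phe`` — D-amino acid (inverted Calpha chirality flag);
* ``Dab(1)- ... -Thr-(1)`` — side-chain-to-backbone amide cross-link: the
  tagged Dab's side-chain nitrogen bonds to the C of the residue carrying
  the trailing tag, closing a branch cycle (the trailing residue is
  amidated rather than a free carboxylate).
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import templates as T
from .chem_io import ParameterizedMolecule
from .graph_core import ATOMIC_NUMBER, AtomNode, BondEdge, MolecularGraph
from .picker import derive_term_tuples


@dataclass
class ResidueSpec:
    name: str                    # template key, e.g. "PHE"
    dextro: bool = False
    link_label: Optional[str] = None   # "(1)" donor tag on this residue


@dataclass
class SequenceSpec:
    """Parsed peptide specification."""

    residues: list[ResidueSpec]
    cyclic: bool = False
    n_cap: Optional[str] = None            # e.g. "OCT"
    crosslink_to: Optional[str] = None     # trailing tag: last residue C -> tagged donor
    charged_termini: bool = True
    name: str = ""


_TOKEN = re.compile(r"^(D-)?([A-Za-z]{3})(\((\d+)\))?$")


def parse_sequence(text: str, name: str = "") -> SequenceSpec:
    """Parse the hyphenated sequence notation described in the module docstring."""
    text = text.strip()
    spec = SequenceSpec(residues=[], name=name or text)
    if text.lower().startswith("cyclo(") and text.endswith(")"):
        spec.cyclic = True
        spec.charged_termini = False
        text = text[len("cyclo("):-1]
    tokens = [t for t in text.split("-") if t != ""]
    # re-join D- prefixes split by the hyphen separator
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        if tokens[i] == "D" and i + 1 < len(tokens):
            merged.append("D-" + tokens[i + 1])
            i += 2
        else:
            merged.append(tokens[i])
            i += 1
    for tok in merged:
        if tok.lower() == "octanoyl":
            spec.n_cap = "OCT"
            spec.charged_termini = False
            continue
        m = re.match(r"^\((\d+)\)$", tok)
        if m:
            spec.crosslink_to = m.group(1)
            continue
        m = _TOKEN.match(tok)
        if not m:
            raise ValueError(f"unrecognized residue token {tok!r}")
        dextro, resname, _g, label = m.group(1), m.group(2), m.group(3), m.group(4)
        key = T.THREE_LETTER.get(resname.capitalize(), resname.upper())
        if key not in T.LIBRARY:
            raise ValueError(f"unknown residue {resname!r}")
        spec.residues.append(ResidueSpec(name=key, dextro=bool(dextro), link_label=label))
    if not spec.residues:
        raise ValueError("empty sequence")
    return spec


def _placeholder_coords(i: int) -> np.ndarray:
    """Deterministic spread-out dummy coordinates (nm) for file output."""
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * math.pi * ((i * golden) % 1.0)
    r = 0.3 + 0.05 * i
    return np.array([r * math.cos(theta), r * math.sin(theta), 0.02 * i])


def build_peptide(spec: SequenceSpec | str, name: str = "") -> ParameterizedMolecule:
    """Assemble a parameterized molecule from a sequence specification."""
    if isinstance(spec, str):
        spec = parse_sequence(spec, name=name)
    n_res = len(spec.residues)
    tpls: list[T.ResidueTemplate] = []
    donor_idx = acceptor_idx = None
    for i, rs in enumerate(spec.residues):
        tpl = copy.deepcopy(T.LIBRARY[rs.name])
        if rs.dextro:
            tpl = T.dextro(tpl)
        if rs.link_label is not None:
            if rs.link_label != spec.crosslink_to:
                raise ValueError(f"cross-link tag ({rs.link_label}) has no partner")
            donor_idx = i
            tpl = T.sidechain_amide(tpl)
        tpls.append(tpl)
    if spec.crosslink_to is not None:
        if donor_idx is None:
            raise ValueError(f"trailing cross-link tag ({spec.crosslink_to}) has no donor")
        acceptor_idx = n_res - 1  # trailing tag: the last residue's C closes the ring
    if spec.charged_termini and not spec.cyclic:
        tpls[0] = T.nterm_charged(tpls[0])
        if acceptor_idx != n_res - 1:
            tpls[-1] = T.cterm_charged(tpls[-1])
    if spec.n_cap is not None:
        tpls.insert(0, copy.deepcopy(T.LIBRARY[spec.n_cap]))

    mol = MolecularGraph(name=spec.name or name)
    pmol = ParameterizedMolecule(graph=mol)
    offset_of: list[dict[str, int]] = []
    group_base = 0
    for seq, tpl in enumerate(tpls, start=1):
        local: dict[str, int] = {}
        for a in tpl.atoms:
            idx = mol.add_atom(AtomNode(
                element=ATOMIC_NUMBER[a.element.upper()],
                formal_charge=a.formal_charge, chirality=a.chirality,
                atom_name=a.name, residue_id=(tpl.name, seq),
                coordinates=_placeholder_coords(len(mol.atoms))))
            local[a.name] = idx
            pmol.atom_types.append(T.TYPE_CODE[a.type_name])
            pmol.charges.append(a.charge)
            pmol.charge_groups.append(group_base + a.group + 1)
        group_base = max(pmol.charge_groups)
        for x, y, order in tpl.bonds:
            mol.add_bond(BondEdge(local[x], local[y], order=order))
        offset_of.append(local)

    def link_atom(res_i: int, which: str) -> int:
        tpl = tpls[res_i]
        nm = tpl.link_c if which == "c" else tpl.link_n
        if nm is None:
            raise ValueError(f"residue {tpl.name} cannot link at its {which.upper()} side")
        return offset_of[res_i][nm]

    for i in range(len(tpls) - 1):
        mol.add_bond(BondEdge(link_atom(i, "c"), link_atom(i + 1, "n"), order=1))
    if spec.cyclic:
        mol.add_bond(BondEdge(link_atom(len(tpls) - 1, "c"), link_atom(0, "n"), order=1))
    if donor_idx is not None:
        cap_shift = 1 if spec.n_cap is not None else 0
        donor = offset_of[donor_idx + cap_shift]["ND"]
        acceptor = link_atom(acceptor_idx + cap_shift, "c")
        mol.add_bond(BondEdge(donor, acceptor, order=1))

    _assign_bonded_terms(pmol)
    pmol.validate()
    return pmol


def _assign_bonded_terms(pmol: ParameterizedMolecule) -> None:
    """Generate bond/angle/dihedral/improper terms with deterministic codes."""
    g = pmol.graph
    bonds, angles, propers, impropers = derive_term_tuples(g)
    t = pmol.atom_types
    pmol.bonds = [((i, j), T.bond_code(t[i], t[j])) for i, j in bonds]
    pmol.angles = [((i, j, k), T.angle_code(t[i], t[j], t[k])) for i, j, k in angles]
    pmol.dihedrals = [(tup, T.dihedral_code(t[tup[1]], t[tup[2]])) for tup in propers]
    imp = []
    for tup in impropers:
        c = tup[0]
        planar = any(g.bond_between(c, n).order != 1 for n in g.neighbors(c)) \
            or g.atoms[c].element == 7
        imp.append((tup, T.IMPROPER_PLANAR if planar else T.IMPROPER_TETRAHEDRAL))
    pmol.impropers = imp


def build_heptane() -> ParameterizedMolecule:
    """United-atom heptane: a seven-vertex path of CH3/CH2 pseudo-atoms."""
    mol = MolecularGraph(name="heptane")
    pmol = ParameterizedMolecule(graph=mol)
    for i in range(7):
        typ = "CH3" if i in (0, 6) else "CH2"
        mol.add_atom(AtomNode(element=6, atom_name=f"C{i + 1}",
                              residue_id=("HEP", 1),
                              coordinates=_placeholder_coords(i)))
        pmol.atom_types.append(T.TYPE_CODE[typ])
        pmol.charges.append(0.0)
        pmol.charge_groups.append(i + 1)
    for i in range(6):
        mol.add_bond(BondEdge(i, i + 1))
    _assign_bonded_terms(pmol)
    pmol.validate()
    return pmol


# ---------------------------------------------------------------------------
# the bundled study set
# ---------------------------------------------------------------------------

#: the nineteen listed tripeptide sequences (central residues cover every
#: natural amino acid except Asp)
TRIPEPTIDE_SEQUENCES = [
    "Val-Gly-Ser", "Trp-Ala-Thr", "Arg-Ser-Trp", "Pro-Thr-Tyr", "Thr-Cys-Val",
    "Ser-Val-Phe", "Ile-Leu-Arg", "Gly-Ile-Val", "Ser-Met-Asp", "Cys-Pro-Trp",
    "Cys-Phe-Lys", "Trp-Tyr-Cys", "Asp-Trp-Leu", "Leu-Glu-Ile", "Ile-Asn-Phe",
    "Trp-Gln-Thr", "Val-His-Ile", "Val-Lys-Met", "Gln-Arg-Gly",
]

#: stand-in for the twentieth tripeptide (Asp is the only residue missing
#: as a central); configurable, always flagged in reports
STANDIN_SEQUENCE = "Gly-Asp-Gly"

TARGET_SEQUENCES = {
    "octapeptide": "Arg-Gly-Ser-Val-Lys-Ser-Trp-Phe",
    "axinellin_a": "cyclo(Asn-Pro-Phe-Thr-Ile-Phe-Pro)",
    "polymyxin_b3": "octanoyl-Dab-Thr-Dab-Dab(1)-Dab-D-Phe-Leu-Dab-Dab-Thr-(1)",
}


def build_source_molecules(standin: Optional[str] = STANDIN_SEQUENCE
                           ) -> list[ParameterizedMolecule]:
    """The fragment-source set: tripeptides (plus optional stand-in) and heptane."""
    seqs = list(TRIPEPTIDE_SEQUENCES)
    if standin:
        seqs.append(standin)
    mols = [build_peptide(s) for s in seqs]
    mols.append(build_heptane())
    return mols


def residue_atom_indices(pmol: ParameterizedMolecule, seq: int) -> list[int]:
    return [i for i, a in enumerate(pmol.graph.atoms) if a.residue_id[1] == seq]


def user_fragments_for_tripeptide(pmol: ParameterizedMolecule) -> list[tuple[list[int], list[int]]]:
    """The user-directed fragment layout for one tripeptide.

    Three fragments: each residue is a core, with the neighboring amine
    and/or carboxo groups as overlap — residue 1 overlaps the amine (N) of
    residue 2, residue 2 overlaps the carboxo (C, O) of residue 1 and the
    amine of residue 3, residue 3 overlaps the carboxo of residue 2.
    """
    name_idx = {}
    for i, a in enumerate(pmol.graph.atoms):
        name_idx[(a.residue_id[1], a.atom_name)] = i
    frags = []
    for seq in (1, 2, 3):
        core = residue_atom_indices(pmol, seq)
        overlap = []
        if seq > 1:
            overlap += [name_idx[(seq - 1, "C")], name_idx[(seq - 1, "O")]]
        if seq < 3:
            overlap += [name_idx[(seq + 1, "N")]]
        frags.append((core, overlap))
    return frags


def user_fragments_for_heptane(pmol: ParameterizedMolecule) -> list[tuple[list[int], list[int]]]:
    """Two heptane fragments: a methyl-terminal triple (overlap: the next
    carbon) and the central triple (overlap: one carbon on either side)."""
    return [([0, 1, 2], [3]), ([2, 3, 4], [1, 5])]


def fragment_spec_text(mols: list[ParameterizedMolecule]) -> str:
    """Render the user fragment specification file for the source set."""
    lines = ["# user-directed fragment specification: one core per residue,",
             "# neighboring amine/carboxo groups as overlap"]
    for pmol in mols:
        if pmol.name == "heptane":
            frags = user_fragments_for_heptane(pmol)
        else:
            frags = user_fragments_for_tripeptide(pmol)
        lines.append(f"molecule {pmol.name}")
        for core, overlap in frags:
            lines.append("core: " + " ".join(str(i + 1) for i in core))
            lines.append("overlap: " + " ".join(str(i + 1) for i in overlap))
    return "\n".join(lines) + "\n"


def build_study_set(standin: Optional[str] = STANDIN_SEQUENCE):
    """Source molecules, user fragment layout, and the three test peptides.

    Returns ``(sources, user_spec, targets)`` where ``user_spec`` is a list
    of ``(molecule name, core atom indices, overlap atom indices)`` and
    ``targets`` maps name -> ParameterizedMolecule (the targets come with
    reference parameters for validation; picking uses only their graphs).
    """
    sources = build_source_molecules(standin)
    user_spec = []
    for pmol in sources:
        frags = (user_fragments_for_heptane(pmol) if pmol.name == "heptane"
                 else user_fragments_for_tripeptide(pmol))
        for core, overlap in frags:
            user_spec.append((pmol.name, core, overlap))
    targets = {name: build_peptide(seq, name=name)
               for name, seq in TARGET_SEQUENCES.items()}
    for t in targets.values():
        t.graph.name = t.graph.name or "target"
    return sources, user_spec, targets


def bare_graph(pmol: ParameterizedMolecule) -> MolecularGraph:
    """A copy of the molecular graph with no parameters attached (a picking
    target as it would arrive from an annotated PDB file)."""
    g = MolecularGraph(name=pmol.graph.name)
    for a in pmol.graph.atoms:
        g.add_atom(AtomNode(element=a.element, formal_charge=a.formal_charge,
                            chirality=a.chirality, atom_name=a.atom_name,
                            residue_id=a.residue_id, coordinates=a.coordinates))
    for b in pmol.graph.bonds:
        g.add_bond(BondEdge(b.i, b.j, order=b.order, stereo=b.stereo))
    return g


def build_user_athenaeum(sources=None, user_spec=None):
    """Assemble the self-consistent user-directed athenaeum."""
    from .athenaeum import Athenaeum

    if sources is None:
        sources, user_spec, _targets = build_study_set()
    ath = Athenaeum(name="user", k=1, self_consistent=True)
    ids = {}
    for pmol in sources:
        ids[pmol.name] = ath.add_molecule(pmol)
    for mol_name, core, overlap in user_spec:
        ath.fragment_from_spec(ids[mol_name], core, overlap)
    ath.rebuild_tree()
    return ath


def build_auto_athenaeum(sources=None, k: int = 1, min_core: int = 2,
                         max_core: Optional[int] = None):
    """Assemble the automatically generated athenaeum (not self-consistent)."""
    from .athenaeum import Athenaeum

    if sources is None:
        sources = build_source_molecules()
    ath = Athenaeum(name="auto", k=k, self_consistent=False)
    for pmol in sources:
        mid = ath.add_molecule(pmol)
        ath.generate_auto(mid, min_core=min_core, max_core=max_core)
    return ath
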
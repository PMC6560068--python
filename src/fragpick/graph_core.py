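"""Molecular graph model, leaf condensation and bit-packed label codec.

A molecule is a simple labeled graph: vertices are atoms (element, formal
charge, chirality), edges are bonds (integer order code, E/Z stereo).  For
subgraph matching the graph is *condensed*: every uncharged hydrogen or
halogen leaf attached by a single bond is absorbed into its parent vertex,
and the parent's label records how many atoms of each condensable element
were absorbed.  Condensed vertex labels pack ten fields into 32 bits and
edge labels pack four fields into 12 bits, so that a masked comparison of
two labels is a single integer equality.

Vertex label layout (least-significant bit first):

    bits  0-6   atomic number (1-118)
    bits  7-9   |formal charge| (0-7)
    bit   10    charge sign (1 = negative)
    bits 11-13  condensed H count     (0-7)
    bits 14-16  condensed F count     (0-7)
    bits 17-19  condensed Cl count    (0-7)
    bits 20-22  condensed Br count    (0-7)
    bits 23-25  condensed I count     (0-7)
    bit   26    member of a simple cycle of length <= 8
    bit   27    R chirality
    bit   28    S chirality
    bits 29-31  vertex degree in the condensed graph (0-7)

Edge label layout:

    bits  0-2   bond order code (1-7; 5 = aromatic, 6 = 1.5, 7 = 2.5)
    bit   3     E stereo
    bit   4     Z stereo
    bit   5     member of a simple cycle of length <= 8
    bits  6-8   smaller endpoint degree (0-7)
    bits  9-11  larger endpoint degree (0-7)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("fragpick")

# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()

ATOMIC_NUMBER = {s.upper(): i + 1 for i, s in enumerate(_SYMBOLS)}
SYMBOL = {i + 1: s for i, s in enumerate(_SYMBOLS)}

#: elements whose uncharged, singly bonded leaves may be condensed, in the
#: order of their count fields (H, then down the halogen column).  Astatine
#: has no count field and is deliberately not condensable.
CONDENSABLE = (1, 9, 17, 35, 53)
_CONDENSABLE_SLOT = {z: i for i, z in enumerate(CONDENSABLE)}

AROMATIC = 5  #: bond order code for aromatic bonds

MAX_CYCLE_SIZE = 8


class LabelRangeError(ValueError):
    """A label field is outside the range its bit field can store."""


class CondensationError(ValueError):
    """A leaf cannot be absorbed (count overflow or non-condensable element)."""


# ---------------------------------------------------------------------------
# molecular graph
# ---------------------------------------------------------------------------

@dataclass
class AtomNode:
    """One atom: element, formal charge, optional chirality and metadata."""

    element: int
    formal_charge: int = 0
    chirality: Optional[str] = None  # None | "R" | "S"
    atom_name: str = ""
    residue_id: tuple[str, int] = ("", 0)
    coordinates: Optional[np.ndarray] = None  # nm

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 118:
            raise LabelRangeError(f"element {self.element} outside [1, 118]")
        if abs(self.formal_charge) > 7:
            raise LabelRangeError(
                f"|formal charge| {self.formal_charge} exceeds 7 (3-bit field)"
            )
        if self.chirality not in (None, "R", "S"):
            raise ValueError(f"chirality must be None, 'R' or 'S', got {self.chirality!r}")


@dataclass
class BondEdge:
    """One bond between atom indices ``i`` and ``j`` (unordered)."""

    i: int
    j: int
    order: int = 1
    stereo: Optional[str] = None  # None | "E" | "Z"

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 7:
            raise LabelRangeError(f"bond order code {self.order} outside [1, 7]")
        if self.stereo not in (None, "E", "Z"):
            raise ValueError(f"stereo must be None, 'E' or 'Z', got {self.stereo!r}")

    @property
    def endpoints(self) -> frozenset[int]:
        return frozenset((self.i, self.j))


class MolecularGraph:
    """Simple labeled graph of atoms and bonds with stable 0-based indices."""

    def __init__(self, name: str = "", atoms: Sequence[AtomNode] = (),
                 bonds: Sequence[BondEdge] = ()) -> None:
        self.name = name
        self.atoms: list[AtomNode] = list(atoms)
        self.bonds: list[BondEdge] = []
        self._adj: dict[int, dict[int, BondEdge]] = {i: {} for i in range(len(self.atoms))}
        for b in bonds:
            self.add_bond(b)

    # -- construction -------------------------------------------------------
    def add_atom(self, atom: AtomNode) -> int:
        self.atoms.append(atom)
        idx = len(self.atoms) - 1
        self._adj[idx] = {}
        return idx

    def add_bond(self, bond: BondEdge) -> None:
        n = len(self.atoms)
        if bond.i == bond.j:
            raise ValueError(f"self-loop on atom {bond.i}")
        if not (0 <= bond.i < n and 0 <= bond.j < n):
            raise ValueError(f"bond ({bond.i}, {bond.j}) references missing atom")
        if bond.j in self._adj[bond.i]:
            raise ValueError(f"parallel bond ({bond.i}, {bond.j})")
        self.bonds.append(bond)
        self._adj[bond.i][bond.j] = bond
        self._adj[bond.j][bond.i] = bond

    # -- queries ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def bond_between(self, i: int, j: int) -> Optional[BondEdge]:
        return self._adj[i].get(j)

    @property
    def net_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for i, a in enumerate(self.atoms):
            g.add_node(i, atom=a)
        for b in self.bonds:
            g.add_edge(b.i, b.j, bond=b)
        return g


# ---------------------------------------------------------------------------
# label codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VertexFields:
    element: int
    charge: int
    condensed_counts: tuple[int, int, int, int, int]  # H, F, Cl, Br, I
    cyclic: bool
    chirality: Optional[str]
    degree: int


@dataclass(frozen=True)
class EdgeFields:
    order: int
    stereo: Optional[str]
    cyclic: bool
    deg_low: int
    deg_high: int


def _check(value: int, lo: int, hi: int, what: str) -> int:
    if not lo <= value <= hi:
        raise LabelRangeError(f"{what} {value} outside [{lo}, {hi}]")
    return value


def encode_vertex_label(element: int, charge: int = 0,
                        condensed_counts: Mapping[int, int] | Sequence[int] = (),
                        cyclic: bool = False, chirality: Optional[str] = None,
                        degree: int = 0) -> int:
    """Pack the ten vertex fields into a 32-bit integer.

    ``condensed_counts`` is either a mapping from condensable atomic number
    to count, or a 5-sequence in field order (H, F, Cl, Br, I).
    """
    _check(element, 0, 118, "element")
    _check(abs(charge), 0, 7, "|formal charge|")
    _check(degree, 0, 7, "degree")
    if isinstance(condensed_counts, Mapping):
        counts = [0, 0, 0, 0, 0]
        for z, c in condensed_counts.items():
            if z not in _CONDENSABLE_SLOT:
                raise CondensationError(
                    f"element {z} ({SYMBOL.get(z, '?')}) has no condensed-count field"
                )
            counts[_CONDENSABLE_SLOT[z]] = c
    else:
        counts = list(condensed_counts) + [0] * (5 - len(condensed_counts))
    label = _check(element, 0, 118, "element")
    label |= _check(abs(charge), 0, 7, "|formal charge|") << 7
    label |= (1 << 10) if charge < 0 else 0
    for slot, c in enumerate(counts):
        label |= _check(c, 0, 7, "condensed count") << (11 + 3 * slot)
    label |= (1 << 26) if cyclic else 0
    if chirality == "R":
        label |= 1 << 27
    elif chirality == "S":
        label |= 1 << 28
    elif chirality is not None:
        raise ValueError(f"chirality must be None, 'R' or 'S', got {chirality!r}")
    label |= degree << 29
    return label


def decode_vertex_label(label: int) -> VertexFields:
    if not 0 <= label < 1 << 32:
        raise LabelRangeError(f"vertex label {label} is not a 32-bit integer")
    sign = -1 if label & (1 << 10) else 1
    chir = "R" if label & (1 << 27) else "S" if label & (1 << 28) else None
    return VertexFields(
        element=label & 0x7F,
        charge=sign * ((label >> 7) & 0x7),
        condensed_counts=tuple((label >> (11 + 3 * s)) & 0x7 for s in range(5)),
        cyclic=bool(label & (1 << 26)),
        chirality=chir,
        degree=(label >> 29) & 0x7,
    )


def encode_edge_label(order: int, stereo: Optional[str] = None, cyclic: bool = False,
                      deg_a: int = 0, deg_b: int = 0) -> int:
    """Pack the four edge fields into a 12-bit integer.

    The endpoint degrees are stored sorted: the smaller one in bits 6-8,
    the larger in bits 9-11, so the label is independent of edge direction.
    """
    _check(order, 1, 7, "bond order code")
    _check(deg_a, 0, 7, "degree")
    _check(deg_b, 0, 7, "degree")
    label = order
    if stereo == "E":
        label |= 1 << 3
    elif stereo == "Z":
        label |= 1 << 4
    elif stereo is not None:
        raise ValueError(f"stereo must be None, 'E' or 'Z', got {stereo!r}")
    label |= (1 << 5) if cyclic else 0
    label |= min(deg_a, deg_b) << 6
    label |= max(deg_a, deg_b) << 9
    return label


def decode_edge_label(label: int) -> EdgeFields:
    if not 0 <= label < 1 << 12:
        raise LabelRangeError(f"edge label {label} is not a 12-bit integer")
    stereo = "E" if label & (1 << 3) else "Z" if label & (1 << 4) else None
    return EdgeFields(
        order=label & 0x7,
        stereo=stereo,
        cyclic=bool(label & (1 << 5)),
        deg_low=(label >> 6) & 0x7,
        deg_high=(label >> 9) & 0x7,
    )


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

#: named bit regions of the vertex label
VERTEX_PARTS: dict[str, int] = {
    "element": 0x7F,
    "charge_magnitude": 0x7 << 7,
    "charge_sign": 1 << 10,
    "charge": (0x7 << 7) | (1 << 10),
    "condensed_counts": 0x7FFF << 11,
    "cycle": 1 << 26,
    "chirality": 0x3 << 27,
    "degree": 0x7 << 29,
}

#: named bit regions of the edge label
EDGE_PARTS: dict[str, int] = {
    "order": 0x7,
    "stereo": 0x3 << 3,
    "cycle": 1 << 5,
    "degrees": 0x3F << 6,
}

VERTEX_ALL = (1 << 32) - 1
EDGE_ALL = (1 << 12) - 1


@dataclass(frozen=True)
class LabelMask:
    """Bit masks selecting which label fields participate in a comparison."""

    vertex_mask: int = VERTEX_ALL
    edge_mask: int = EDGE_ALL

    def __post_init__(self) -> None:
        if not 0 <= self.vertex_mask < 1 << 32:
            raise LabelRangeError("vertex mask is not a 32-bit integer")
        if not 0 <= self.edge_mask < 1 << 12:
            raise LabelRangeError("edge mask is not a 12-bit integer")

    @classmethod
    def from_parts(cls, vertex_parts: Iterable[str], edge_parts: Iterable[str]) -> "LabelMask":
        vm = 0
        for p in vertex_parts:
            vm |= VERTEX_PARTS[p]
        em = 0
        for p in edge_parts:
            em |= EDGE_PARTS[p]
        return cls(vm, em)


def apply_mask(label: int, mask: int) -> int:
    """Bitwise-AND of label and mask; masked labels compare by equality."""
    return label & mask


# ---------------------------------------------------------------------------
# cycle annotation
# ---------------------------------------------------------------------------

def cyclic_elements(graph: nx.Graph, max_size: int = MAX_CYCLE_SIZE):
    """Vertices and edges lying on at least one simple cycle of length <= max_size.

    Returns ``(vertex_set, edge_set)`` with edges as frozensets of endpoints.
    """
    verts: set = set()
    edges: set[frozenset] = set()
    for cycle in nx.simple_cycles(graph, length_bound=max_size):
        verts.update(cycle)
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.add(frozenset((a, b)))
    return verts, edges


# ---------------------------------------------------------------------------
# condensation
# ---------------------------------------------------------------------------

@dataclass
class CondensedVertex:
    """A surviving atom plus the leaves absorbed into it."""

    parent: int                      # index into the source MolecularGraph
    absorbed: tuple[int, ...] = ()   # absorbed atom indices, sorted
    label: int = 0

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return (self.parent,) + self.absorbed


@dataclass
class CondensedEdge:
    i: int  # condensed vertex ids
    j: int
    label: int = 0


class CondensedMolecularGraph:
    """Leaf-suppressed molecular graph with packed 32/12-bit labels."""

    def __init__(self, parent: MolecularGraph, vertices: list[CondensedVertex],
                 edges: list[CondensedEdge]) -> None:
        self.parent = parent
        self.vertices = vertices
        self.edges = edges
        self._adj: dict[int, dict[int, CondensedEdge]] = {i: {} for i in range(len(vertices))}
        for e in edges:
            self._adj[e.i][e.j] = e
            self._adj[e.j][e.i] = e
        #: source atom index -> condensed vertex id (parents and absorbed atoms)
        self.atom_to_vertex: dict[int, int] = {}
        for vid, v in enumerate(vertices):
            for ai in v.atom_indices:
                self.atom_to_vertex[ai] = vid

    def __len__(self) -> int:
        return len(self.vertices)

    def neighbors(self, vid: int) -> list[int]:
        return sorted(self._adj[vid])

    def degree(self, vid: int) -> int:
        return len(self._adj[vid])

    def edge_between(self, i: int, j: int) -> Optional[CondensedEdge]:
        return self._adj[i].get(j)

    def vertex_labels(self) -> list[int]:
        return [v.label for v in self.vertices]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for vid, v in enumerate(self.vertices):
            g.add_node(vid, label=v.label)
        for e in self.edges:
            g.add_edge(e.i, e.j, label=e.label)
        return g

    def subgraph_is_connected(self, vertex_ids: Iterable[int]) -> bool:
        ids = set(vertex_ids)
        if not ids:
            return False
        start = next(iter(ids))
        seen = {start}
        stack = [start]
        while stack:
            for n in self._adj[stack.pop()]:
                if n in ids and n not in seen:
                    seen.add(n)
                    stack.append(n)
        return seen == ids


def _leaf_condensable(mol: MolecularGraph, i: int) -> bool:
    """True if atom ``i`` is a leaf that the condensation rule absorbs."""
    if mol.degree(i) != 1:
        return False
    atom = mol.atoms[i]
    if atom.formal_charge != 0:
        return False
    if atom.element != 1 and atom.element not in (9, 17, 35, 53, 85):
        return False
    (parent,) = mol.neighbors(i)
    if mol.bond_between(i, parent).order != 1:
        return False
    if atom.element == 85:
        raise CondensationError(
            f"astatine leaf (atom {i}) qualifies for condensation but has no count field"
        )
    return True


def condense(mol: MolecularGraph, max_cycle_size: int = MAX_CYCLE_SIZE) -> CondensedMolecularGraph:
    """Build the condensed molecular graph of ``mol``.

    Every hydrogen/halogen leaf with zero formal charge attached by a
    single bond is absorbed into its neighbor; all other atoms survive as
    condensed vertices.  Labels are computed on the condensed topology
    (degree fields and cycle flags refer to the condensed graph).
    """
    absorbed_by: dict[int, list[int]] = {}
    absorbed: set[int] = set()
    for i in range(len(mol)):
        if _leaf_condensable(mol, i):
            (parent,) = mol.neighbors(i)
            absorbed_by.setdefault(parent, []).append(i)
            absorbed.add(i)
    # a two-atom molecule like H2 would have both atoms absorb each other;
    # keep any atom that is itself a parent of an absorbed atom
    for parent in list(absorbed_by):
        if parent in absorbed:
            for leaf in absorbed_by[parent]:
                absorbed.discard(leaf)
            del absorbed_by[parent]

    vertices: list[CondensedVertex] = []
    vid_of: dict[int, int] = {}
    for i in range(len(mol)):
        if i in absorbed:
            continue
        vid_of[i] = len(vertices)
        vertices.append(CondensedVertex(parent=i, absorbed=tuple(sorted(absorbed_by.get(i, ())))))

    edges: list[CondensedEdge] = []
    for b in mol.bonds:
        if b.i in absorbed or b.j in absorbed:
            continue
        edges.append(CondensedEdge(vid_of[b.i], vid_of[b.j]))

    cg = CondensedMolecularGraph(mol, vertices, edges)
    annotate_labels(cg, max_cycle_size)
    return cg


def annotate_labels(cg: CondensedMolecularGraph, max_cycle_size: int = MAX_CYCLE_SIZE) -> None:
    """(Re)compute all packed vertex and edge labels of a condensed graph."""
    cyc_v, cyc_e = cyclic_elements(cg.to_networkx(), max_cycle_size)
    mol = cg.parent
    for vid, v in enumerate(cg.vertices):
        atom = mol.atoms[v.parent]
        counts = [0, 0, 0, 0, 0]
        for ai in v.absorbed:
            z = mol.atoms[ai].element
            slot = _CONDENSABLE_SLOT[z]
            counts[slot] += 1
            if counts[slot] > 7:
                raise CondensationError(
                    f"more than 7 condensed {SYMBOL[z]} leaves on atom "
                    f"{atom.atom_name or v.parent} (3-bit count field)"
                )
        if cg.degree(vid) > 7:
            raise LabelRangeError(
                f"condensed degree {cg.degree(vid)} of atom {v.parent} exceeds 7"
            )
        v.label = encode_vertex_label(
            element=atom.element, charge=atom.formal_charge,
            condensed_counts=counts, cyclic=vid in cyc_v,
            chirality=atom.chirality, degree=cg.degree(vid),
        )
    for e in cg.edges:
        bond = mol.bond_between(cg.vertices[e.i].parent, cg.vertices[e.j].parent)
        e.label = encode_edge_label(
            order=bond.order, stereo=bond.stereo,
            cyclic=frozenset((e.i, e.j)) in cyc_e,
            deg_a=cg.degree(e.i), deg_b=cg.degree(e.j),
        )
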
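"""Fragment libraries: user-directed and automated fragment generation.

An athenaeum is an ordered library of already-parameterized source
molecules and fragments cut from their condensed graphs.  Each fragment is
a connected induced subgraph split into a parameter-donating *core* and a
context-checking *overlap* region.  In automated mode every connected
induced core passing the validity rules is generated, and the overlap is
the set of vertices within graph distance ``k`` of the core.

Validity rules for automated cores (each can be toggled):

* ``incident-order`` — every boundary edge (one endpoint in the core, one
  outside) must be a single or aromatic bond; a core never cuts through a
  multiple bond.
* ``incident-carbon`` — every boundary edge must have at least one carbon
  endpoint.
* ``overlap-leaf-distance`` — every leaf of the core+overlap subgraph that
  belongs to the overlap must lie at graph distance >= k from the nearest
  core vertex (only binding for k >= 2).

Fragments of one molecule are threaded into a superset tree: a fragment
references its immediate vertex supersets, each superset being referenced
by exactly one (the first-inserted) of its subsets.  The matching loop
uses the tree to skip every superset of a fragment that failed to match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chem_io import ParameterizedMolecule
from .graph_core import AROMATIC, CondensedMolecularGraph

logger = logging.getLogger("fragpick")

ALL_RULES = frozenset({"incident-order", "incident-carbon", "overlap-leaf-distance"})

ARCHIVE_VERSION = 1


class FragmentError(ValueError):
    """A fragment specification violates the connectivity contract."""


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """Core + overlap vertex sets over one source molecule's condensed graph."""

    mol_id: int
    core: frozenset[int]
    overlap: frozenset[int]
    index: int = -1                               # insertion order in the athenaeum
    supersets: list[int] = field(default_factory=list)  # indices of immediate supersets

    @property
    def vertices(self) -> frozenset[int]:
        return self.core | self.overlap

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Fragment(mol={self.mol_id}, core={sorted(self.core)}, "
                f"overlap={sorted(self.overlap)})")


@dataclass
class SourceMolecule:
    mol: ParameterizedMolecule
    condensed: CondensedMolecularGraph


# ---------------------------------------------------------------------------
# validity rules and enumeration
# ---------------------------------------------------------------------------

def _boundary_edges(cond: CondensedMolecularGraph, core: Iterable[int]):
    core = set(core)
    for u in core:
        for w in cond.neighbors(u):
            if w not in core:
                yield u, w


def _k_neighborhood(cond: CondensedMolecularGraph, core: frozenset[int], k: int) -> frozenset[int]:
    frontier = set(core)
    seen = set(core)
    for _ in range(k):
        nxt = set()
        for u in frontier:
            for w in cond.neighbors(u):
                if w not in seen:
                    nxt.add(w)
        seen |= nxt
        frontier = nxt
    return frozenset(seen - core)


def validate_fragment(core: Iterable[int], cond: CondensedMolecularGraph, k: int = 1,
                      enabled_rules: frozenset[str] = ALL_RULES,
                      overlap: Optional[frozenset[int]] = None):
    """Test a connected core against the three validity rules.

    Returns ``(True, None)`` or ``(False, failed_rule_name)``; rules are
    checked in their listed order and the first violation is reported.
    """
    core = frozenset(core)
    mol = cond.parent
    if "incident-order" in enabled_rules or "incident-carbon" in enabled_rules:
        for u, w in _boundary_edges(cond, core):
            edge_order = mol.bond_between(cond.vertices[u].parent,
                                          cond.vertices[w].parent).order
            if "incident-order" in enabled_rules and edge_order not in (1, AROMATIC):
                return False, "incident-order"
            if "incident-carbon" in enabled_rules:
                if mol.atoms[cond.vertices[u].parent].element != 6 and \
                        mol.atoms[cond.vertices[w].parent].element != 6:
                    return False, "incident-carbon"
    if "overlap-leaf-distance" in enabled_rules and k >= 2:
        if overlap is None:
            overlap = _k_neighborhood(cond, core, k)
        combined = core | overlap
        # BFS distances from the core within the combined subgraph
        dist = {v: 0 for v in core}
        frontier = set(core)
        d = 0
        while frontier:
            d += 1
            nxt = set()
            for u in frontier:
                for w in cond.neighbors(u):
                    if w in combined and w not in dist:
                        dist[w] = d
                        nxt.add(w)
            frontier = nxt
        for v in overlap:
            deg = sum(1 for w in cond.neighbors(v) if w in combined)
            if deg <= 1 and dist.get(v, k) < k:
                return False, "overlap-leaf-distance"
    return True, None


def _adjacency_masks(cond: CondensedMolecularGraph) -> list[int]:
    masks = []
    for v in range(len(cond)):
        m = 0
        for w in cond.neighbors(v):
            m |= 1 << w
        masks.append(m)
    return masks


def _forbidden_masks(cond: CondensedMolecularGraph, enabled_rules: frozenset[str]) -> list[int]:
    """Per-vertex bitmask of neighbors whose connecting edge may not be cut."""
    mol = cond.parent
    forbid = [0] * len(cond)
    for e in cond.edges:
        bond = mol.bond_between(cond.vertices[e.i].parent, cond.vertices[e.j].parent)
        bad = False
        if "incident-order" in enabled_rules and bond.order not in (1, AROMATIC):
            bad = True
        if not bad and "incident-carbon" in enabled_rules:
            if mol.atoms[cond.vertices[e.i].parent].element != 6 and \
                    mol.atoms[cond.vertices[e.j].parent].element != 6:
                bad = True
        if bad:
            forbid[e.i] |= 1 << e.j
            forbid[e.j] |= 1 << e.i
    return forbid


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


def enumerate_cores(cond: CondensedMolecularGraph, min_core: int = 2,
                    max_core: Optional[int] = None,
                    enabled_rules: frozenset[str] = ALL_RULES) -> list[frozenset[int]]:
    """All connected induced subgraphs passing the boundary rules.

    Enumeration uses canonical vertex-anchored expansion (each subgraph is
    grown only from its minimum vertex, extending with exclusive neighbors
    of the frontier), so every connected induced subgraph is produced
    exactly once and no post-hoc deduplication is needed.  Vertex sets are
    handled as bitmasks.  The distance rule is applied separately by the
    caller (it depends on k); only the two boundary-edge rules prune here.
    """
    n = len(cond)
    adj = _adjacency_masks(cond)
    forbid = _forbidden_masks(cond, enabled_rules)
    max_core = max_core if max_core is not None else n
    out: list[int] = []

    def expand(sub: int, size: int, ext: int, closed: int, forb: int, ge_mask: int) -> None:
        if size >= min_core and forb & ~sub == 0:
            out.append(sub)
        if size == max_core:
            return
        while ext:
            low = ext & -ext
            ext ^= low
            w = low.bit_length() - 1
            new_ext = ext | (adj[w] & ge_mask & ~closed)
            expand(sub | low, size + 1, new_ext, closed | adj[w], forb | forbid[w], ge_mask)

    for v in range(n):
        ge_mask = ~((1 << (v + 1)) - 1)
        expand(1 << v, 1, adj[v] & ge_mask, (1 << v) | adj[v], forbid[v], ge_mask)
    return [frozenset(_bits(m)) for m in out]


def enumerate_fragments(cond: CondensedMolecularGraph, k: int = 1, min_core: int = 2,
                        max_core: Optional[int] = None,
                        enabled_rules: frozenset[str] = ALL_RULES
                        ) -> list[tuple[frozenset[int], frozenset[int]]]:
    """Automated fragment generation: cores plus their k-neighborhood overlaps."""
    frags = []
    for core in enumerate_cores(cond, min_core, max_core, enabled_rules):
        overlap = _k_neighborhood(cond, core, k)
        if "overlap-leaf-distance" in enabled_rules and k >= 2:
            ok, _why = validate_fragment(core, cond, k, frozenset({"overlap-leaf-distance"}),
                                         overlap=overlap)
            if not ok:
                continue
        frags.append((core, overlap))
    return frags


# ---------------------------------------------------------------------------
# the library
# ---------------------------------------------------------------------------

class Athenaeum:
    """Ordered fragment library over one or more source molecules."""

    def __init__(self, name: str = "", k: int = 1, self_consistent: bool = False,
                 enabled_rules: frozenset[str] = ALL_RULES) -> None:
        if k < 0:
            raise ValueError("overlap length k must be >= 0")
        unknown = frozenset(enabled_rules) - ALL_RULES
        if unknown:
            raise ValueError(f"unknown rules: {sorted(unknown)}")
        self.name = name
        self.k = k
        self.self_consistent = self_consistent
        self.enabled_rules = frozenset(enabled_rules)
        self.molecules: list[SourceMolecule] = []
        self.fragments: list[Fragment] = []
        self._core_index: dict[tuple[int, frozenset[int]], int] = {}

    # -- molecules ----------------------------------------------------------
    def add_molecule(self, mol: ParameterizedMolecule) -> int:
        self.molecules.append(SourceMolecule(mol=mol, condensed=mol.condensed))
        return len(self.molecules) - 1

    def source(self, frag: Fragment) -> SourceMolecule:
        return self.molecules[frag.mol_id]

    # -- fragments ----------------------------------------------------------
    def add_fragment(self, mol_id: int, core: Iterable[int],
                     overlap: Iterable[int], link: bool = True) -> Optional[Fragment]:
        """Insert a fragment; duplicates (same molecule and core) are ignored.

        When ``link`` is true the new fragment is attached to the superset
        tree: the smallest-index immediate subset already present gains a
        reference to it.
        """
        if not 0 <= mol_id < len(self.molecules):
            raise FragmentError(f"molecule id {mol_id} not registered")
        cond = self.molecules[mol_id].condensed
        core = frozenset(core)
        overlap = frozenset(overlap)
        if core & overlap:
            raise FragmentError(f"core and overlap intersect: {sorted(core & overlap)}")
        if not cond.subgraph_is_connected(core):
            raise FragmentError(f"core does not induce a connected subgraph: {sorted(core)}")
        if not cond.subgraph_is_connected(core | overlap):
            raise FragmentError(
                f"core+overlap does not induce a connected subgraph: {sorted(core | overlap)}")
        key = (mol_id, core)
        if key in self._core_index:
            return None
        frag = Fragment(mol_id=mol_id, core=core, overlap=overlap,
                        index=len(self.fragments))
        self.fragments.append(frag)
        self._core_index[key] = frag.index
        if link:
            self._link_one(frag)
        return frag

    def _link_one(self, frag: Fragment) -> None:
        """Attach ``frag`` under its first-inserted immediate subset, if any."""
        candidates = []
        for v in sorted(frag.core):
            sub = (frag.mol_id, frag.core - {v})
            idx = self._core_index.get(sub)
            if idx is not None:
                candidates.append(idx)
        if candidates:
            self.fragments[min(candidates)].supersets.append(frag.index)

    def rebuild_tree(self) -> None:
        """Recompute superset references from scratch (general subset order).

        Used for user-specified libraries whose fragments may differ in
        size by more than one vertex.  For every fragment the immediate
        supersets are found pairwise; each superset keeps a reference from
        only its first-inserted immediate subset.
        """
        for f in self.fragments:
            f.supersets = []
        by_mol: dict[int, list[Fragment]] = {}
        for f in self.fragments:
            by_mol.setdefault(f.mol_id, []).append(f)
        for frags in by_mol.values():
            frags = sorted(frags, key=lambda f: len(f.core))
            for sup in frags:
                subs = [f for f in frags if f.core < sup.core]
                if not subs:
                    continue
                # immediate = no intermediate subset between f and sup
                immediate = [f for f in subs
                             if not any(f.core < g.core < sup.core for g in subs)]
                first = min(immediate, key=lambda f: f.index)
                first.supersets.append(sup.index)

    def fragment_from_spec(self, mol_id: int, core_atoms: Iterable[int],
                           overlap_atoms: Iterable[int]) -> Fragment:
        """User-directed fragment from molecular-graph atom indices.

        Atom indices (e.g. from a fragment-specification file) are mapped
        to condensed vertices; hydrogens that were absorbed by condensation
        map to their parent vertex.
        """
        cond = self.molecules[mol_id].condensed
        core = frozenset(cond.atom_to_vertex[a] for a in core_atoms)
        overlap = frozenset(cond.atom_to_vertex[a] for a in overlap_atoms) - core
        frag = self.add_fragment(mol_id, core, overlap, link=False)
        if frag is None:
            raise FragmentError("duplicate user fragment (same molecule and core)")
        return frag

    def generate_auto(self, mol_id: int, min_core: int = 2,
                      max_core: Optional[int] = None) -> int:
        """Automated fragmentation of one registered molecule; returns count added."""
        cond = self.molecules[mol_id].condensed
        before = len(self.fragments)
        frags = enumerate_fragments(cond, self.k, min_core, max_core, self.enabled_rules)
        # size-ordered insertion keeps tree links pointing upward in size
        for core, overlap in sorted(frags, key=lambda co: (len(co[0]), sorted(co[0]))):
            self.add_fragment(mol_id, core, overlap)
        return len(self.fragments) - before

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "format": "fragpick-athenaeum",
            "version": ARCHIVE_VERSION,
            "name": self.name,
            "k": self.k,
            "self_consistent": self.self_consistent,
            "rules": sorted(self.enabled_rules),
            "molecules": [s.mol.to_dict() for s in self.molecules],
            "fragments": [
                [f.mol_id, sorted(f.core), sorted(f.overlap), f.supersets]
                for f in self.fragments
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "Athenaeum":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "fragpick-athenaeum":
            raise ValueError(f"{path} is not an athenaeum archive")
        if doc.get("version") != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {doc.get('version')}")
        ath = cls(name=doc["name"], k=doc["k"], self_consistent=doc["self_consistent"],
                  enabled_rules=frozenset(doc["rules"]))
        for md in doc["molecules"]:
            ath.add_molecule(ParameterizedMolecule.from_dict(md))
        for mol_id, core, overlap, supersets in doc["fragments"]:
            frag = ath.add_fragment(mol_id, core, overlap, link=False)
            frag.supersets = list(supersets)
        return ath

    def __len__(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# fragment-specification files
# ---------------------------------------------------------------------------

def parse_fragment_spec(path) -> list[tuple[str, list, list]]:
    """Parse a user fragment-specification file.

    Dialect::

        molecule <name>
        core: <tokens>
        overlap: <tokens>
        core: ...
        overlap: ...

    Each ``core:``/``overlap:`` pair defines one fragment of the molecule
    named by the preceding ``molecule`` line.  Tokens are either 1-based
    atom serials or ``<residue-seq>:<atom-name>`` references; ``#`` starts
    a comment.  Returns ``(molecule name, core tokens, overlap tokens)``
    triples with tokens as ``int`` (0-based) or ``(resseq, name)`` tuples.
    """

    def parse_token(tok: str):
        if ":" in tok:
            seq, name = tok.split(":", 1)
            return (int(seq), name)
        return int(tok) - 1

    out: list[tuple[str, list, list]] = []
    current: Optional[str] = None
    pending_core: Optional[list] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.split("#")[0].strip()
            if not text:
                continue
            low = text.lower()
            if low.startswith("molecule"):
                current = text.split(None, 1)[1]
                pending_core = None
            elif low.startswith("core:"):
                if current is None:
                    raise ValueError(f"{path}:{lineno}: core before any molecule line")
                if pending_core is not None:
                    raise ValueError(f"{path}:{lineno}: core line without overlap line")
                pending_core = [parse_token(t) for t in text[5:].split()]
            elif low.startswith("overlap:"):
                if pending_core is None:
                    raise ValueError(f"{path}:{lineno}: overlap before core")
                overlap = [parse_token(t) for t in text[8:].split()]
                out.append((current, pending_core, overlap))
                pending_core = None
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized line {text!r}")
    if pending_core is not None:
        raise ValueError(f"{path}: trailing core line without overlap")
    return out


def resolve_atom_tokens(mol: ParameterizedMolecule, tokens: Sequence) -> list[int]:
    """Map fragment-spec tokens to 0-based atom indices of ``mol``."""
    by_ref = {}
    for i, a in enumerate(mol.graph.atoms):
        by_ref[(a.residue_id[1], a.atom_name)] = i
    out = []
    for tok in tokens:
        if isinstance(tok, int):
            out.append(tok)
        else:
            if tok not in by_ref:
                raise KeyError(f"{mol.name}: no atom {tok[1]!r} in residue {tok[0]}")
            out.append(by_ref[tok])
    return out
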
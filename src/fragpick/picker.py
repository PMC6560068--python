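"""Parameter assignment by masked fragment matching.

The matching loop walks an ordered list of athenaeums (first-in
first-out, most reliable first).  Within an athenaeum, fragments are
tested smallest-core-first for subgraph isomorphism between the fragment's
core+overlap graph and the target's condensed molecular graph.  Vertex and
edge labels are compared after masking, so the caller chooses which label
fields (element, formal charge, condensed counts, degree, ...) must agree.
Matches are *induced*: a target edge between two mapped vertices must also
exist in the fragment.

Every match tallies the fragment's parameters into the target's parameter
pool: per-atom type-code counts and partial-charge lists for core atoms,
and type-code counts for bonded terms lying in the core — including
*dangling* terms that straddle the core/overlap boundary with at least
half their atoms (and, for dihedrals, two adjacent atoms) in the core.
After each athenaeum, every target element that received parameters is
marked and excluded from later athenaeums.  The pool is finally distilled:
mean for partial charges, mode for everything else, followed by a single-
atom correction that restores the expected integer net charge.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .athenaeum import Athenaeum, Fragment
from .chem_io import ParameterizedMolecule
from .graph_core import (
    CondensedMolecularGraph,
    LabelMask,
    MolecularGraph,
    apply_mask,
    condense,
)

logger = logging.getLogger("fragpick")

#: label parts used for matching unless the caller chooses otherwise:
#: element, formal charge, condensed counts and degree for vertices;
#: bond order and endpoint degrees for edges.  Cycle membership, chirality
#: and E/Z stereo are ignored by default.
DEFAULT_MASK = LabelMask.from_parts(
    vertex_parts=("element", "charge", "condensed_counts", "degree"),
    edge_parts=("order", "degrees"),
)


class SelfConsistencyError(RuntimeError):
    """A self-consistent athenaeum produced conflicting parameter values."""

    def __init__(self, conflicts: list[str]) -> None:
        super().__init__("self-consistent athenaeum produced conflicting values:\n  "
                         + "\n  ".join(conflicts))
        self.conflicts = conflicts


class ChargeAdjustmentError(RuntimeError):
    """Net-charge correction impossible (all assigned atoms protected)."""


# ---------------------------------------------------------------------------
# target topology convention
# ---------------------------------------------------------------------------

def derive_term_tuples(mol: MolecularGraph):
    """Bonded terms a topology of ``mol`` must carry, from the graph alone.

    * one bond term per edge;
    * one angle term per connected triple (all neighbor pairs of each
      central atom);
    * one proper dihedral per central bond whose endpoints both have
      degree >= 2, with the lowest-index remaining neighbor on each side
      as the representative outer atoms;
    * one improper dihedral (central atom first, then sorted neighbors)
      for every atom with exactly three neighbors that is either a carbon,
      a nitrogen, or engaged in a multiple/aromatic bond — i.e. united-atom
      stereocenters and planar sp2 centers.

    The same convention generates the terms of library molecules built
    from the bundled templates, so a target's required terms line up with
    what matching fragments can donate.
    """
    bonds = [tuple(sorted((b.i, b.j))) for b in mol.bonds]
    angles = []
    propers = []
    impropers = []
    for j in range(len(mol)):
        nbrs = mol.neighbors(j)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                angles.append((nbrs[x], j, nbrs[y]))
        if len(nbrs) == 3:
            a = mol.atoms[j]
            multiple = any(mol.bond_between(j, n).order != 1 for n in nbrs)
            if a.element in (6, 7) or multiple:
                impropers.append((j, nbrs[0], nbrs[1], nbrs[2]))
    for b, c in bonds:
        nb = [x for x in mol.neighbors(b) if x != c]
        nc = [x for x in mol.neighbors(c) if x != b]
        if nb and nc:
            propers.append((nb[0], b, c, nc[0]))
    return bonds, angles, propers, impropers


def _angle_key(tup):
    i, j, k = tup
    return (j, min(i, k), max(i, k))


def _proper_key(tup):
    return (min(tup[1], tup[2]), max(tup[1], tup[2]))


def _improper_key(tup):
    return (tup[0], frozenset(tup[1:]))


def _key_of(category: str):
    return {"bond": lambda t: tuple(sorted(t)), "angle": _angle_key,
            "dihedral": _proper_key, "improper": _improper_key}[category]


# ---------------------------------------------------------------------------
# parameter pool
# ---------------------------------------------------------------------------

@dataclass
class AtomPool:
    charges: list[float] = field(default_factory=list)
    types: Counter = field(default_factory=Counter)


class ParameterPool:
    """Tallied observations for every atom and required bonded term of a target."""

    CATEGORIES = ("bond", "angle", "dihedral", "improper")

    def __init__(self, target: MolecularGraph) -> None:
        self.target = target
        self.atoms: list[AtomPool] = [AtomPool() for _ in range(len(target))]
        bonds, angles, propers, impropers = derive_term_tuples(target)
        self.term_tuples = {
            "bond": {tuple(sorted(t)): t for t in bonds},
            "angle": {_angle_key(t): t for t in angles},
            "dihedral": {_proper_key(t): t for t in propers},
            "improper": {_improper_key(t): t for t in impropers},
        }
        self.terms: dict[str, dict] = {
            cat: {key: Counter() for key in self.term_tuples[cat]}
            for cat in self.CATEGORIES
        }
        self.marked_atoms: set[int] = set()
        self.protected_atoms: set[int] = set()
        self.marked_terms: set[tuple[str, tuple]] = set()
        self._unfilled = len(self.atoms) + sum(len(t) for t in self.terms.values())

    def term_pool(self, category: str) -> dict:
        return self.terms[category]

    @property
    def complete(self) -> bool:
        """True once every atom and required term has at least one observation."""
        return self._unfilled == 0

    def add_atom_observation(self, i: int, type_code: int, charge: float) -> None:
        ap = self.atoms[i]
        if not ap.charges:
            self._unfilled -= 1
        ap.charges.append(charge)
        ap.types[type_code] += 1

    def add_term_observation(self, category: str, key, type_code: int) -> bool:
        counter = self.terms[category].get(key)
        if counter is None:
            return False
        if not counter:
            self._unfilled -= 1
        counter[type_code] += 1
        return True

    def unassigned_atoms(self) -> list[int]:
        return [i for i, ap in enumerate(self.atoms) if not ap.charges]


@dataclass
class AssignedParameters:
    """Distilled per-atom and per-term values; ``None`` marks unassigned."""

    atom_types: list[Optional[int]]
    charges: list[Optional[float]]
    terms: dict[str, dict]          # category -> {key: code or None}

    def all_atoms_assigned(self) -> bool:
        return all(t is not None for t in self.atom_types)

    def fully_assigned(self) -> bool:
        return self.all_atoms_assigned() and all(
            code is not None for cat in self.terms.values() for code in cat.values())

    def unassigned_summary(self) -> dict[str, int]:
        return {
            "atoms": sum(1 for t in self.atom_types if t is None),
            **{cat: sum(1 for c in d.values() if c is None)
               for cat, d in self.terms.items()},
        }


# ---------------------------------------------------------------------------
# subgraph matching
# ---------------------------------------------------------------------------

class _PatternGraph:
    """Fragment core+overlap as a compact labeled graph for matching."""

    __slots__ = ("vids", "labels", "adj", "order", "core_positions")

    def __init__(self, cond: CondensedMolecularGraph, frag: Fragment) -> None:
        self.vids = sorted(frag.vertices)
        pos = {v: i for i, v in enumerate(self.vids)}
        self.labels = [cond.vertices[v].label for v in self.vids]
        self.adj: list[dict[int, int]] = [{} for _ in self.vids]
        for i, v in enumerate(self.vids):
            for w in cond.neighbors(v):
                if w in pos:
                    self.adj[i][pos[w]] = cond.edge_between(v, w).label
        self.core_positions = [pos[v] for v in sorted(frag.core)]
        self.order = self._search_order()

    def _search_order(self) -> list[int]:
        n = len(self.vids)
        placed: list[int] = []
        placed_set: set[int] = set()
        while len(placed) < n:
            best = None
            for i in range(n):
                if i in placed_set:
                    continue
                nplaced = sum(1 for j in self.adj[i] if j in placed_set)
                key = (-nplaced, -len(self.adj[i]), i)  # constraint-first
                if best is None or key < best[0]:
                    best = (key, i)
            placed.append(best[1])
            placed_set.add(best[1])
        return placed


class _TargetIndex:
    """Masked labels and adjacency of the target condensed graph."""

    def __init__(self, cond: CondensedMolecularGraph, mask: LabelMask) -> None:
        self.cond = cond
        self.mask = mask
        self.labels = [apply_mask(v.label, mask.vertex_mask) for v in cond.vertices]
        self.adj: list[dict[int, int]] = [{} for _ in cond.vertices]
        for e in cond.edges:
            lbl = apply_mask(e.label, mask.edge_mask)
            self.adj[e.i][e.j] = lbl
            self.adj[e.j][e.i] = lbl
        self.by_label: dict[int, list[int]] = {}
        for v, lbl in enumerate(self.labels):
            self.by_label.setdefault(lbl, []).append(v)


def _match_pattern(pat: _PatternGraph, tgt: _TargetIndex) -> list[dict[int, int]]:
    vm, em = tgt.mask.vertex_mask, tgt.mask.edge_mask
    plabels = [apply_mask(l, vm) for l in pat.labels]
    padj = [{j: apply_mask(l, em) for j, l in d.items()} for d in pat.adj]
    n = len(plabels)
    order = pat.order
    mapping = [-1] * n
    used: set[int] = set()
    results: list[dict[int, int]] = []

    def backtrack(pos: int) -> None:
        if pos == n:
            results.append({pat.vids[i]: mapping[i] for i in range(n)})
            return
        p = order[pos]
        placed_nbrs = [(q, padj[p][q]) for q in padj[p] if mapping[q] >= 0]
        if placed_nbrs:
            q0, lbl0 = placed_nbrs[0]
            candidates = [t for t, l in tgt.adj[mapping[q0]].items() if l == lbl0]
        else:
            candidates = tgt.by_label.get(plabels[p], ())
        nonadj = [q for q in range(n) if mapping[q] >= 0 and q not in padj[p]]
        for t in candidates:
            if t in used or tgt.labels[t] != plabels[p]:
                continue
            ok = True
            for q, lbl in placed_nbrs[1:]:
                if tgt.adj[t].get(mapping[q]) != lbl:
                    ok = False
                    break
            if ok:
                for q in nonadj:
                    if mapping[q] in tgt.adj[t]:
                        ok = False  # induced: no extra target edge
                        break
            if ok:
                mapping[p] = t
                used.add(t)
                backtrack(pos + 1)
                mapping[p] = -1
                used.discard(t)

    backtrack(0)
    results.sort(key=lambda m: tuple(m[v] for v in pat.vids))
    return results


def find_matches(frag: Fragment, ath: Athenaeum, target_cond: CondensedMolecularGraph,
                 mask: LabelMask = DEFAULT_MASK) -> list[dict[int, int]]:
    """All induced, label-masked mappings of a fragment into the target.

    Returns dictionaries mapping fragment condensed-vertex ids (over
    core+overlap) to target condensed-vertex ids, in a canonical order.
    """
    pat = _PatternGraph(ath.source(frag).condensed, frag)
    return _match_pattern(pat, _TargetIndex(target_cond, mask))


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

def _expand_mapping(src_cond: CondensedMolecularGraph, tgt_cond: CondensedMolecularGraph,
                    vmap: dict[int, int]) -> dict[int, int]:
    """Extend a condensed-vertex mapping to source-atom -> target-atom.

    Parents map to parents; condensed leaves are paired up element-by-
    element in index order.  Under the default mask the leaf counts agree
    exactly; under looser masks unpaired leaves are simply left unmapped.
    """
    amap: dict[int, int] = {}
    for sv, tv in vmap.items():
        s = src_cond.vertices[sv]
        t = tgt_cond.vertices[tv]
        amap[s.parent] = t.parent
        if s.absorbed:
            t_by_elem: dict[int, list[int]] = {}
            for ai in t.absorbed:
                t_by_elem.setdefault(tgt_cond.parent.atoms[ai].element, []).append(ai)
            s_by_elem: dict[int, list[int]] = {}
            for ai in s.absorbed:
                s_by_elem.setdefault(src_cond.parent.atoms[ai].element, []).append(ai)
            for elem, s_list in s_by_elem.items():
                for sa, ta in zip(s_list, t_by_elem.get(elem, [])):
                    amap[sa] = ta
    return amap


def _dangling_ok(category: str, tup: tuple, in_core) -> bool:
    """The at-least-half rule for bonded terms straddling the boundary."""
    flags = [in_core(a) for a in tup]
    n_core = sum(flags)
    if category == "bond":
        return n_core >= 1
    if category == "angle":
        return n_core >= 2
    # dihedrals (proper and improper): two adjacent chain atoms in core;
    # for impropers the central atom (first) must be in the core
    if category == "dihedral":
        return n_core >= 2 and any(flags[i] and flags[i + 1] for i in range(3))
    if category == "improper":
        return n_core >= 2 and flags[0]
    raise ValueError(category)


def tally(pool: ParameterPool, frag: Fragment, ath: Athenaeum,
          target_cond: CondensedMolecularGraph, vmap: dict[int, int]) -> None:
    """Add one match's parameter observations to the pool.

    Atoms of the fragment core donate their type code and partial charge
    to the mapped target atoms; bonded terms fully inside the core or
    dangling by the at-least-half rule donate their type codes.  Elements
    already marked by an earlier athenaeum are skipped.
    """
    src = ath.source(frag)
    src_cond = src.condensed
    amap = _expand_mapping(src_cond, target_cond, vmap)
    core_atoms = set()
    for v in frag.core:
        core_atoms.update(src_cond.vertices[v].atom_indices)

    for sa in sorted(core_atoms):
        ta = amap.get(sa)
        if ta is None or ta in pool.marked_atoms:
            continue
        code = src.mol.atom_types[sa]
        if code is None:
            continue
        pool.add_atom_observation(ta, code, src.mol.charges[sa])

    def in_core(a: int) -> bool:
        return a in core_atoms

    term_lists = (("bond", src.mol.bonds), ("angle", src.mol.angles),
                  ("dihedral", src.mol.dihedrals), ("improper", src.mol.impropers))
    key_of = {"bond": lambda t: tuple(sorted(t)), "angle": _angle_key,
              "dihedral": _proper_key, "improper": _improper_key}
    for category, terms in term_lists:
        for tup, code in terms:
            if code is None:
                continue
            if category == "dihedral":
                # proper torsions pool on the target's central bond: the two
                # central atoms must map, but a dangling torsion's outer
                # atoms may lie beyond the fragment (edge-terminated cores)
                if tup[1] not in amap or tup[2] not in amap:
                    continue
                if not _dangling_ok(category, tup, in_core):
                    continue
                key = _proper_key((0, amap[tup[1]], amap[tup[2]], 0))
            else:
                if not all(a in amap for a in tup):
                    continue
                if not _dangling_ok(category, tup, in_core):
                    continue
                mapped = tuple(amap[a] for a in tup)
                key = key_of[category](mapped)
            if (category, key) in pool.marked_terms:
                continue
            if not pool.add_term_observation(category, key, code):
                logger.debug("%s term %s maps to non-existent target term %s; skipped",
                             category, tup, mapped)


# ---------------------------------------------------------------------------
# distillation and charge correction
# ---------------------------------------------------------------------------

def _mode(counter: Counter) -> int:
    """Most common code; ties broken toward the lowest code."""
    best = max(counter.values())
    return min(c for c, n in counter.items() if n == best)


def distill(pool: ParameterPool) -> AssignedParameters:
    """Mean of pooled charges per atom, mode of pooled type codes elsewhere."""
    atom_types: list[Optional[int]] = []
    charges: list[Optional[float]] = []
    for ap in pool.atoms:
        if ap.charges:
            atom_types.append(_mode(ap.types))
            charges.append(sum(ap.charges) / len(ap.charges))
        else:
            atom_types.append(None)
            charges.append(None)
    terms = {
        cat: {key: (_mode(cnt) if cnt else None) for key, cnt in pools.items()}
        for cat, pools in pool.terms.items()
    }
    return AssignedParameters(atom_types=atom_types, charges=charges, terms=terms)


def adjust_net_charge(assigned: AssignedParameters, expected_total: int,
                      protected: Iterable[int] = (), tol: float = 5e-7) -> Optional[int]:
    """Restore the expected integer net charge by shifting a single atom.

    The whole residual is added to the most positive unprotected atom when
    the assigned total falls short of the expectation, or to the most
    negative one when it overshoots; ties break to the lowest atom index.
    Atoms parameterized from a self-consistent athenaeum are protected and
    never modified.  Returns the adjusted atom index, or None if no
    adjustment was needed.
    """
    if not assigned.all_atoms_assigned():
        raise ValueError("net-charge correction requires all atoms to carry charges")
    protected = set(protected)
    total = sum(assigned.charges)
    delta = expected_total - total
    if abs(delta) < tol:
        return None
    free = [i for i in range(len(assigned.charges)) if i not in protected]
    if not free:
        raise ChargeAdjustmentError(
            f"assigned total charge {total:.6f} differs from expected "
            f"{expected_total} but every atom is protected")
    if delta > 0:  # assigned < expected: push the most positive atom up
        pick = max(free, key=lambda i: (assigned.charges[i], -i))
    else:          # assigned > expected: push the most negative atom down
        pick = min(free, key=lambda i: (assigned.charges[i], i))
    others = total - assigned.charges[pick]
    assigned.charges[pick] = expected_total - others  # exact to machine precision
    return pick


def check_self_consistency(pool: ParameterPool, round_atoms: Iterable[int],
                           round_terms: Iterable[tuple[str, tuple]],
                           charge_tol: float = 1e-6) -> list[str]:
    """Conflicting observations within one self-consistent athenaeum.

    Type-code tallies must be unanimous and each atom's pooled charges
    must agree within ``charge_tol``.  Returns a list of human-readable
    conflict descriptions (empty if consistent).
    """
    conflicts = []
    for i in sorted(round_atoms):
        ap = pool.atoms[i]
        name = pool.target.atoms[i].atom_name or str(i)
        if len(ap.types) > 1:
            conflicts.append(f"atom {name} ({i}): conflicting type codes "
                             f"{dict(sorted(ap.types.items()))}")
        if ap.charges and max(ap.charges) - min(ap.charges) > charge_tol:
            conflicts.append(f"atom {name} ({i}): charge spread "
                             f"[{min(ap.charges):.6f}, {max(ap.charges):.6f}] "
                             f"exceeds {charge_tol:g}")
    for category, key in sorted(round_terms):
        cnt = pool.terms[category][key]
        if len(cnt) > 1:
            conflicts.append(f"{category} term {key}: conflicting type codes "
                             f"{dict(sorted(cnt.items()))}")
    return conflicts


# ---------------------------------------------------------------------------
# the matching loop
# ---------------------------------------------------------------------------

@dataclass
class PickReport:
    """Per-athenaeum bookkeeping from one run."""

    matched_fragments: list[int] = field(default_factory=list)
    tested_fragments: list[int] = field(default_factory=list)
    skipped_by_pruning: list[int] = field(default_factory=list)
    adjusted_atom: Optional[int] = None


@dataclass
class PickResult:
    pool: ParameterPool
    assigned: AssignedParameters
    report: PickReport

    def to_molecule(self, target: MolecularGraph) -> ParameterizedMolecule:
        """Assemble an output molecule with placeholders where unassigned."""
        a = self.assigned
        pool = self.pool
        mol = ParameterizedMolecule(
            graph=target,
            atom_types=list(a.atom_types),
            charges=[(math.nan if q is None else q) for q in a.charges],
            charge_groups=list(range(1, len(target) + 1)),
        )
        for cat, attr in (("bond", "bonds"), ("angle", "angles"),
                          ("dihedral", "dihedrals"), ("improper", "impropers")):
            tuples = sorted(pool.term_tuples[cat].values())
            setattr(mol, attr, [(t, a.terms[cat][key])
                                for t, key in ((t, _key_of(cat)(t)) for t in tuples)])
        return mol


def run(target: MolecularGraph, athenaeums: Sequence[Athenaeum],
        mask: LabelMask = DEFAULT_MASK, min_core: int = 4,
        max_core: Optional[int] = None, expected_charge: Optional[int] = None,
        prune: bool = True, charge_tol: float = 1e-6) -> PickResult:
    """Parameterize ``target`` against an ordered list of athenaeums.

    ``min_core``/``max_core`` bound the core sizes of the fragments that
    are tested (defaults: minimum four, no maximum).  The loop stops early
    once every atom and required term of the target has a parameter pool.
    Set ``prune=False`` to disable superset-tree skipping (results are
    identical; only the amount of matching work changes).
    """
    if not athenaeums:
        logger.warning("no athenaeums supplied; every parameter will be a placeholder")
    target_cond = condense(target)
    pool = ParameterPool(target)
    report = PickReport()

    for ath in athenaeums:
        tgt_index = _TargetIndex(target_cond, mask)
        eligible = [f for f in ath.fragments
                    if len(f.core) >= min_core
                    and (max_core is None or len(f.core) <= max_core)]
        eligible.sort(key=lambda f: (len(f.core), f.index))
        skipped: set[int] = set()
        atoms_before = {i for i, ap in enumerate(pool.atoms) if ap.charges}
        terms_before = {(cat, key) for cat, pools in pool.terms.items()
                        for key, cnt in pools.items() if cnt}
        tested = matched = pruned = 0
        for frag in eligible:
            if pool.complete:
                break
            if prune and frag.index in skipped:
                skipped.update(frag.supersets)
                pruned += 1
                continue
            tested += 1
            pat = _PatternGraph(ath.source(frag).condensed, frag)
            mappings = _match_pattern(pat, tgt_index)
            if mappings:
                matched += 1
                for vmap in mappings:
                    tally(pool, frag, ath, target_cond, vmap)
            else:
                skipped.update(frag.supersets)
        report.tested_fragments.append(tested)
        report.matched_fragments.append(matched)
        report.skipped_by_pruning.append(pruned)
        logger.info("athenaeum %s: %d fragments tested, %d matched, %d skipped by pruning",
                    ath.name or "?", tested, matched, pruned)

        round_atoms = {i for i, ap in enumerate(pool.atoms)
                       if ap.charges} - atoms_before
        round_terms = {(cat, key) for cat, pools in pool.terms.items()
                       for key, cnt in pools.items() if cnt} - terms_before
        if ath.self_consistent:
            conflicts = check_self_consistency(pool, round_atoms, round_terms, charge_tol)
            if conflicts:
                raise SelfConsistencyError(conflicts)
        pool.marked_atoms |= round_atoms
        pool.marked_terms |= round_terms
        if ath.self_consistent:
            pool.protected_atoms |= round_atoms
        if pool.complete:
            break

    assigned = distill(pool)
    if assigned.all_atoms_assigned():
        expected = expected_charge if expected_charge is not None \
            else target.net_formal_charge
        report.adjusted_atom = adjust_net_charge(assigned, expected,
                                                 pool.protected_atoms)
    return PickResult(pool=pool, assigned=assigned, report=report)
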
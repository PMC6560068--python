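"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive subset / injection
enumeration with no shared code paths into the package internals.
"""

from __future__ import annotations

import itertools
import random

from fragpick.graph_core import (
    AROMATIC,
    AtomNode,
    BondEdge,
    MolecularGraph,
    apply_mask,
)


# ---------------------------------------------------------------------------
# simple-cycle enumeration (cycle-flag oracle)
# ---------------------------------------------------------------------------

def bruteforce_cyclic_elements(n: int, edges: list[tuple[int, int]], max_size: int = 8):
    """Vertices/edges on a simple cycle of length <= max_size, by path DFS."""
    adj = {v: set() for v in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    verts, cyc_edges = set(), set()

    def dfs(start, current, path):
        for nxt in adj[current]:
            if nxt == start and len(path) >= 3:
                verts.update(path)
                for x, y in zip(path, path[1:] + [start]):
                    cyc_edges.add(frozenset((x, y)))
            elif nxt > start and nxt not in path and len(path) < max_size:
                dfs(start, nxt, path + [nxt])

    for start in range(n):
        dfs(start, start, [start])
    return verts, cyc_edges


# ---------------------------------------------------------------------------
# connected-induced-subgraph enumeration + validity rules (fragment oracle)
# ---------------------------------------------------------------------------

def bruteforce_valid_cores(cond, min_core=2, max_core=None,
                           rules=("incident-order", "incident-carbon")):
    """All valid cores by testing every one of the 2^|V| vertex subsets."""
    n = len(cond)
    mol = cond.parent
    max_core = max_core if max_core is not None else n
    out = []
    for bits in range(1, 1 << n):
        sub = {v for v in range(n) if bits >> v & 1}
        if not min_core <= len(sub) <= max_core:
            continue
        # connectivity by flood fill
        seen = {next(iter(sub))}
        frontier = list(seen)
        while frontier:
            v = frontier.pop()
            for w in cond.neighbors(v):
                if w in sub and w not in seen:
                    seen.add(w)
                    frontier.append(w)
        if seen != sub:
            continue
        ok = True
        for u in sub:
            for w in cond.neighbors(u):
                if w in sub:
                    continue
                bond = mol.bond_between(cond.vertices[u].parent, cond.vertices[w].parent)
                if "incident-order" in rules and bond.order not in (1, AROMATIC):
                    ok = False
                if "incident-carbon" in rules and \
                        mol.atoms[cond.vertices[u].parent].element != 6 and \
                        mol.atoms[cond.vertices[w].parent].element != 6:
                    ok = False
        if ok:
            out.append(frozenset(sub))
    return out


# ---------------------------------------------------------------------------
# subgraph-isomorphism oracle (injective mapping enumeration)
# ---------------------------------------------------------------------------

def bruteforce_matches(pat_labels, pat_edges, tgt_labels, tgt_edges, vmask, emask):
    """All induced label-masked injections pattern -> target.

    ``pat_edges``/``tgt_edges`` map frozenset{(i, j)} -> edge label.
    Returns a set of mapping tuples (target vertex per pattern vertex).
    """
    np_, nt = len(pat_labels), len(tgt_labels)
    out = set()
    for perm in itertools.permutations(range(nt), np_):
        ok = all(apply_mask(pat_labels[i], vmask) == apply_mask(tgt_labels[perm[i]], vmask)
                 for i in range(np_))
        if not ok:
            continue
        for i in range(np_):
            for j in range(i + 1, np_):
                pl = pat_edges.get(frozenset((i, j)))
                tl = tgt_edges.get(frozenset((perm[i], perm[j])))
                if (pl is None) != (tl is None):
                    ok = False
                elif pl is not None and apply_mask(pl, emask) != apply_mask(tl, emask):
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if ok:
            out.add(perm)
    return out


# ---------------------------------------------------------------------------
# random labeled molecules
# ---------------------------------------------------------------------------

def random_connected_molecule(rng: random.Random, n: int, elements=(6, 7, 8),
                              orders=(1, 1, 1, 2), name="rand") -> MolecularGraph:
    """A random connected simple graph dressed up as a molecule (no leaves
    that condensation would absorb, so the condensed graph is the graph)."""
    mol = MolecularGraph(name=name)
    for _ in range(n):
        mol.add_atom(AtomNode(element=rng.choice(elements)))
    nodes = list(range(n))
    rng.shuffle(nodes)
    for i in range(1, n):  # random spanning tree keeps it connected
        j = rng.choice(nodes[:i])
        mol.add_bond(BondEdge(nodes[i], j, order=rng.choice(orders)))
    extra = rng.randint(0, n)
    for _ in range(extra):
        a, b = rng.sample(range(n), 2)
        if mol.bond_between(a, b) is None:
            mol.add_bond(BondEdge(a, b, order=rng.choice(orders)))
    return mol
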
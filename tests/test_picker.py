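"""Matching, tallying, distillation, charge correction, the full loop."""

import random
from collections import Counter

import pytest

from fragpick import molbuilder as mb
from fragpick import picker
from fragpick.athenaeum import Athenaeum
from fragpick.chem_io import ParameterizedMolecule
from fragpick.graph_core import AtomNode, BondEdge, LabelMask, MolecularGraph, condense
from fragpick.picker import (
    DEFAULT_MASK,
    AssignedParameters,
    ChargeAdjustmentError,
    ParameterPool,
    adjust_net_charge,
    check_self_consistency,
    distill,
    find_matches,
)

from _oracles import bruteforce_matches, random_connected_molecule


def _as_pmol(mol, types=None, charges=None):
    n = len(mol)
    return ParameterizedMolecule(
        graph=mol, atom_types=types or [1] * n, charges=charges or [0.0] * n,
        charge_groups=list(range(1, n + 1)))


def _uniform(elements, bonds, orders=None):
    mol = MolecularGraph()
    for e in elements:
        mol.add_atom(AtomNode(element=e))
    for idx, (a, b) in enumerate(bonds):
        mol.add_bond(BondEdge(a, b, order=(orders[idx] if orders else 1)))
    return mol


def _whole_fragment(ath, mol_id):
    cond = ath.molecules[mol_id].condensed
    return ath.add_fragment(mol_id, set(range(len(cond))), set())


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_triangle_onto_triangle_has_six_mappings():
    ath = Athenaeum()
    mid = ath.add_molecule(_as_pmol(_uniform([6] * 3, [(0, 1), (1, 2), (0, 2)])))
    frag = _whole_fragment(ath, mid)
    target = condense(_uniform([6] * 3, [(0, 1), (1, 2), (0, 2)]))
    assert len(find_matches(frag, ath, target)) == 6


def test_two_path_onto_three_path():
    ath = Athenaeum()
    mid = ath.add_molecule(_as_pmol(_uniform([6, 6], [(0, 1)])))
    frag = _whole_fragment(ath, mid)
    # mask out degree fields: a 2-path embeds in a 3-path 4 ways only if the
    # path-end labels are not forced to agree
    mask = LabelMask.from_parts(("element",), ("order",))
    target = condense(_uniform([6, 6, 6], [(0, 1), (1, 2)]))
    assert len(find_matches(frag, ath, target, mask)) == 4


def test_element_mismatch_gives_no_mapping():
    ath = Athenaeum()
    mid = ath.add_molecule(_as_pmol(_uniform([7], [])))
    frag = _whole_fragment(ath, mid)
    target = condense(_uniform([6], []))
    assert find_matches(frag, ath, target) == []


def test_matching_is_induced():
    # a 3-path pattern must not map onto a triangle (extra target edge)
    ath = Athenaeum()
    mid = ath.add_molecule(_as_pmol(_uniform([6] * 3, [(0, 1), (1, 2)])))
    frag = _whole_fragment(ath, mid)
    mask = LabelMask.from_parts(("element",), ("order",))
    triangle = condense(_uniform([6] * 3, [(0, 1), (1, 2), (0, 2)]))
    assert find_matches(frag, ath, triangle, mask) == []


def test_matcher_agrees_with_bruteforce_oracle():
    """200 random labeled graph pairs against exhaustive injection search."""
    rng = random.Random(424242)
    checked = 0
    for trial in range(200):
        tgt_mol = random_connected_molecule(rng, rng.randint(3, 7),
                                            elements=(6, 7, 8), orders=(1, 2))
        pat_mol = random_connected_molecule(rng, rng.randint(2, 5),
                                            elements=(6, 7, 8), orders=(1, 2))
        ath = Athenaeum()
        mid = ath.add_molecule(_as_pmol(pat_mol))
        frag = _whole_fragment(ath, mid)
        tgt = condense(tgt_mol)
        pat = ath.molecules[mid].condensed
        for mask in (DEFAULT_MASK, LabelMask.from_parts(("element",), ("order",))):
            got = {tuple(m[v] for v in range(len(pat)))
                   for m in find_matches(frag, ath, tgt, mask)}
            exp = bruteforce_matches(
                [v.label for v in pat.vertices],
                {frozenset((e.i, e.j)): e.label for e in pat.edges},
                [v.label for v in tgt.vertices],
                {frozenset((e.i, e.j)): e.label for e in tgt.edges},
                mask.vertex_mask, mask.edge_mask)
            assert got == exp, f"trial {trial}"
            checked += len(exp)
    assert checked > 0  # the instances are not all trivially matchless


# ---------------------------------------------------------------------------
# tallying and dangling terms
# ---------------------------------------------------------------------------

@pytest.fixture()
def chain_setup():
    """A 5-carbon chain molecule matched onto itself with core {1,2,3}."""
    src = _as_pmol(_uniform([6] * 5, [(i, i + 1) for i in range(4)]),
                   types=[11, 12, 13, 14, 15], charges=[0.1] * 5)
    src.bonds = [((i, i + 1), 100 + i) for i in range(4)]
    src.angles = [((i, i + 1, i + 2), 200 + i) for i in range(3)]
    src.dihedrals = [((i, i + 1, i + 2, i + 3), 300 + i) for i in range(2)]
    ath = Athenaeum()
    mid = ath.add_molecule(src)
    frag = ath.add_fragment(mid, {1, 2, 3}, {0, 4})
    target = _uniform([6] * 5, [(i, i + 1) for i in range(4)])
    return ath, frag, target


def test_tally_dangling_rules(chain_setup):
    ath, frag, target = chain_setup
    pool = ParameterPool(target)
    tgt_cond = condense(target)
    maps = find_matches(frag, ath, tgt_cond)
    identity = next(m for m in maps if all(k == v for k, v in m.items()))
    picker.tally(pool, frag, ath, tgt_cond, identity)
    # atoms: only core atoms tallied
    assert [bool(p.charges) for p in pool.atoms] == [False, True, True, True, False]
    # bond (0,1): one atom in core -> dangling, tallied
    assert pool.terms["bond"][(0, 1)] == Counter({100: 1})
    # angle (0,1,2): two of three in core -> tallied; all-overlap impossible here
    assert pool.terms["angle"][(1, 0, 2)] == Counter({200: 1})
    # dihedral (0,1,2,3): adjacent pair (1,2) in core -> tallied on central bond
    assert pool.terms["dihedral"][(1, 2)] == Counter({300: 1})


def test_dihedral_outer_pair_does_not_dangle():
    # only the two outer atoms of a dihedral in core -> not tallied
    from fragpick.picker import _dangling_ok
    core = {0, 3}
    assert not _dangling_ok("dihedral", (0, 1, 2, 3), lambda a: a in core)
    assert _dangling_ok("dihedral", (0, 1, 2, 3), lambda a: a in {1, 2})
    assert not _dangling_ok("angle", (0, 1, 2), lambda a: False)
    assert _dangling_ok("bond", (0, 1), lambda a: a == 0)
    # improper: central atom (first) must be in core
    assert not _dangling_ok("improper", (0, 1, 2, 3), lambda a: a in {1, 2})
    assert _dangling_ok("improper", (0, 1, 2, 3), lambda a: a in {0, 1})


# ---------------------------------------------------------------------------
# distillation and charge correction
# ---------------------------------------------------------------------------

def test_distill_mean_mode_and_tie():
    target = _uniform([6], [])
    pool = ParameterPool(target)
    for q, t in [(0.10, 15), (0.20, 15), (0.30, 15)]:
        pool.add_atom_observation(0, t, q)
    assigned = distill(pool)
    assert assigned.charges[0] == pytest.approx(0.20)
    assert assigned.atom_types[0] == 15
    pool2 = ParameterPool(target)
    for t in [15, 15, 15, 27]:
        pool2.add_atom_observation(0, t, 0.0)
    assert distill(pool2).atom_types[0] == 15
    pool3 = ParameterPool(target)
    for t in [27, 27, 15, 15]:
        pool3.add_atom_observation(0, t, 0.0)
    assert distill(pool3).atom_types[0] == 15  # tie -> lowest code


def _assigned(charges):
    return AssignedParameters(atom_types=[1] * len(charges),
                              charges=list(charges), terms={})


def test_charge_correction_examples():
    a = _assigned([0.30, -0.20, -0.15])
    assert adjust_net_charge(a, 0) == 0
    assert a.charges == pytest.approx([0.35, -0.20, -0.15])
    b = _assigned([0.10, 0.10, -0.17])
    assert adjust_net_charge(b, 0) == 2
    assert b.charges == pytest.approx([0.10, 0.10, -0.20])
    c = _assigned([0.5, -0.5])
    assert adjust_net_charge(c, 0) is None
    assert c.charges == [0.5, -0.5]


def test_charge_correction_exact_and_single_atom():
    rng = random.Random(7)
    for _ in range(50):
        n = rng.randint(2, 9)
        charges = [round(rng.uniform(-0.8, 0.8), 3) for _ in range(n)]
        expected = rng.randint(-2, 2)
        a = _assigned(charges)
        changed = adjust_net_charge(a, expected)
        assert sum(a.charges) == pytest.approx(expected, abs=1e-12)
        diffs = [i for i in range(n) if a.charges[i] != charges[i]]
        assert diffs == ([] if changed is None else [changed])


def test_charge_correction_respects_protection():
    a = _assigned([0.30, -0.20, -0.15])
    adjust_net_charge(a, 0, protected={0})
    assert a.charges[0] == 0.30  # most positive atom protected: next best used
    b = _assigned([0.30, -0.20, -0.15])
    with pytest.raises(ChargeAdjustmentError):
        adjust_net_charge(b, 0, protected={0, 1, 2})


def test_self_consistency_tolerance_boundary():
    target = _uniform([6], [])
    pool = ParameterPool(target)
    pool.add_atom_observation(0, 12, 0.129)
    pool.add_atom_observation(0, 12, 0.131)
    assert check_self_consistency(pool, [0], [], charge_tol=1e-3)
    assert not check_self_consistency(pool, [0], [], charge_tol=5e-3)
    pool.add_atom_observation(0, 14, 0.130)
    conflicts = check_self_consistency(pool, [0], [], charge_tol=5e-3)
    assert any("12" in c and "14" in c for c in conflicts)


# ---------------------------------------------------------------------------
# the matching loop
# ---------------------------------------------------------------------------

def test_empty_athenaeum_list_gives_placeholders():
    target = mb.bare_graph(mb.build_heptane())
    res = picker.run(target, [])
    assert res.pool.unassigned_atoms() == list(range(7))
    assert not res.assigned.fully_assigned()
    assert all(t is None for t in res.assigned.atom_types)


def test_self_parametrization_identity(study_set):
    """Auto-fragmenting a source and picking its own bare graph recovers
    every atom and term type code."""
    sources, _spec, _targets = study_set
    for name in ("Val-Gly-Ser", "Ile-Asn-Phe"):
        pmol = next(m for m in sources if m.name == name)
        ath = Athenaeum(name="self", k=1)
        mid = ath.add_molecule(pmol)
        ath.generate_auto(mid, min_core=2)
        res = picker.run(mb.bare_graph(pmol), [ath], min_core=2)
        assert res.assigned.fully_assigned()
        assert res.assigned.atom_types == pmol.atom_types
        ref_bonds = {tuple(sorted(t)): c for t, c in pmol.bonds}
        assert res.assigned.terms["bond"] == ref_bonds


def test_pruning_is_lossless(study_set):
    sources, _spec, _targets = study_set
    pmol = next(m for m in sources if m.name == "Val-Gly-Ser")
    ath = Athenaeum(k=1)
    mid = ath.add_molecule(pmol)
    ath.generate_auto(mid, min_core=2)
    target = mb.bare_graph(next(m for m in sources if m.name == "Gly-Ile-Val"))
    with_prune = picker.run(target, [ath], min_core=2, prune=True)
    without = picker.run(target, [ath], min_core=2, prune=False)
    for a, b in zip(with_prune.pool.atoms, without.pool.atoms):
        assert a.types == b.types and a.charges == b.charges
    assert with_prune.pool.terms == without.pool.terms
    assert with_prune.report.tested_fragments[0] <= without.report.tested_fragments[0]


def test_fifo_exclusivity():
    """Atoms marked by an earlier athenaeum receive no later observations."""
    elems = [7, 6, 6, 8]  # asymmetric chain: each fragment maps one way only
    chain = _uniform(elems, [(0, 1), (1, 2), (2, 3)])
    src1 = _as_pmol(chain, types=[21, 22, 23, 24], charges=[0.1] * 4)
    chain2 = _uniform(elems, [(0, 1), (1, 2), (2, 3)])
    src2 = _as_pmol(chain2, types=[31, 32, 33, 34], charges=[0.5] * 4)
    ath1 = Athenaeum(name="first")
    m1 = ath1.add_molecule(src1)
    ath1.add_fragment(m1, {0, 1}, {2})
    ath2 = Athenaeum(name="second")
    m2 = ath2.add_molecule(src2)
    ath2.add_fragment(m2, {0, 1, 2, 3}, set())
    target = _uniform(elems, [(0, 1), (1, 2), (2, 3)])
    res = picker.run(target, [ath1, ath2], min_core=2)
    # atoms covered by athenaeum 1 keep its values exclusively
    for i in (0, 1):
        assert set(res.pool.atoms[i].types) <= {21, 22, 23, 24}
    # remaining atoms were filled by athenaeum 2
    for i in (2, 3):
        assert res.pool.atoms[i].charges and set(res.pool.atoms[i].types) <= {31, 32, 33, 34}


def test_self_consistency_violation_aborts():
    chain = _uniform([6, 6], [(0, 1)])
    src = _as_pmol(chain, types=[21, 22], charges=[0.1, -0.1])
    chain2 = _uniform([6, 6], [(0, 1)])
    src2 = _as_pmol(chain2, types=[23, 24], charges=[0.2, -0.2])
    ath = Athenaeum(name="sc", self_consistent=True)
    m1 = ath.add_molecule(src)
    m2 = ath.add_molecule(src2)
    ath.add_fragment(m1, {0, 1}, set())
    ath.add_fragment(m2, {0, 1}, set())
    target = _uniform([6, 6], [(0, 1)])
    with pytest.raises(picker.SelfConsistencyError):
        picker.run(target, [ath], min_core=2)
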
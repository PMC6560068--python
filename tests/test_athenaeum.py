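"""Fragment validity rules, enumeration, superset tree, persistence."""

import random

import pytest

from fragpick.athenaeum import (
    ALL_RULES,
    Athenaeum,
    FragmentError,
    enumerate_cores,
    enumerate_fragments,
    parse_fragment_spec,
    resolve_atom_tokens,
    validate_fragment,
)
from fragpick.chem_io import ParameterizedMolecule
from fragpick.graph_core import AROMATIC, AtomNode, BondEdge, MolecularGraph
from fragpick import molbuilder as mb

from _oracles import bruteforce_valid_cores, random_connected_molecule


def _as_pmol(mol: MolecularGraph) -> ParameterizedMolecule:
    p = ParameterizedMolecule(graph=mol, atom_types=[1] * len(mol),
                              charges=[0.0] * len(mol),
                              charge_groups=list(range(1, len(mol) + 1)))
    return p


def _carbon_ring(n, order=AROMATIC):
    mol = MolecularGraph(name=f"ring{n}")
    for _ in range(n):
        mol.add_atom(AtomNode(element=6))
    for i in range(n):
        mol.add_bond(BondEdge(i, (i + 1) % n, order=order))
    return mol


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_heptane_enumeration_counts():
    hep = mb.build_heptane()
    frags = enumerate_fragments(hep.condensed, k=1, min_core=2)
    assert len(frags) == 21  # contiguous sub-paths of length >= 2
    for core, overlap in frags:
        assert overlap == frozenset(
            v for c in core for v in hep.condensed.neighbors(c)) - core


def test_aromatic_hexagon_enumeration():
    cond = _as_pmol(_carbon_ring(6)).condensed
    frags = enumerate_fragments(cond, k=0, min_core=2)
    # arcs of length 2..5 (6 each) plus the full ring
    assert len(frags) == 25
    assert all(ov == frozenset() for _c, ov in frags)  # k=0: empty overlaps


def test_single_vertex_molecule_yields_nothing():
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=6))
    assert enumerate_fragments(_as_pmol(mol).condensed, k=1, min_core=2) == []


def test_enumeration_matches_bruteforce_oracle():
    rng = random.Random(73)
    for trial in range(25):
        mol = random_connected_molecule(rng, rng.randint(3, 12),
                                        elements=(6, 6, 7, 8, 16), orders=(1, 1, 2))
        cond = _as_pmol(mol).condensed
        got = set(enumerate_cores(cond, min_core=2))
        exp = set(bruteforce_valid_cores(cond, min_core=2))
        assert got == exp, f"trial {trial}: {len(got)} vs {len(exp)} cores"


def test_enumeration_invariant_under_relabeling():
    rng = random.Random(99)
    mol = random_connected_molecule(rng, 10, elements=(6, 7), orders=(1, 2))
    count = len(enumerate_cores(_as_pmol(mol).condensed, min_core=2))
    perm = list(range(10))
    rng.shuffle(perm)
    inverse = [perm.index(i) for i in range(10)]
    shuffled = MolecularGraph()
    for i in range(10):
        shuffled.add_atom(AtomNode(element=mol.atoms[inverse[i]].element))
    for b in mol.bonds:
        shuffled.add_bond(BondEdge(perm[b.i], perm[b.j], order=b.order))
    assert len(enumerate_cores(_as_pmol(shuffled).condensed, min_core=2)) == count


def test_overlap_is_exact_k_neighborhood():
    hep = mb.build_heptane()
    for k in (0, 1, 2, 3):
        for core, overlap in enumerate_fragments(hep.condensed, k=k, min_core=2):
            expected = set()
            for v in range(len(hep.condensed)):
                if v in core:
                    continue
                dmin = min(abs(v - c) for c in core)  # path graph distance
                if dmin <= k:
                    expected.add(v)
            assert overlap == frozenset(expected)


# ---------------------------------------------------------------------------
# validity rules
# ---------------------------------------------------------------------------

def _carbonyl_chain():
    # C0 - C1(=O2) - N3 ... a core cutting the C1=O2 bond violates rule 1
    mol = MolecularGraph()
    for elem in (6, 6, 8, 7):
        mol.add_atom(AtomNode(element=elem))
    mol.add_bond(BondEdge(0, 1))
    mol.add_bond(BondEdge(1, 2, order=2))
    mol.add_bond(BondEdge(1, 3))
    return _as_pmol(mol).condensed


def test_rule_incident_order():
    cond = _carbonyl_chain()
    ok, why = validate_fragment({0, 1}, cond)  # boundary cuts C=O
    assert not ok and why == "incident-order"
    ok, _ = validate_fragment({0, 1, 2}, cond)
    assert ok


def test_rule_incident_carbon():
    # N0 - S1 boundary edge with no carbon endpoint
    mol = MolecularGraph()
    for elem in (7, 16, 6):
        mol.add_atom(AtomNode(element=elem))
    mol.add_bond(BondEdge(0, 1))
    mol.add_bond(BondEdge(1, 2))
    cond = _as_pmol(mol).condensed
    ok, why = validate_fragment({0}, cond, enabled_rules=ALL_RULES)
    assert not ok and why == "incident-carbon"


def test_rule_overlap_leaf_distance():
    hep = mb.build_heptane()
    cond = hep.condensed
    # overlap leaf adjacent to the core (distance 1) fails for k=2
    ok, why = validate_fragment({2, 3}, cond, k=2, overlap=frozenset({1}))
    assert not ok and why == "overlap-leaf-distance"
    ok, _ = validate_fragment({2, 3}, cond, k=2, overlap=frozenset({0, 1, 4, 5}))
    assert ok


# ---------------------------------------------------------------------------
# user fragments and the superset tree
# ---------------------------------------------------------------------------

def test_fragment_from_spec_tripeptide(study_set):
    sources, _spec, _targets = study_set
    cfk = next(m for m in sources if m.name == "Cys-Phe-Lys")
    ath = Athenaeum(name="t", self_consistent=True)
    mid = ath.add_molecule(cfk)
    core, overlap = mb.user_fragments_for_tripeptide(cfk)[1]  # central Phe
    frag = ath.fragment_from_spec(mid, core, overlap)
    assert {cfk.graph.atoms[cfk.condensed.vertices[v].parent].residue_id[0]
            for v in frag.core} == {"PHE"}
    assert len(frag.overlap) == 3  # preceding carboxo C,O + following amine N


def test_fragment_from_spec_rejects_disconnected_core():
    hep = mb.build_heptane()
    ath = Athenaeum()
    mid = ath.add_molecule(hep)
    with pytest.raises(FragmentError):
        ath.fragment_from_spec(mid, [0, 2], [])
    with pytest.raises(FragmentError):
        ath.add_fragment(mid, {0, 1}, {3})  # core+overlap disconnected


def test_superset_tree_references():
    hep = mb.build_heptane()
    ath = Athenaeum()
    mid = ath.add_molecule(hep)
    f12 = ath.add_fragment(mid, {1, 2}, set())
    f23 = ath.add_fragment(mid, {2, 3}, set())
    f123 = ath.add_fragment(mid, {1, 2, 3}, set())
    # the larger fragment is referenced by the first-inserted subset only
    assert f123.index in f12.supersets
    assert f123.index not in f23.supersets
    assert ath.add_fragment(mid, {1, 2}, set()) is None  # dedup
    assert len(ath) == 3


def test_tree_references_increase_core_size(auto_ath):
    for frag in auto_ath.fragments[:5000]:
        for s in frag.supersets:
            sup = auto_ath.fragments[s]
            assert sup.mol_id == frag.mol_id
            assert frag.core < sup.core


def test_rebuild_tree_general_sizes():
    hep = mb.build_heptane()
    ath = Athenaeum()
    mid = ath.add_molecule(hep)
    f_a = ath.add_fragment(mid, {1, 2}, set(), link=False)
    f_b = ath.add_fragment(mid, {1, 2, 3, 4}, set(), link=False)  # gap of 2
    ath.rebuild_tree()
    assert f_b.index in f_a.supersets


# ---------------------------------------------------------------------------
# persistence and spec files
# ---------------------------------------------------------------------------

def test_archive_round_trip(tmp_path, study_set):
    sources, user_spec, _targets = study_set
    ath = mb.build_user_athenaeum(sources, user_spec)
    path = tmp_path / "user.json"
    ath.save(path)
    loaded = Athenaeum.load(path)
    assert len(loaded) == len(ath)
    assert loaded.k == ath.k and loaded.self_consistent
    for a, b in zip(ath.fragments, loaded.fragments):
        assert (a.mol_id, a.core, a.overlap, a.supersets) == \
            (b.mol_id, b.core, b.overlap, b.supersets)
    assert [s.mol.name for s in loaded.molecules] == [s.mol.name for s in ath.molecules]


def test_parse_fragment_spec(tmp_path):
    text = ("# comment\nmolecule heptane\ncore: 1 2 3\noverlap: 4\n"
            "core: 3 4 5\noverlap: 2 6\nmolecule pep\ncore: 2:CA 2:N\noverlap: 1:C\n")
    p = tmp_path / "frags.txt"
    p.write_text(text)
    spec = parse_fragment_spec(p)
    assert spec[0] == ("heptane", [0, 1, 2], [3])
    assert spec[1] == ("heptane", [2, 3, 4], [1, 5])
    assert spec[2] == ("pep", [(2, "CA"), (2, "N")], [(1, "C")])
    hep = mb.build_heptane()
    assert resolve_atom_tokens(hep, spec[0][1]) == [0, 1, 2]


def test_parse_fragment_spec_errors(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("core: 1 2\n")
    with pytest.raises(ValueError):
        parse_fragment_spec(p)
    p.write_text("molecule m\ncore: 1\ncore: 2\noverlap: 3\n")
    with pytest.raises(ValueError):
        parse_fragment_spec(p)
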
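"""Label codec, masks, condensation and cycle annotation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragpick.graph_core import (
    AROMATIC,
    AtomNode,
    BondEdge,
    CondensationError,
    LabelMask,
    LabelRangeError,
    MolecularGraph,
    VERTEX_PARTS,
    EDGE_PARTS,
    apply_mask,
    condense,
    cyclic_elements,
    decode_edge_label,
    decode_vertex_label,
    encode_edge_label,
    encode_vertex_label,
)

from _oracles import bruteforce_cyclic_elements, random_connected_molecule


# ---------------------------------------------------------------------------
# codec
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs, expected", [
    # carbon with four condensed hydrogens (methane vertex)
    (dict(element=6, charge=0, condensed_counts={1: 4}, degree=0), 6 + (4 << 11)),
    # O(-) of degree 1
    (dict(element=8, charge=-1, degree=1), 8 + (1 << 7) + (1 << 10) + (1 << 29)),
    (dict(element=0, charge=0), 0),  # all-zero label
])
def test_vertex_label_examples(kwargs, expected):
    assert encode_vertex_label(**kwargs) == expected


@pytest.mark.parametrize("kwargs, expected", [
    (dict(order=1, deg_a=3, deg_b=2), 1 + (2 << 6) + (3 << 9)),
    (dict(order=AROMATIC, cyclic=True, deg_a=2, deg_b=2), 5 + (1 << 5) + (2 << 6) + (2 << 9)),
    (dict(order=1, deg_a=1, deg_b=1), 1 + (1 << 6) + (1 << 9)),
])
def test_edge_label_examples(kwargs, expected):
    assert encode_edge_label(**kwargs) == expected


@settings(max_examples=300, derandomize=True)
@given(
    element=st.integers(0, 118),
    charge=st.integers(-7, 7),
    counts=st.tuples(*[st.integers(0, 7)] * 5),
    cyclic=st.booleans(),
    chirality=st.sampled_from([None, "R", "S"]),
    degree=st.integers(0, 7),
)
def test_vertex_codec_round_trip(element, charge, counts, cyclic, chirality, degree):
    label = encode_vertex_label(element, charge, counts, cyclic, chirality, degree)
    assert 0 <= label < 1 << 32
    f = decode_vertex_label(label)
    # a zero-magnitude charge loses its sign by construction
    assert (f.element, f.condensed_counts, f.cyclic, f.chirality, f.degree) == \
        (element, counts, cyclic, chirality, degree)
    assert f.charge == charge or (charge == 0 and f.charge == 0)


@settings(max_examples=300, derandomize=True)
@given(
    order=st.integers(1, 7),
    stereo=st.sampled_from([None, "E", "Z"]),
    cyclic=st.booleans(),
    deg_a=st.integers(0, 7),
    deg_b=st.integers(0, 7),
)
def test_edge_codec_round_trip(order, stereo, cyclic, deg_a, deg_b):
    label = encode_edge_label(order, stereo, cyclic, deg_a, deg_b)
    assert 0 <= label < 1 << 12
    f = decode_edge_label(label)
    assert (f.order, f.stereo, f.cyclic) == (order, stereo, cyclic)
    assert (f.deg_low, f.deg_high) == (min(deg_a, deg_b), max(deg_a, deg_b))


@pytest.mark.parametrize("bad", [
    dict(element=119), dict(element=6, charge=8), dict(element=6, degree=8),
    dict(element=6, condensed_counts=(8, 0, 0, 0, 0)),
])
def test_vertex_label_range_errors(bad):
    with pytest.raises(LabelRangeError):
        encode_vertex_label(**{"element": 6, **bad})


def test_edge_label_range_errors():
    with pytest.raises(LabelRangeError):
        encode_edge_label(order=0)
    with pytest.raises(LabelRangeError):
        encode_edge_label(order=1, deg_a=8)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_mask_examples():
    label = encode_vertex_label(6, 0, {1: 4})
    assert apply_mask(label, 0x7F) == 6          # element only
    assert apply_mask(label, (1 << 32) - 1) == label
    assert apply_mask(label, 0) == 0


@settings(max_examples=200, derandomize=True)
@given(label=st.integers(0, 2**32 - 1), m1=st.integers(0, 2**32 - 1),
       m2=st.integers(0, 2**32 - 1))
def test_mask_idempotent_and_monotone(label, m1, m2):
    assert apply_mask(apply_mask(label, m1), m1) == apply_mask(label, m1)
    # labels equal under a superset mask stay equal under any submask
    sub = m1 & m2
    other = label ^ (~m2 & 0xFFFFFFFF)  # differs only outside m2
    assert apply_mask(label, m2) == apply_mask(other, m2)
    assert apply_mask(label, sub) == apply_mask(other, sub)


def test_mask_from_parts_covers_label_space():
    vm = 0
    for part in ("element", "charge", "condensed_counts", "cycle", "chirality", "degree"):
        vm |= VERTEX_PARTS[part]
    assert vm == (1 << 32) - 1
    em = 0
    for part in EDGE_PARTS:
        em |= EDGE_PARTS[part]
    assert em == (1 << 12) - 1
    mask = LabelMask.from_parts(("element",), ("order",))
    assert mask.vertex_mask == 0x7F and mask.edge_mask == 0x7


# ---------------------------------------------------------------------------
# condensation
# ---------------------------------------------------------------------------

def _methane():
    mol = MolecularGraph(name="methane")
    mol.add_atom(AtomNode(element=6))
    for _ in range(4):
        h = mol.add_atom(AtomNode(element=1))
        mol.add_bond(BondEdge(0, h))
    return mol


def test_condense_methane():
    cg = condense(_methane())
    assert len(cg) == 1 and not cg.edges
    f = decode_vertex_label(cg.vertices[0].label)
    assert f.element == 6 and f.condensed_counts[0] == 4 and f.degree == 0


def test_condense_no_leaves_is_identity():
    mol = MolecularGraph(name="benzene-heavy")
    for _ in range(6):
        mol.add_atom(AtomNode(element=6))
    for i in range(6):
        mol.add_bond(BondEdge(i, (i + 1) % 6, order=AROMATIC))
    cg = condense(mol)
    assert len(cg) == 6 and len(cg.edges) == 6
    assert all(not v.absorbed for v in cg.vertices)


def test_condense_charged_leaf_kept_ammonium_leaf_absorbed():
    # metal hydride: H(-1) leaf is NOT condensed (its own charge is nonzero)
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=30))  # Zn
    mol.add_atom(AtomNode(element=1, formal_charge=-1))
    mol.add_bond(BondEdge(0, 1))
    assert len(condense(mol)) == 2
    # ammonium: the N carries the charge, each H leaf is neutral -> condensed
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=7, formal_charge=1))
    for _ in range(4):
        h = mol.add_atom(AtomNode(element=1))
        mol.add_bond(BondEdge(0, h))
    cg = condense(mol)
    assert len(cg) == 1
    assert decode_vertex_label(cg.vertices[0].label).condensed_counts[0] == 4


def test_condense_rules_keep_other_leaves():
    # non-H/halogen leaf, and a leaf attached by a double bond, both survive
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=6))
    mol.add_atom(AtomNode(element=8))   # carbonyl O, order 2
    mol.add_atom(AtomNode(element=7))   # N leaf
    mol.add_atom(AtomNode(element=1))   # H leaf, condensable
    mol.add_bond(BondEdge(0, 1, order=2))
    mol.add_bond(BondEdge(0, 2))
    mol.add_bond(BondEdge(0, 3))
    cg = condense(mol)
    assert len(cg) == 3
    assert cg.vertices[cg.atom_to_vertex[0]].absorbed == (3,)


def test_condense_count_overflow():
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=16))
    for _ in range(8):
        h = mol.add_atom(AtomNode(element=1))
        mol.add_bond(BondEdge(0, h))
    with pytest.raises(CondensationError):
        condense(mol)


def test_condense_astatine_rejected():
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=6))
    at = mol.add_atom(AtomNode(element=85))
    mol.add_bond(BondEdge(0, at))
    with pytest.raises(CondensationError):
        condense(mol)


def test_condensation_conserves_atoms(study_set):
    sources, _spec, targets = study_set
    for pmol in sources + list(targets.values()):
        cg = pmol.condensed
        absorbed = sum(len(v.absorbed) for v in cg.vertices)
        assert len(pmol.graph) == len(cg) + absorbed
        for v in cg.vertices:  # every absorbed atom is a qualifying leaf
            for ai in v.absorbed:
                atom = pmol.graph.atoms[ai]
                assert atom.element in (1, 9, 17, 35, 53)
                assert atom.formal_charge == 0
                assert pmol.graph.degree(ai) == 1


# ---------------------------------------------------------------------------
# cycle annotation
# ---------------------------------------------------------------------------

def _ring(n, order=1):
    mol = MolecularGraph()
    for _ in range(n):
        mol.add_atom(AtomNode(element=6))
    for i in range(n):
        mol.add_bond(BondEdge(i, (i + 1) % n, order=order))
    return mol


def test_cycle_flags_threshold():
    assert all(decode_vertex_label(v.label).cyclic for v in condense(_ring(6)).vertices)
    assert all(decode_edge_label(e.label).cyclic for e in condense(_ring(8)).edges)
    nine = condense(_ring(9))
    assert not any(decode_vertex_label(v.label).cyclic for v in nine.vertices)
    assert not any(decode_edge_label(e.label).cyclic for e in nine.edges)


def test_cycle_flags_fused_rings():
    # naphthalene-like fused 6+6 skeleton: everything cyclic, shared edge too
    mol = MolecularGraph()
    for _ in range(10):
        mol.add_atom(AtomNode(element=6))
    ring1 = [0, 1, 2, 3, 4, 5]
    for i in range(6):
        if mol.bond_between(ring1[i], ring1[(i + 1) % 6]) is None:
            mol.add_bond(BondEdge(ring1[i], ring1[(i + 1) % 6], order=AROMATIC))
    for a, b in [(0, 6), (6, 7), (7, 8), (8, 9), (9, 5)]:
        mol.add_bond(BondEdge(a, b, order=AROMATIC))
    cg = condense(mol)
    assert all(decode_vertex_label(v.label).cyclic for v in cg.vertices)
    assert all(decode_edge_label(e.label).cyclic for e in cg.edges)


def test_cycle_flags_match_bruteforce_oracle():
    import random
    rng = random.Random(20240917)
    for _ in range(30):
        mol = random_connected_molecule(rng, rng.randint(4, 12))
        g = condense(mol).to_networkx()
        edges = [tuple(e) for e in g.edges]
        got_v, got_e = cyclic_elements(g, 8)
        exp_v, exp_e = bruteforce_cyclic_elements(len(g), edges, 8)
        assert set(got_v) == exp_v
        assert set(got_e) == exp_e


def test_degree_overflow_rejected():
    mol = MolecularGraph()
    mol.add_atom(AtomNode(element=6))
    for _ in range(8):
        c = mol.add_atom(AtomNode(element=6))
        mol.add_bond(BondEdge(0, c))
    with pytest.raises(LabelRangeError):
        condense(mol)
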
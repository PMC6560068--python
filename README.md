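# fragpick

Fragment-based assignment of molecular-mechanics force-field parameters to
large biomolecules, without quantum chemistry.

Simulating a novel molecule — a cyclic peptide, a lipopeptide antibiotic, a
post-translationally modified protein — requires force-field parameters that
are compatible with an existing parameter set such as GROMOS 54A7.
Quantum-chemistry-based parametrization servers scale poorly with molecule
size and conformational flexibility.  `fragpick` instead transfers parameters
from molecules that are *already* parameterized: it cuts them into fragments,
matches those fragments onto the target by subgraph isomorphism, and pools
the parameter observations.  It is aimed at molecular-simulation
practitioners preparing GROMACS/GROMOS topologies for molecules that tools
like `pdb2gmx` cannot handle.

## The method

**Condensed molecular graphs.**  A molecule is a labeled graph G = (V, E):
vertices are atoms, edges are bonds.  Every hydrogen or halogen leaf with
zero formal charge attached by a single bond is absorbed into its parent
vertex, whose label records the counts of absorbed atoms.  Each condensed
vertex label packs ten fields into 32 bits (element, |q| and sign of the
formal charge, five condensed-element counts, cycle membership for simple
cycles of length ≤ 8, R/S chirality, degree); each edge label packs four
fields into 12 bits (bond order, E/Z stereo, cycle membership, sorted
endpoint degrees).  A *mask* selects which fields must agree, so comparing
two vertices or edges during matching is a single integer equality.

**Athenaeums.**  An athenaeum is an ordered library of parameterized source
molecules and fragments cut from them.  A fragment is a connected induced
subgraph split into a parameter-donating **core** and a context-checking
**overlap**.  Fragments are either user-specified or enumerated
automatically: every connected induced subgraph whose boundary edges are
single/aromatic and carbon-anchored becomes a core, and the overlap is the
set of vertices within graph distance *k* of it.  Per molecule, fragments
are threaded into a superset tree used to skip every superset of a fragment
that failed to match.

**Parameter picking.**  Athenaeums are searched first-in first-out
(most-trusted first).  Each fragment that matches the target (induced,
label-masked subgraph isomorphism) tallies its core atoms' type codes and
partial charges, and the type codes of bonded terms lying in the core —
including *dangling* bonds/angles/dihedrals with at least half their atoms
in the core — onto the target's parameter pool.  Target regions covered by
one athenaeum are excluded from later ones.  The pool is distilled to
assigned values: the mean of pooled partial charges per atom, the mode of
pooled type codes elsewhere.  Finally the residual between the assigned
total charge and the expected integer net charge is folded into the single
most positive (or most negative) unprotected atom, so Σq is exactly
integral.  Libraries flagged *self-consistent* are verified: conflicting
observations abort the run.

## Worked example

The package bundles a united-atom residue template library (reduced
GROMOS-54A7-style fixture) and builders that reconstruct the whole study
corpus from sequences: twenty tripeptides plus heptane as fragment sources,
and three test peptides.

```python
from fragpick import molbuilder, picker

sources, user_spec, targets = molbuilder.build_study_set()
user = molbuilder.build_user_athenaeum(sources, user_spec)
auto = molbuilder.build_auto_athenaeum(sources)
print(f"user athenaeum: {len(user)} fragments; automated: {len(auto)} fragments")

target = molbuilder.bare_graph(targets["axinellin_a"])
partial = picker.run(target, [user])
gaps = sorted({target.atoms[i].residue_id for i in partial.pool.unassigned_atoms()})
print("user athenaeum only, unparameterized residues:", gaps)

full = picker.run(target, [user, auto])
print("with automated athenaeum:", full.assigned.unassigned_summary())
print("net charge after correction:", round(sum(full.assigned.charges), 6))
```

prints

```
user athenaeum: 62 fragments; automated: 133015 fragments
user athenaeum only, unparameterized residues: [('ASN', 1), ('PHE', 6)]
with automated athenaeum: {'atoms': 0, 'bond': 0, 'angle': 0, 'dihedral': 0, 'improper': 0}
net charge after correction: 0.0
```

Axinellin A is a head-to-tail cyclic heptapeptide, cyclo(Asn-Pro-Phe-Thr-
Ile-Phe-Pro).  The hand-curated library covers every residue *except* the
two that precede prolines: a prolyl amide nitrogen is tertiary, so the
overlap region of the ordinary residue fragments refuses the match — the
overlap doing exactly its job of enforcing chemical context.  The
automatically generated library contains fragments with the right context
and closes the gap; the charge correction then restores the expected net
charge of zero.

The same workflow is available from the shell:

```sh
fragpick fixtures --out fix/
fragpick build-athenaeum --mode user --mtb fix/sources.mtb \
    --ifp fix/forcefield.ifp --fragments fix/user_fragments.txt \
    --self-consistent -o user.json
fragpick pick fix/targets/octapeptide.pdb --athenaeum user.json -o octa.itp
```

`pick` exits 0 on full parametrization, 2 when placeholders remain in the
output topology, 1 on errors (including self-consistency conflicts).

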
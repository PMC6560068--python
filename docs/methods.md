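# Methods

This note records the model, the tunable parameters, the design choices
made where the design was genuinely open, and what the bundled test corpus
does and does not demonstrate.

## Graph model and labels

Molecules are simple labeled graphs; bonds carry an integer order code
(1–4 for single to quadruple, 5 aromatic, 6 one-and-a-half, 7
two-and-a-half) and optional E/Z stereo descriptors.  Stereo and chirality
flags are taken from input annotations (templates or topology files); no
geometric perception is performed.  Condensation absorbs every uncharged
H/halogen leaf bonded by order one; the absorbed counts are stored per
element in the order H, F, Cl, Br, I.  Astatine has no count field and a
qualifying astatine leaf raises an error, as does a parent with more than
seven absorbed leaves of one element (3-bit fields) or a condensed degree
above seven.

Two points the label layout leaves open were resolved as follows:

* **Degree fields refer to the condensed graph.**  Matching happens on
  condensed graphs, so degrees stored in labels must be self-consistent
  there; a CH3 group has degree 1 after its hydrogens are absorbed.
* **Cycle flags use simple cycles up to length 8**, found by bounded
  cycle enumeration (`networkx.simple_cycles(length_bound=8)`), not a
  smallest-ring basis; this avoids any tie-breaking among ring systems.
  The test suite checks the flags against an independent brute-force
  path-DFS cycle enumerator.

## Fragment generation

Automated enumeration walks every connected induced subgraph exactly once
(canonical anchored expansion over vertex bitmasks: a subgraph is grown
only from its minimum vertex by exclusive frontier neighbors), applying
the two boundary rules incrementally as forbidden-edge masks:

1. boundary edges must be single or aromatic (cores never cut multiple
   bonds; aromatic cuts keep fused ring systems fragmentable);
2. boundary edges need at least one carbon endpoint.

Rule 3 — every leaf of the core+overlap subgraph in the overlap must lie
at graph distance ≥ k from the core — is read as *distance to the nearest
core vertex*; read literally ("to all vertices") it would be unsatisfiable
for any overlap neighbor at k = 1.  With k = 1 the rule is vacuous; it is
enforced for k ≥ 2.

Defaults: all three rules enabled, minimum core size 2 for generation,
overlap length k a property of the athenaeum (default 1).  Duplicate cores
(same molecule, same vertex set) are dropped; chemically identical
fragments from *different* molecules are kept, as independent parameter
observations.  The superset tree links each fragment to its immediate
supersets, each superset referenced by exactly one (the first-inserted)
subset; for user libraries with arbitrary size gaps the tree is rebuilt
pairwise.

## Matching

Matching is **induced** subgraph isomorphism: fragments are induced
subgraphs of their sources and their degree label fields assume full
neighborhoods, so a non-induced embedding would be inconsistent with the
labels it matched.  The matcher is a backtracking search with a
greatest-constraint-first vertex order and candidate seeding from a
masked-label index; it is validated against an exhaustive
injective-mapping oracle on hundreds of random labeled graph pairs.  The
default mask compares element, formal charge, condensed counts and degree
on vertices, bond order and endpoint degrees on edges — cycle flags,
chirality and E/Z are ignored unless requested.

## Tallying, dangling terms and distillation

Atom observations (type code, partial charge) flow from core atoms to
their images; every mapping occurrence contributes, so a fragment matching
one site in two symmetric ways contributes twice.  Bonded terms donate
when fully inside the core or *dangling*: one of two bond atoms, two of
three angle atoms, or two adjacent chain atoms of a dihedral in the core;
impropers additionally require their central atom in the core and are
otherwise treated like dihedrals.

Proper torsions pool on the target's **central bond**, and a dangling
torsion is tallied once its two central atoms are mapped — its outer atoms
may lie beyond the fragment.  This is the "edge-terminated core" reading
of dangling terms, and it is load-bearing: under the stricter
all-four-atoms-inside-the-fragment reading, the backbone ψ torsion of any
residue preceding a proline is provably unassignable from a k = 1 library
built from linear tripeptides (a fragment whose core contains the carbonyl
carbon pulls the tertiary prolyl nitrogen into its overlap and cannot
match elsewhere; with the carbonyl in the overlap, the outer oxygen cannot
be inside the fragment at all).  The relaxed rule parameterizes cyclic
peptides with Xxx-Pro junctions completely, which is the behavior this
package targets.

Distillation: per-atom charge = arithmetic mean of the pooled charges;
atom and bonded types = mode of the pooled codes, ties broken toward the
lowest code (deterministic and force-field-neutral).  Self-consistent
athenaeums are verified after their pass: type tallies must be unanimous
and per-atom charge spreads must stay within 1e-6 e (configurable);
violations abort with a report naming the element and values.

Charge correction adds the whole residual between assigned and expected
total charge to the most positive unprotected atom (if assigned <
expected) or the most negative one (if assigned > expected), ties to the
lowest atom index; the adjusted charge is computed as
`expected − Σ(others)` so the total is exact to machine precision.  Atoms
assigned from self-consistent athenaeums are protected; if all atoms are
protected and the totals disagree, the run fails loudly rather than
silently editing trusted values.

Picking defaults: fragments with core size ≥ 4 are tested, no maximum;
the loop stops early once every atom and required term has a non-empty
pool.  Note that small-core fragments (e.g. the three-carbon heptane
cores, or the fragments needed for short Dab side chains) only participate
when `min_core` is lowered to 2, which is how the bundled corpus was
exercised.

## Target topology convention

A bare target graph does not say which bonded terms its topology must
contain, so one convention is applied to targets and template-built
sources alike: a bond per edge; an angle per connected triple; one proper
torsion per central bond whose endpoints both have degree ≥ 2 (lowest-index
outer atoms as representatives); an improper for every three-neighbor atom
that is carbon, nitrogen, or engaged in a multiple/aromatic bond (covering
united-atom stereocenters and planar sp2 centers).  Because both sides use
the same convention, "fully parameterized" is well defined.  Impropers on
some prochiral centers (e.g. valine Cβ) are generated that a curated force
field would omit; this is cosmetic for matching purposes.

## The bundled corpus and the force-field fixture

`molbuilder` reconstructs the whole test corpus from sequences: the
nineteen listed tripeptides (charged termini; Asp/Glu deprotonated,
Lys/Arg protonated, His neutral with the proton on NE2), heptane, and the
three targets — a linear octapeptide, the cyclic heptapeptide Axinellin A,
and the branched cyclic lipopeptide polymyxin B3 (octanoyl cap, six Dab
residues, a D-Phe, and a Dab-side-chain-to-Thr-backbone amide closure).
The twentieth tripeptide's sequence is not on record; a configurable
stand-in (default Gly-Asp-Gly — Asp is the only residue missing as a
central) is always flagged, and library counts are reported with and
without it.

Templates are united-atom: aliphatic hydrogens are merged into CHn
pseudo-atoms at the template level, polar and aromatic hydrogens are
explicit and subsequently handled by graph condensation.  Aromatic rings
(Phe, Tyr, Trp, His) carry order-5 edges; carboxylates and the guanidinium
group are represented localized (one double bond, the formal charge on the
singly bonded heteroatom).  Partial charges form zero- or integer-sum
charge groups and are chemically sensible, but the bundled tables are a
**reduced fixture in the style of GROMOS 54A7, not the published force
field**, which is not redistributed.  Bonded type codes are composed
deterministically from the participating atom type codes (bonds from the
sorted pair, angles from the central type plus sorted ends, torsions from
the central bond's pair), so independently built molecules agree on codes
without shared lookup tables; the bundled IFP lists exactly the codes in
use.  The user-directed fragment layout cuts one core per residue with the
neighboring amine/carboxo groups as overlap (62 fragments over the 21
molecules: three per tripeptide plus two from heptane).  The historical
reference count for this layout (44 over the twenty tripeptides) could not
be reconciled with the procedure as described and is treated as an open
question; the tests therefore assert only that the count is stable across
rebuilds.

**What passing tests show, and what they do not.**  The corpus exercises
peptide chemistry broadly (charged termini and side chains, aromatic and
fused-ring systems, cyclic backbones, branches, non-natural residues) and
the full pipeline end to end, including the coverage-gap behavior at
Xxx-Pro junctions.  It does not show that the *parameter values* are
simulation-quality: the fixture tables are placeholders, real inputs
carry pdb2gmx-derived topologies whose term conventions may differ in
detail from the convention above, and real PDB files bring conformational
and naming noise the generated fixtures do not have.  Because the fixture
octanoyl cap reuses the backbone carbonyl types, the fatty-acid/peptide
junction of polymyxin B3 is matchable here, whereas with genuine lipid
chemistry it would expose an athenaeum deficiency.

## Numerical and bookkeeping choices

* Graph indices are 0-based in memory; PDB/MTB/ITP are 1-based, converted
  at the I/O boundary.  PDB parsing keeps the first conformer and ignores
  altloc/occupancy otherwise; elements come from columns 77–78 with an
  atom-name heuristic fallback.
* Bond orders and formal charges are absent from PDB: they are restored
  from the residue template library keyed by (residue name, atom name),
  with terminal variants detected from atom presence (H1/H2/H3, OXT) and
  an optional sidecar file overriding individual bond orders.
* Charges are written to 5 decimals; unassigned parameters are emitted as
  a visible placeholder token, and the full parameter pool is written as
  comment lines so assignments can be audited or overridden.
* Everything is deterministic: sorted iteration orders, canonical mapping
  order, lowest-code/lowest-index tie-breaks.  The CLI accepts `--seed`
  for interface stability; repeated runs are byte-identical.
* Degenerate inputs: an empty athenaeum list yields an all-placeholder
  topology; a single-vertex molecule yields no fragments; fragments whose
  mapped term does not exist in the target (e.g. an angle whose image
  atoms are not mutually bonded) are skipped and logged.

## Known limitations

* ITP files carry parameters, not chemistry; molecules read from ITP have
  inferred elements and unit bond orders.  MTB (with this package's
  element/order columns) or PDB+templates are the structural sources.
* No automatic perception of formal charges, bond orders, aromaticity or
  stereochemistry from coordinates; inputs must be annotated or covered
  by templates.
* No capping/extraction of unmatched regions for external parametrization;
  gaps are reported and emitted as placeholders.
* Parameter quality is bounded by the athenaeum: fragment sources with
  poor parameters, or libraries missing the target's chemistry, propagate
  directly into the output.  Overlap length trades coverage against
  chemical-context selectivity.
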
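# Methods

## The mechanical model

A protein is modeled as a *body-bar-hinge framework*. Every non-terminal
atom, together with its covalently bonded neighbours, forms one rigid body:
bond lengths plus bond-angle constraints remove all internal freedom of such
a star, so two bodies whose anchor atoms are bonded share exactly the two
bonded atoms and can only rotate about their common bond. In graph terms
each body is a node with 6 degrees of freedom, a rotatable bond a hinge
(5 parallel edges), and every other constraint a bundle of generic bars:

| interaction | bars | rule |
|---|---|---|
| rotatable covalent bond | 5 | distance &le; covalent-radius sum + 0.4 &Aring; |
| locked covalent bond | 6 | peptide bonds, aromatic/proline ring bonds, sp2 template pairs (C=O, carboxylate, amide, guanidinium) |
| hydrogen bond | 5 (configurable) | donor-acceptor &le; 3.5 &Aring;; D-H&hellip;A &ge; 110&deg; when explicit hydrogens exist |
| hydrophobic tether | 2 (configurable) | side-chain C/S pairs, residues &ge; 2 apart, distance &le; vdW sum + 0.25 &Aring; |

The cutoffs follow the constraint-counting lineage of rigidity software for
molecules; all are exposed in the run configuration. Hydrogen-bond
detection additionally excludes 1-3 pairs (atoms sharing a covalent
neighbour): without that exclusion every peptide O(i)&hellip;N(i+1) pair
(~2.25 &Aring;) would register as a spurious hydrogen bond in unprotonated
files. Unprotonated structures are supported by the distance-only branch;
an energy-based hydrogen-bond scorer is deliberately out of scope.

Parallel bars beyond 6 between one body pair are combinatorially redundant
in a (6,6) framework. The stored edge multiset keeps every bar (so
provenance and raw counts stay visible); the pebble game consumes the
per-pair multiplicity capped at 6, and the independent/redundant accounting
refers to that capped total.

## The (6,6) pebble game

Generic rigidity of the body-bar multigraph is decided combinatorially.
Each node holds 6 pebbles; an edge is independent iff 7 pebbles can be
gathered on its endpoints (depth-first search over the directed graph of
previously inserted edges, reversing the augmenting path); inserting an
independent edge consumes a pebble. By Tay's theorem the independent edges
form a maximal (6,6)-sparse subgraph, so their count is the generic rank,
and the number of internal degrees of freedom is 6n − 6 − rank. For a
disconnected graph this convention counts the relative motions between
components as free degrees of freedom, which keeps the pebble game and the
matrix oracle (below) on the same scale.

Rigid components are maintained during the game: when, after an insertion,
only 6 pebbles remain collectable on the edge's endpoints, every vertex
with no directed path to a free pebble (outside those 6) joins the new
component. For l = k = 6 maximal rigid sets are vertex-disjoint, so the
components form a partition of the bodies, tracked with union-find; edges
inside a finished component are redundant without further search. Atom-level
clusters are the unions of their bodies' atoms and may overlap at shared
atoms (for example a C&alpha; sitting in two adjacent backbone bodies),
which matches how molecular rigid-cluster decompositions are usually drawn.
The result is independent of edge-insertion order; a dedicated test replays
shuffled insertion orders.

### Independent verification

`rigidity_matrix_oracle` realizes the multigraph as generic bars in 3-space:
each unit of multiplicity becomes one bar between random points p on body i
and q on body j, contributing the row
((t_i + &omega;_i &times; p) − (t_j + &omega;_j &times; q)) &middot; (p − q) = 0
for body screws (&omega;, t). Degrees of freedom = nullity − 6; bodies are
mutually rigid iff their screw components agree (within 1e-8, orthonormal
nullspace basis) in every nullspace vector. The construction repeats at
3 seeds and keeps the maximal-rank outcome to guard against an unlucky
non-generic placement. Modeling a hinge as 5 generic bars is
rank-equivalent to the true hinge constraint in the generic setting, which
is exactly what the pebble game computes, so the two routes must agree
exactly — and a 500-graph randomized test plus the acceptance script hold
them to that. The oracle is dense linear algebra and refuses graphs beyond
50 bodies.

## In-silico mutation

Mutation to glycine removes every hydrogen bond and hydrophobic tether
incident to the residue's side-chain atoms (C&beta; and beyond); mutation
to alanine keeps C&beta;'s contributions. Covalent bonds and atoms are
never removed — the body topology is preserved and only constraints drop,
i.e. no cavity remodeling or repacking is attempted. The score is the
percentage decrease of the largest rigid body measured in atoms
(100·(LRB_wt − LRB_mut)/LRB_wt, plus the raw atom-count drop); the
criticality threshold &tau;_r defaults to 0 with a strict inequality, so
any nonzero shrinkage counts as a rigidity detection. Constraint removal is
monotone (the mutant LRB can never exceed the wild type), and residues
contributing no side-chain constraints score exactly 0 without recomputing
the game.

## Conservation score

Given ET ranks for one chain, c_i = (&mu; − rank_i)/&sigma;. &sigma; is the
population standard deviation by default (z-score convention; the sample
estimator is available by configuration — the choice only rescales all
scores by a common factor and cannot change any flag). A residue is
conservation-critical iff c_i > &tau;_c, default 0, strict: a residue
exactly at the chain average is not critical. The score is affine-invariant
in the ranks, so integer coverage ranks and real-valued rank variants give
identical flags. All-equal ranks leave the score undefined and raise an
error rather than guessing. Multi-chain inputs get independent profiles per
chain.

## Combination and confusion analysis

Per residue the two boolean flags define four agreement categories
(both-critical, both-noncritical, conservation-only, rigidity-only) and the
combined detector is their OR. Per-protein summaries report the seven
percentage columns (critical by conservation / by rigidity / by both /
noncritical by both / total match / only-conservation / only-rigidity) with
half-up rounding to one decimal, chosen to reproduce printed benchmark
digits; cohort summaries take unweighted means across proteins. A mutation
with measured &Delta;&Delta;G is experimentally critical iff
−10 &le; &Delta;&Delta;G &lt; 0 kcal/mol (upper bound exclusive: a mildly
stabilizing +0.48 mutant is a negative), and confusion labels are
TP/FN/FP/TN of combined detection against that ground truth. The
binding-site tally (records with &Delta;&Delta;G &lt; −1.0, solvent
accessible, with &ge; 1 annotated binding partner) is reported for
orientation only; it is sensitive to the exact SASA cutoff and is not a
gated number.

## Solvent-accessible surface area

An internal Shrake-Rupley implementation: a 1.4 &Aring; probe, 960
golden-spiral sphere points per atom (deterministic), per-residue sums over
all the residue's atoms. The point set is expressed in the molecule's
principal-axes frame (variance-sorted, sign-fixed eigenvectors), which
makes the discretized areas exactly invariant under rigid transforms of the
input; without that the discretization error would vary by a few percent
with orientation. Published per-residue SASA values computed by other
implementations differ by tens of percent depending on radii sets and
summation conventions, so SASA agreement is treated as directional, not
exact.

## Synthetic data

The toy generator builds poly-alanine chains (N, CA, C, O, CB) with
standard bond geometry from per-residue torsions and *plants* interactions
by construction:

- backbone contacts: the carbonyl oxygen of residue i is aimed so that
  O(i)&hellip;N(i+2) lands at 2.7-3.1 &Aring; (0.4+ &Aring; inside the
  cutoff), which locks &phi;/&psi; of residue i+1 through a rigid
  body-bar triangle; a run of such contacts makes a backbone segment one
  rigid cluster. Unplanted oxygens are aimed &ge; 3.6 &Aring; from every
  nitrogen.
- tethers: C&beta; atoms of chosen residue pairs are re-aimed toward each
  other into the 2.7-3.4 &Aring; window while staying &ge; 3.75 &Aring;
  from all other side-chain carbons.

Positions are chosen by deterministic feasibility search over a Fibonacci
sphere of candidate directions; the seed only re-poses the finished
structure rigidly (rotation + translation), so topology is a pure function
of the specification. Every generated structure is validated by running the
real detectors: the detected noncovalent set must equal the planted set or
generation fails.

The `two_domain_hinge` geometry leaves one &phi;/&psi; pair free at the
junction per planted tether, so the wild type (2g free torsions vs 2g
tether bars) is exactly rigid with no redundancy: mutating any
tether-bearing residue splits the assembly into two rigid domains and the
LRB drops by ~40-50 %, while every other residue scores exactly 0. Because
the tethers ride on C&beta;, a glycine scan severs them but an alanine scan
does not — the two mutation modes are distinguishable on the same toy. The
junction torsions come from a precomputed candidate list (searched once for
sterically open, bridgeable junction geometries); candidates are tried in
order until the planting validation passes. The generator supports 8-10
residues and 1-2 tethers — longer compact-coil domains wrap into the
junction corridor, and 10 residues (~41 bodies) already approach the matrix
oracle's size limit.

What the toys do **not** emulate: real side-chain diversity and packing,
hydrogen-bond networks with explicit hydrogens, solvent effects, crystal
contacts, or realistic rigidity percolation in globular cores. Passing
tests on toys therefore validates the machinery (detection windows, model
construction, counting, mutation bookkeeping), not the biological accuracy
of any particular cutoff set on real structures.

The synthetic rank files draw planted-conserved ranks from U(1, 5) and the
rest from U(60, 100); the gap guarantees the strict positive-score rule
recovers exactly the planted subset. A zero conserved fraction produces the
degenerate all-equal file used to exercise the &sigma; = 0 error path.

The benchmark tables of the published glycine/alanine comparison study
(42-protein agreement percentages, single-method detections, and the
per-mutation &Delta;&Delta;G tables) are embedded as code fixtures with
row-count checksums, so the reporting layer can be tested against printed
numbers without downloads. Two printed confusion labels are internally
inconsistent with the stated rules (one mutation flagged conserved yet
labeled false negative; one stabilizing mutation labeled false negative);
the tests document both and assert agreement on the other 52 rows.

## Numerical choices

- Covalent radii: single-bond radii (C 0.77, N 0.75, O 0.73, S 1.02,
  H 0.31 &Aring;); van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20 &Aring;.
- Alternate locations keep the highest-occupancy conformer, ties broken
  toward altloc 'A'; multi-model files read one model (default the first);
  HETATM groups and waters are dropped by default.
- Oracle nullspace via SVD with rcond 1e-10; screw-equality tolerance 1e-8.
- Ties for the largest rigid body go to the component whose smallest body
  id is smallest, making all reported LRB values deterministic.
- Rounding of report percentages is decimal half-up, not banker's.

## Known limitations

- Generic rigidity only: geometric singularities (exactly parallel
  constraint geometries) are modeled by their generic rank, as in all
  pebble-game software.
- Side-chain constraint removal keeps atoms in place; mutations that
  repack or collapse cavities are outside the model.
- The pipeline assumes rank files and structures agree on residue
  numbering and errors out otherwise, listing the unmatched residues.
- HETATM groups are excluded from the model by default, so per-protein
  percentages can shift slightly for structures whose published analyses
  included ligands.
- Binding partners are consumed as a pre-supplied annotation column;
  no interface database is queried.
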
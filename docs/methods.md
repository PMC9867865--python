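# Methods

## Graph model

A molecule is a connected labeled multigraph over *united atoms*: every
heavy atom absorbs its bonded hydrogens in a preprocessing step and its
valence is reduced by the number absorbed, so hydrogen never appears as a
vertex (the only exception is H2 itself, represented as two H vertices).
The united-atom type is the pair (element, attached-H count); atoms of equal
type are interchangeable.  Connectivity is a symmetric adjacency matrix of
integer bond orders 0–4 with zero diagonal; for a finished molecule every
row sums to the atom's effective valence.  Valences are fixed per element
(C 4, N 3, O 2, halogens and H 1, Si 4, B 3); charged species, radicals and
isotopes are out of scope.

Atom types are ordered canonically by decreasing effective valence, ties by
element symbol, then by decreasing attached-H count.  The ordering is
arbitrary but fixed: it decides which matrix of an isomorphism class is
"the" canonical one and nothing else; all counts are invariant to it.

The degree of unsaturation of a formula uses the closed form
`(2 + Σ_e n_e (δ_e − 2)) / 2`, which for fixed valences counts one per ring
or double bond and two per triple bond.  The cycle count is the cyclomatic
number `E − N + 1` of the simple-graph skeleton with bond multiplicity
ignored, so a double bond is an unsaturation but never a cycle; the two
quantities are filtered independently.

## Hydrogen distribution

For each concrete formula the hydrogens are distributed over the heavy
atoms as multisets of (element, n_H) with `0 ≤ n_H ≤ δ − 1` (n_H = δ only
for a single-atom molecule such as CH4).  Distributions that cannot form a
connected molecule are dropped immediately: a zero effective valence in a
multi-atom molecule, an odd valence sum, total valence below `2(N − 1)`, or
one atom demanding more bonds than the rest can supply.  United-atom
constraints from the formula (`{CH1}` …) pin their share of hydrogens.
Distinct distributions give disjoint isomer sets, because the united-atom
type multiset is itself a graph invariant.

## Orderly generation and canonicity

Constitutional isomers are exactly the connected, lexicographically maximal
adjacency matrices (row-wise upper-triangle comparison, first difference
decides).  The generator performs a depth-first search over upper-triangle
cells in row-major order, trying larger bond orders first; emissions are
therefore strictly decreasing.  Three prunes bound the tree:

1. *Valence bookkeeping* — a cell never exceeds the remaining valence of
   either atom, the final cell of a row must absorb the row's residue, and
   a row is abandoned when the remaining cells cannot absorb it.
2. *Residual realizability* — after each completed row the remaining
   degrees must have an even sum, no atom may exceed the sum of the others,
   and a completed prefix without a bond into the suffix is disconnected
   and abandoned.
3. *Semi-canonicity* — after each completed row r, if some type-preserving
   relabeling that maps the filled rows {0..r} onto themselves makes the
   filled rows lexicographically larger, no completion can be canonical.
   This is sound because such a relabeling evaluates only entries in filled
   rows of any completion.

The (semi-)canonicity test is a backtracking search over relabelings
organized by target row.  For each candidate pre-image of the current row
it computes the greedy lexicographic maximum of the permuted row over all
cell-respecting assignments of the remaining columns: per aligned
position/source cell, values sorted descending meet positions sorted
ascending.  A maximum exceeding the actual row proves non-canonicity; a
maximum below it kills the branch; equality refines every cell by realized
value and recurses into the next row.  On the complete matrix the test is
exhaustive, and the relabelings that reach the final row with equality
everywhere are precisely the automorphism group Aut(A), returned with each
emitted isomer.  This partition-refinement formulation was chosen over a
naive permutation scan because block sizes grow quickly (an n-alkane has
up to n − 2 equivalent CH2 atoms); correctness is certified against
brute-force oracles rather than against any particular refinement scheme.

## Canonical SMILES

The writer needs a canonical atom ranking.  Iterative refinement starts
from (element, attached H, effective valence, degree, bond-order multiset)
and refines by sorted neighbor ranks until stable.  Remaining ties are
broken by individualizing each tied candidate of the first non-singleton
class in turn, re-refining, and keeping the labeling whose relabeled
adjacency matrix is smallest.  The branch-and-minimize step makes the
labeling canonical in the strict sense — any input labeling of the same
molecule yields the same string — not merely deterministic; for molecules
of enumeration size the extra branching is negligible.  The string is then
a depth-first traversal from the top-ranked atom, neighbors in rank order,
ring closures numbered in discovery order (`%nn` beyond 9), bond symbols
`= # $`, hydrogens implicit except inside stereocenter brackets.

Stereo annotations are defined *relative to the string itself*:
configuration 0 at a tetrahedral center writes `@@` and 1 writes `@`; for a
cis/trans bond 0 is trans and 1 cis, encoded with directional slashes.  The
neighbor order of a center is its string order — preceding atom, implicit
hydrogen, ring closures, then branches; a leading stereocenter treats its
hydrogen as the neighbor visited before it.  Slash tokens are assigned by
processing stereo double bonds in string order; a directionality bond
already annotated by a conjugated predecessor keeps its token and the
partner bond is chosen to realize the requested relation, which produces
`Br/C=C\C=C/Br` rather than the invalid `Br/C=C\/C=C\Br` for the cis,cis
diene.

## Stereoisomer enumeration

Candidate tetrahedral centers have four singly-bonded substituents
(implicit H included, at most one); candidate cis/trans half-centers are
tetravalent atoms outside any cycle with exactly one double bond and two
singly-bonded substituents.  A candidate with two identical monovalent
substituents is discarded outright.  A candidate is *true* when its four
first neighbors differ, or when no automorphism fixes it while permuting
its first neighbors; otherwise it is a *potential para* center.  Two
potential half-centers joined by a double bond form a cis/trans center; a
pair in which at least one half was discarded only by the automorphism test
is a para cis/trans candidate.

True stereoisomers: binary counting over configuration vectors in string
order; a vector is reported unless some π ∈ Aut(A) produces a
lexicographically smaller permuted vector.  Parity transport follows the
local-notation rules: when π carries center j onto center i, the new entry
is c_j for an even permutation of the neighbor order and ¬c_j for an odd
one; for cis/trans centers the entry is preserved when both or neither
directionality neighbor maps onto the image's directionality neighbor and
flipped when exactly one does.

Para stereoisomers are generated per true stereoisomer.  Aut^true is the
stabilizer of the true vector under the parity action.  For each binary
para vector, centers fixed by an element of Aut^para (the stabilizer of the
current para vector within Aut^true) that swaps two of their immediate
neighbors are deactivated to −1; deactivation is monotone, so the loop
reaches a fixed point within one pass per center and cannot oscillate.
Vectors are deduplicated under Aut^true with −1 read as 0.  Enantiomers are
located by flipping every tetrahedral entry (−1 fixed) and searching the
reported list for a group-equivalent vector; a self-match is a meso form
and gets no partner.

*Para retention.*  A potential para center is kept only if the molecule has
at least one true stereocenter and the candidate either lies in a cycle or
is the equal-distance midpoint on a shortest path between two
automorphism-swapped true stereocenters.  Ring para centers that would
depend only on other para centers (the cis/trans-1,4-dimethylcyclohexane
situation, and the cage hydrocarbons where every center is para) are
deliberately not enumerated; cross-validation of the emitted strings
against an independent parser showed that the local-parity bookkeeping is
not a faithful quotient for such systems, so they are excluded wholesale
rather than half-handled.  Ring double bonds, cumulated double bonds and
centers of valence above four are likewise not treated as stereogenic.
These are accepted limitations of the method, shared with the program
lineage it reimplements; counts for molecules whose stereochemistry lives
entirely inside rings are therefore lower bounds.

## Filters and substructures

The unsaturation restriction is applied per concrete formula before any
matrix is generated; bond-order tallies, total bonds and cycle count are
checked on each emitted isomer; only survivors are stereo-expanded.
Substructures (atom list plus upper-triangle adjacency stack, wildcards and
attached-H-pinned atoms allowed, SMILES accepted for convenience) are
counted as subgraph monomorphisms with exact bond-order matching, collapsed
to atom/bond sets so automorphic images count once, then accepted greedily
in sorted order under the convention that accepted matches share at most
one atom pairwise — this reproduces the counts 3 and 1 for the patterns CC
and CCC in butane.  The monomorphism search is delegated to networkx's VF2
implementation; the classic backtracking search it replaces is standard
machinery, not part of this package's contribution.  Kekulé duplicates are
merged by marking the bonds of every six-ring with alternating single and
double bonds and comparing canonical keys of the marked graphs; larger or
fused aromatic systems are not recognized.

## Reference implementations and test scaling

The `oracle` module certifies the enumerator on small instances with
deliberately naive re-derivations: all upper-triangle matrices with labeled
hydrogen compositions, deduplicated by VF2 isomorphism (capped at 8 heavy
atoms), and stereo counts as orbits of parity assignments under the
exhaustively computed automorphism group (capped at 10 united atoms,
acyclic molecules).  The orbit formulation is independent of the
true/para machinery: identical substituents merge configurations through
automorphism transport without ever being classified.

Problem sizes in the default test run were chosen to keep the suite at a
few minutes on one core: the alkane series is checked to n = 14
(1858 constitutional, 6563 spatial), constitutional oracle equivalence runs
exhaustively over all C/N/O/H formulas with up to four heavy atoms plus
selected five-heavy-atom formulas, and stereo oracle equivalence covers a
fixed panel of acyclic C/O/Cl/Br/H formulas with up to five heavy atoms
plus individual para-rich molecules at up to eight atoms.  The synthetic
fixtures exercise every code path (pinned hydrogens, multiple bonds, rings,
conjugated stereo chains, meso forms, active and inactive para centers);
what they do not model is anything beyond the fixed-valence, closed-shell
molecule class itself.
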
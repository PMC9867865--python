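# molenum

Exhaustive, duplicate-free enumeration of the **constitutional isomers** of a
molecular formula, followed by enumeration of all unique **stereoisomers** of
every survivor, reported as canonical stereo-annotated SMILES strings.

`molenum` is aimed at cheminformatics tasks where a complete, provably
non-redundant list of structures matters: coverage analysis of chemical
space, structure elucidation candidates, virtual-library seeds, and
combinatorial force-field parameterization over whole compound families.

## The method in brief

A molecule is modeled as a connected labeled multigraph: a vector of
*united atoms* **a** (heavy atoms with their hydrogens absorbed and valences
reduced accordingly), a degree vector **d** of effective valences, and a
symmetric adjacency matrix **A** of bond orders.  Two matrices describe the
same molecule exactly when a type-preserving index permutation π maps one to
the other, `PᵀAP = A′`.

* **Constitutional isomers.**  Each isomerism class is represented by its
  *canonical* matrix — the lexicographically largest under row-wise
  upper-triangle comparison over all type-preserving relabelings.  The
  generator fills the upper triangle in row-major order, largest bond order
  first, so complete matrices appear in strictly decreasing lexicographic
  order (orderly generation).  Valence bookkeeping, degree-sequence
  realizability and a per-row semi-canonicity test prune the search tree;
  each emitted matrix is connected, canonical and carries its automorphism
  group `Aut(A) = {π : PᵀAP = A}` as a by-product of the canonicity test.
* **Stereoisomers.**  Tetrahedral centers (four singly-bonded substituents,
  implicit H included) and cis/trans double bonds (two tetravalent
  half-centers outside rings) are classified as *true* — substituents differ
  constitutionally, i.e. no automorphism fixes the center while swapping two
  of its first neighbors — or *para* — substituents differ only by stereo
  configuration.  Binary configuration vectors over the true centers are
  deduplicated under `Aut(A)` using local SMILES parity rules (an even
  permutation of a center's neighbor order preserves the `@`/`@@` or slash
  encoding, an odd one flips it).  Para centers are then activated per true
  stereoisomer with the subgroups `Aut^true(A) ⊇ Aut^para(A)`, inactive
  centers marked `-1`, and the resulting ternary vectors deduplicated with
  `-1` read as `0`.  Enantiomer partners (or meso self-images) are
  cross-referenced.
* **Filters.**  Formulas accept counts as integers, lists and ranges
  (`C[1-20]H[4-42]`), united-atom constraints (`{CH1}1{CH2}2{OH1}3`),
  property restrictions (unsaturations, bond-order tallies, cycle count) and
  substructure occurrence requirements counted under a maximum one-atom
  overlap convention.  Kekulé duplicates of six-ring aromatics are merged.

## Worked example

```python
>>> from molenum import RestrictionSet, count_isomers, enumerate_isomers
>>> for record in enumerate_isomers("{CH1}1{CH2}2{OH1}3"):
...     print(record.formula, record.smiles, len(record.stereoisomers))
C3H8O3 C(CO)(CO)O 1
C3H8O3 C(CCO)(O)O 1
>>> count_isomers("C3H8O3")          # unrestricted: (constitutional, spatial)
(28, 36)
>>> count_isomers("C5H8Br2", RestrictionSet(cycles=0))
(52, 106)
```

The two strings are glycerol (`OCC(O)CO`) and 1,2,3-propanetriol's chain
isomer `OCCC(O)O`; neither has stereocenters, so each contributes one
spatial isomer.  Dropping the attached-H constraints admits 28 skeletons and
36 spatial isomers; the acyclic dibromide run shows the stereo expansion at
work (52 constitutional, 106 spatial isomers, each with one double bond).

The same runs from the shell:

```console
$ molenum --formula "C3H8O3" --count-only
constitutional isomers: 28
spatial isomers: 36
$ molenum --formula "C4H10" --out butane.xml     # XML list with DTD
```

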
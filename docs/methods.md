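# Methods

This note documents the models, parameter choices and numerical conventions
implemented in `structmotif`, and what the synthetic fixtures do and do not
establish about real crystallographic data.

## Scope and assumptions

The method predicts the sequence specificity of a DNA-bound protein from a
single co-crystal structure.  Its central assumption is **backbone
rigidity**: when a base pair is mutated, the sugar–phosphate backbone and
every other residue keep their native coordinates, and only the two base
moieties are exchanged as rigid bodies.  This is reasonable for a small
number of mutations in a site; it degrades as the mutation load grows,
which is why the per-mutant RMSD is reported and why the default maximum
number of mutations for PFM construction is two (larger values admit
structures whose real conformational change the model cannot see).  There
is no relaxation, solvation, or protein-side design.

## Structure handling

PDB parsing and writing are delegated to gemmi.  On load, hydrogens are
dropped (all scoring and contact logic is heavy-atom only), alternate
locations other than blank/'A' are discarded, and the first model is used.
Chains containing at least one standard amino acid are protein chains,
chains with at least one deoxyribonucleotide (DA/DT/DC/DG, legacy A/T/C/G
accepted) are DNA chains; a chain containing both is rejected.  Waters and
ligands are retained but never scored.  MSE is typed as MET; unrecognized
nucleotides are excluded from duplex detection.

**Duplex detection.**  Two bases are paired when they are Watson–Crick
complementary and the purine N1 – pyrimidine N3 distance is at most 3.5 Å;
a duplex is reported for every antiparallel run of at least three
consecutive pairs.  The criterion is deliberately minimal: it is exact on
idealized fixtures and robust on crystal structures, at the cost of missing
wobble or heavily distorted pairs (out of scope).  A self-complementary
hairpin is never paired with itself.

**Contacts.**  A base pair is flagged as protein-contacting when any heavy
atom of either **base moiety** (sugar–phosphate excluded) lies within 4.5 Å
of any protein heavy atom.  Restricting the DNA side to the base moiety
makes the flag mean "the protein reads this base", not "the protein grips
the backbone"; the threshold is a parameter should the alternative
convention be wanted.

## Base templates and replacement

Every base type carries a canonical frame: glycosidic nitrogen (N9 purines,
N1 pyrimidines) at the origin; best-fit base-plane normal on +z, with the
sign fixed by the chirality of the ring traversal p → anchor → q so a
mirror image can never slip through; and the interior bisector of the
C4–N9–C8 (purine) / C2–N1–C6 (pyrimidine) angle, projected into the plane,
on +x.  These bisectors point along the glycosidic direction, which keeps
purine↔pyrimidine swaps geometrically sensible.  The plane fit uses all
ring atoms (9 purine, 6 pyrimidine) via the smallest principal axis of
their covariance.

Templates are built by mapping each instance of a base to its canonical
frame, then refining with two rounds of least-squares (Kabsch) rigid
superposition onto the running mean before atom-wise averaging.  The
refinement uses every atom rather than only the frame atoms, so coordinate
noise enters the average at roughly σ/√n instead of being amplified through
the three-atom bisector.  Atoms missing from some instances are averaged
over the instances that have them.  The shipped default templates use the
idealized geometries described below; averaging over any user-supplied
structure collection is the same code path at any scale.

Replacement maps the new template through the inverse canonical frame of
the old base: anchor-on-anchor, normal-on-normal, bisector-on-bisector,
then deletes the old base atoms.  Backbone coordinates are copied bitwise.
RMSD between mutant and native is computed over equivalent atoms (same
chain, residue number, atom name) without re-superposition, because mutants
live in the native coordinate frame by construction.

## The statistical potential

Atom types are residue-specific — the Cα of cysteine is a different type
from the Cα of alanine — giving exactly 167 protein and 82 DNA heavy-atom
types from the standard residue dictionaries.  OXT and terminal-phosphate
variants are left untyped to preserve those counts; 5′-terminal residues
simply contribute fewer atoms.

Defaults: bin width 0.5 Å, cutoff 15 Å, pseudocount 0.5 per (i, j, bin).
All three are configurable.  The score is S = −ln(P/P_ref) with P the
pseudocounted per-type-pair distance distribution and P_ref the pooled
distance distribution.  P_ref is pooled over the *pseudocounted* counts so
that every bin has positive reference mass and scores stay finite wherever
counts + pseudocount > 0; with a pseudocount of zero the convention reduces
to the raw pooled distribution, uniform count tables score identically
zero, and doubling every count leaves S unchanged.  ΔG is the sum of S over
all typed protein–DNA pairs within the cutoff (pairs beyond it contribute
nothing), reported dimensionless with kT = 1.  Potentials serialize to a
self-describing TSV of non-zero counts; scores are recomputed on load, so
the round trip is bit-exact.

## Selection, PFM and scoring

All mutants with at most k mutations inside the chosen position range are
enumerated (3 alternatives per position; Σ_m C(w,m)·3^m sequences), built,
and scored.  The flexibility threshold is T = |min ΔΔG| over mutants;
records with ΔΔG ≤ T are selected, which always includes the native
sequence and, when every mutant is worse than native, still admits the
least-bad mutants within the tolerance.  The PFM counts each selected
sequence once, unweighted, native included — energy weighting is a
plausible alternative but introduces a scale dependence the selection rule
already encodes.

PFM scoring uses Score = Σ log2((f + ε)/0.25) with ε = 0.01 and a uniform
background.  Any strictly monotone transform of the per-position frequency
product yields identical rankings, and rankings are all the evaluations
consume; the log-odds form was chosen as the field's convention.  Inside
the pipeline the alignment offset is always 1 (the PFM and the records have
equal width); the offset scan and reverse-complement maximization exist for
scoring external sequences.  Ranking ties are always broken by sequence
lexicographic order for determinism.

## Evaluation metrics

Ψ between two width-w column-stochastic matrices is
(1/w) Σ_j Σ_i (a−b)²/(a+b), with 0/0 terms zero: zero iff identical,
symmetric, bounded by 2 per averaged column.  Unequal widths are handled by
scanning all ungapped offsets on both strands (reverse complement of a PFM
= reversed columns with A↔T, C↔G swapped), minimizing the
overlap-normalized Ψ; ties prefer the forward strand and the smallest
offset.  The per-column normalization and the absence of a factor ½ are
conventions of this implementation, isolated in one function; comparisons
against externally published Ψ values must confirm the same convention
before being read quantitatively.

AUC is the rank-sum statistic with average ranks on ties (0.5 per tied
positive–negative pair); top-k labeling breaks boundary ties
lexicographically.  A utility averages probe intensities over all probes
containing a k-mer or its reverse complement, the standard way to read
per-k-mer specificity out of probe-level binding data; retrieval of any
external array data is out of scope.

## Synthetic fixtures

The fixture generator emulates exactly the structural features the pipeline
consumes.  Idealized B-DNA: planar bases built from regular rings (1.39 Å
aromatic bonds, carbonyl 1.23 Å, exocyclic amine 1.34 Å, methyl 1.50 Å,
glycosidic 1.47 Å), Watson–Crick partners placed along the purine's N1
hydrogen-bond direction at exactly 2.9 Å, pairs stacked with rise 3.38 Å
and twist 36° and a pseudo-dyad flip when the strand-A base is a
pyrimidine.  Chains are labeled B and C, numbered 5′→3′ on each strand.
Protein probes are single residues from a small geometry library placed
radially outward so a named atom sits at an exact distance (bisection to
machine precision) from a chosen base pair or base atom, with a 1.5 Å
steric floor.  Training sets draw random sequences and probe placements
from a seeded generator and can plant an enrichment of one
(protein-atom, base-atom) pair at short range.

What passing on fixtures does **not** show: tolerance to real crystal
noise (sugar pucker, propeller twist, modified bases, partial occupancy),
the realism of any trained potential (fixture probes are not folded
proteins, and a potential trained on them is a test instrument, not a
transferable force field), or the field-scale accuracy of the published
evaluations, which require external structure and motif databases.
Fixture-trained potentials are used to verify mechanics — normalization,
oracle equivalence, signal recovery — not biology.

## Problem sizes in tests

The shipped tests and the acceptance script run at deliberately small
scale: 20 training complexes of 8 bp with ~3–11 probes each, 6-mer target
sites, mutation loads ≤ 2, and 200–1000 Monte-Carlo trials for the AUC
oracle.  These sizes make every check exact or statistically comfortable
while keeping the whole suite in seconds; all of them are parameters, and
the same code paths run unchanged at larger scale.

## Known limitations

- Rigid backbone and rigid base templates; no sugar or backbone relaxation.
- The pairing rule misses non-Watson–Crick and distorted pairs.
- The Ψ and Score_PFM functional forms are this package's documented
  conventions; cross-tool numerical comparisons need convention checks.
- mmCIF, RNA duplexes, protonation and symmetry expansion are unsupported.
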
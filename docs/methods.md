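# Methods

This note documents the models, parameter choices and numerical
conventions behind `pepdock`, and what its synthetic benchmarks do and
do not demonstrate.

## Contact model

A protein–peptide residue pair is *in contact* when its minimum
heavy-atom distance is within a class-dependent cutoff:

| pair type | condition | cutoff |
|---|---|---|
| hydrophobic | both residues in {A,V,L,I,M,F,W,P} | 5.0 Å |
| ionic | one of {D,E} with one of {K,R,H} | 6.0 Å |
| generic | anything else | 4.5 Å |

Cutoffs are inclusive (≤) and classes are mutually exclusive with
priority hydrophobic > ionic > generic. The hydrophobic/ionic rule is
the PepBind convention; the class memberships are the conventional
assignments (His is counted as basic because it is protonatable at
interface pKa values, and "ionic" means opposite charges — a salt
bridge). The generic class is this package's addition so that polar
contacts can seed interaction pairs and restraints; all three cutoffs
are configurable (`ContactConfig`). Hydrogens are stripped at parse
time, so "heavy atom" is simply "atom" internally.

## Structure alignment and TM-score

`tm_score` implements the length-normalized score
`TM = (1/L_norm) Σ 1/(1+(d_i/d0)²)` with
`d0 = 1.24 (L_norm−15)^{1/3} − 1.8`, floored at 0.5 Å (the floor is the
standard guard and is what the formula requires for L_norm ≤ 21). The
score is maximized over superpositions by fragment-seeded iterative
subset re-superposition. `align_structures` obtains the sequential
residue correspondence by the usual iterative scheme: seed pairings
(gapless diagonals plus a full-length stretch seed) → superpose →
distance-matrix dynamic programming with score `1/(1+(d²/d0²))` and zero
gap penalty → re-superpose, until the pair set stabilizes; the final
correspondence is polished with the full fragment-seeded TM-score
search. Inside the iteration a cheaper single-seed TM refinement is
used for speed. The DP recurrence is JIT-compiled when numba is
available, with a pure-Python fallback.

TM-scores are normalized by the **target** (query) length: templates are
ranked for a fixed target, so a common normalization makes the database
Z-score meaningful. Alignment is CA-only; full-atom superposition
happens in model building. Bit-compatibility with the original TM-align
program is not a goal (and not required anywhere).

## Template scoring

`S_complex = Z_TM + Z_Inter`, with Z-scores taken over the whole
searched database for the given target (population standard deviation,
n denominator; an all-equal score vector maps to all zeros). A
single-entry database has no meaningful Z-scores; ranking then falls
back to raw TM-score plus per-contact-normalized S_Inter, with a log
warning.

Peptide alignment is gapless with minimum overlap `min(3, shorter
length)` — one- and two-residue overlaps are spurious unless a sequence
is that short. Positive BLOSUM62 entries at template position j are
weighted by `1 + (number of hydrophobic or ionic protein residues in
hydrophobic/ionic contact with j)`; negative entries pass through
unweighted, so dissimilar residues are penalized identically everywhere
while hot-spot matches are rewarded more. Ties between offsets go to the
smallest offset. Target overhangs beyond both template termini are
permitted as long as the overlap requirement is met.

S_Inter sums `S_{i−j} = max[B(i,i′)+B(j,j′), B(i,j′)+B(j,i′)]` over
template contact pairs whose residues are both mapped by the structure
and peptide alignments; unmapped pairs contribute zero and are counted
as skipped. The raw (unnormalized) sum is used for ranking; a
per-contact normalized variant is stored for the accuracy model, where
an unbounded feature would be ill-posed. Selection keeps up to 10
templates with `S_complex > 0.9 × max`; when the maximum is non-positive
the rule is ill-defined and only the top entry is kept.

## Model building and refinement

Models keep the target receptor fixed in its input frame. The template
peptide is carried over by the alignment transform; aligned positions
copy the template backbone (N, CA, C, O) with the side chain mutated to
the target residue — CB placed at ideal tetrahedral geometry, atoms
beyond CB omitted (contacts and restraints anchor at CB, so the missing
atoms affect neither scoring nor evaluation of backbone-level quality).
Terminal overhangs are grown with ideal covalent geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å) in extended conformation
(φ = −120°, ψ = 120°).

One distance restraint is derived per mapped template contact with
`S_{i−j} > 0`: anchors are CB (CA for glycine), the target distance is
the template's anchor–anchor distance, the well is flat-bottomed with
half-width 1.0 Å, and the weight is `S_{i−j} · w0` (w0 default 1).
This weight law preserves the intended monotonicity — interaction pairs
more similar to the template are held more strongly — while pairs with
non-positive similarity are left entirely to the physics term.

The refinement energy is a deliberate simplification of a full
molecular-mechanics treatment: a soft-sphere clash term
`k (d_min − d)²` for heavy-atom pairs closer than d_min = 2.8 Å
(protein–peptide pairs, and peptide–peptide pairs at least 4 bonds
apart — 1-4 pairs such as O(i)–CA(i+1) sit at 2.7 Å by rigid trans-
peptide geometry and are excluded, as force fields conventionally do)
plus the restraint term. Minimization is seeded stochastic descent over
peptide rigid-body moves and per-residue φ/ψ rotations
(accept-if-lower, cooling step sizes, several starts including the
unperturbed pose), so the returned energy never exceeds the input
energy and runs are exactly reproducible per seed. The receptor is held
fixed. The energy evaluator is isolated behind a small interface so a
richer force field could replace it without touching build or ranking
code.

Builds are distributed as `n_build_total / n_templates` (≥ n_build_min)
per selected template from counter-based seed streams
(`SeedSequence([master, template_index, build_index])`), so adding a
template never perturbs the streams of existing ones. The best-energy
model per template is kept and remaining slots up to 10 are filled with
the next-best builds.

## Evaluation

fnat compares residue-contact sets (class-blind, under this package's
contact definition, for internal consistency) between model and native;
ligand-RMSD superposes receptor backbones and measures the peptide
backbone deviation without refitting; interface-RMSD fits the backbone
atoms of native interface residues (any heavy atom within 10 Å of the
partner). CAPRI tiers use the standard published protein–protein
thresholds (high: fnat ≥ 0.8 and l-RMSD ≤ 1.0 or i-RMSD ≤ 0.5; medium:
0.5/2.0/1.0; acceptable: 0.2/5.0/2.0); peptide-specific variants exist
and the thresholds are configurable.

The accuracy estimator is ordinary least squares of observed
binding-site recovery on (TM-score, normalized S_Inter), clamped to
[0, 1]; predictions below 0.2 raise a low-accuracy flag suggesting ab
initio docking instead. The shipped default coefficients are fitted on
an all-against-all cross-docking benchmark of nine generated fixtures
(81 rows) and are synthetic — refit against any real template database
before trusting the estimate.

## Synthetic fixtures

`generate_fixture` builds complexes with an exactly known contact map: a
scaffold (two antiparallel helices, a three-strand sheet, or a seeded
random coil for decoys) kept at least 7 Å from the peptide, plus one
pocket residue per requested contact placed along the direction of the
corresponding peptide side chain at a class-calibrated minimum distance
(hydrophobic 4.7 Å, ionic 5.5 Å, generic 4.2 Å, solved to 1e-9 Å by
bracketed root finding). Contacts sit three peptide positions apart and
non-contact positions use neutral residues, which keeps every
non-engineered pair outside all cutoffs; construction verifies the
realized contact map and fails loudly otherwise.

These fixtures emulate the *contact geometry* of real complexes — not
their packing density, side-chain detail, sequence statistics or
conformational heterogeneity. Green synthetic benchmarks therefore
demonstrate the correctness of the scoring, building and evaluation
machinery (and exact self-consistency of the pipeline), not docking
accuracy on real proteins, which additionally depends on template
coverage and an energy model far richer than the clash+restraint
stand-in used here.

## Problem sizes and numerical conventions

The shipped benchmarks use receptors of ~30–40 residues, peptides of 12,
databases of 20 templates, 10 refinement seeds and 200-row regression
recoveries; these sizes exercise every code path while keeping the full
suite and the acceptance script each around a minute on one CPU. The
pipeline itself accepts queries up to 900 protein / 30 peptide residues
(the conventional server limits, overridable with `--force`).

Other conventions: alternate locations resolve to the highest-occupancy
conformer (file order breaks ties, so altloc 'A' wins in conventionally
ordered files); only the first MODEL of a multi-model file is read;
nonstandard residues with a standard parent (MSE → MET etc.) are mapped,
others dropped with a warning; residue identity is (chain, author
number, insertion code); Kabsch superposition always returns a proper
rotation (det +1); template-ranking ties break by raw TM-score, then
lexicographic id; database archives round coordinates to 10⁻³ Å and
serialize with sorted keys so rebuilds are byte-identical.

## Known limitations

* The receptor is rigid throughout refinement; real induced fit (and
  the conformational change the similarity-based strategy can capture
  through templates) is only represented as far as the template provides
  it.
* Side chains beyond CB are not built or packed.
* The clash+restraint energy cannot rank subtle alternatives the way a
  molecular-mechanics function can; energies are comparable only within
  a run.
* Sequential (order-preserving) structure alignment only; receptors
  whose chain order differs topologically from the template will align
  poorly.
* No redundancy clustering or automatic retrieval for the template
  database.
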
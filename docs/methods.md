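# Methods

This note records the models, conventions and numerical choices behind
`pepgram`, and what the test suite does and does not establish.

## Units, angles and ensembles

A peptide X₁…Xₙ carries n − 1 φ-ψ units; unit *i* belongs to residue
*i + 1* (residue 1 has no φ). Labels are the lower-cased sequence plus the
1-based unit index (`gfgg2`). All angles are degrees canonicalized to
(−180, 180], with −180 mapped to +180 so each angle has one
representative. Angular distance is the shortest arc, in [0, 180].

Energies are consumed as relative kcal/mol; files carrying absolute
energies are shifted on read so the ensemble minimum is 0. The working set
everywhere is the *low-energy* view: conformers within `energy_window`
(default 10 kcal/mol) of the minimum. No unit conversions (e.g. from
hartree) are performed; upstream quantum chemistry is out of scope.

## Word classification

The similarity of two units is the out-of-bag misclassification rate of a
random forest (500 trees by default) trained to separate their (φ, ψ)
samples, after down-sampling the larger sample to balance the classes.
For balanced two-class OOB error the chance level is 0.5: identical
distributions score ≈ 0.5, disjoint ones ≈ 0. Features are
(sin φ, cos φ, sin ψ, cos ψ) so the 360° periodicity is respected; raw
degrees are available behind `feature_encoding="degrees"`. Each pair's
forest and down-sampling seed derive from the *unordered* label pair, so
the matrix is exactly symmetric and invariant to input order.

The published error-rate table that ships with the package reports values
to one decimal and contains entries up to 0.7 — above the 0.5 chance level
of this estimator. The published estimator is not described; this package
documents its own (balanced OOB) and does not attempt to match individual
published cells.

### MDS and the eigenvalue spectrum

Error rates are mapped to dissimilarities by d = 1 − e (zero diagonal);
the transform is a pluggable parameter because the published analysis does
not state one. Classical (Torgerson) scaling — double-center −d²/2,
eigendecompose, scale eigenvectors by √λ — gives the embedding;
eigenvalues are reported normalized by the largest. sklearn's MDS is the
SMACOF stress optimizer, not this closed-form procedure, so the
double-centering is implemented here directly (and cross-checked in tests
against exact recovery of planted Euclidean configurations).

Under d = 1 − e the packaged table yields the spectrum
1, 0.568, 0.355, 0.232, 0.196 against the published
1, 0.54, 0.26, 0.22, 0.16. The first, second, fourth and fifth agree
within 0.05; the third does not (0.355 vs 0.26). We examined other
monotone transforms (√(1 − e); |c − e| for c = 0.5, 0.7, 1.0; centered
similarity variants): none reproduces all five published values, and the
default is kept. The physically load-bearing feature — two dominant
eigenvalues justifying a 2D map — is reproduced under every transform
examined.

### Clustering

Unit classes are average-linkage agglomerative clusters of the 2D
embedding; when the class count is not given it is chosen by maximum mean
silhouette over k ∈ {2..6}. On the packaged table the silhouette narrowly
prefers k = 4 (0.750) over k = 3 (0.741). At k = 3 the partition
reproduces the published classes A/B/C exactly; at k = 4 class A is still
recovered intact and class B splits into its tripeptide-unit-1 and
tetrapeptide-unit-2 halves. We deliberately did not add a parsimony
tie-break to force k = 3: the selection rule is stated once and applied
as-is, and the k = 3 structure is available by passing `k=3` (or
`n_classes=3` on the estimator).

## Grammar learning

For adjacent units (i, i+1) of one ensemble, the distinct observed unit-i
values are crossed with the distinct unit-j values; a combination is
favorable iff all four angles lie within 3° (circular, per angle) of some
observed low-energy conformer of the same ensemble. The 3° rule is
per-angle rather than a joint norm — "noise of 3°" most naturally bounds
each dihedral — and is configurable (`noise_deg`). Every observed
conformer matches itself, so its own combination always labels 1.

The classifier is a 500-tree random forest on sin/cos-encoded angles with
`class_weight="balanced"`: combinatorial negatives vastly outnumber
positives and weighting preserves all data rather than subsampling.
Datasets are split 60/40 by default, stratified by label; a stability
check re-trains across several fractions and reports whether all error
rates stay below a threshold (2% by default). Screening a spliced trial
is a single prediction on its junction combination and is deterministic
given a trained model. Models should be trained on ensembles whose
junction context matches the target's; the API takes an explicit training
set rather than guessing.

## Divide-and-conquer search

Minimal fragment lengths for an n-residue target: n₁ = ⌊(n−1)/2⌋ + 2,
n₂ = ⌊n/2⌋ + 1 (n ≥ 3). The N-fragment supplies target units 1..n₁−2;
C-fragment unit k supplies target unit k + (n − n₂), covering n₁−1..n−1.
The two fragments overlap at the junction residue; the C-fragment's value
for unit n₁−1 is authoritative and the N-fragment's is discarded, making
the coverage a gap-free partition (property-tested for all valid plans up
to n = 12). Exactly one junction pair, (n₁−2, n₁−1), is screened per
splice; multi-way division is out of scope. Trials are ordered
lexicographically by parent conformer ids for determinism, and an optional
deduplication drops trials within a per-angle tolerance of an earlier one
(greedy first-keeper).

Fragment substitution returns a candidate ensemble each of whose units is
class-equivalent to the requested fragment's corresponding unit; the
result is relabelled with the target's residues (side chains follow the
target) and the substitution is recorded in the ensemble's metadata.

## Backbone geometry

Cartesian backbones are rebuilt from unit strings by sequential
natural-extension-reference-frame (NeRF) placement with fixed ideal
internal coordinates: N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å; angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; all
peptide bonds trans (ω = 180° exactly). ψ of residue 1 is pure gauge for
the unit string and is fixed at 180°. Cβ atoms are placed tetrahedrally
for non-glycine residues. Termini are neutral: the C-terminus carries O
and OXT, and the last residue's ψ is defined through OXT (for external
files lacking OXT, the carbonyl O is used with a 180° shift). Dihedrals
are computed in float64 with the standard atan2 form (32-bit intermediates
were observed to cost ~10⁻⁶ degrees, the round-trip tolerance itself);
build→extract and extract→build round-trip to < 10⁻⁶ °. Built structures
are starting points for external optimization, not final geometries: no
hydrogens, single chain A, residues numbered from 1, cis peptide bonds and
χ angles unsupported.

File formats: multi-model PDB via Biopython, with per-model relative
energies on `REMARK 250 ENERGY` lines beside each MODEL record (a dialect
of this package; other readers ignore it); multi-frame XYZ with atom-name
labels and a `peptide=… energy=…` comment line; CSV with columns
`phi1,psi1,…,energy`. CSV carries no sequence, so the peptide is taken
from a `peptide=` argument or a sequence-shaped file name (`gfgg.csv`),
else defaults to poly-glycine.

## Density of states and cost accounting

Each conformer contributes φ(x) = (1/(α√π))·exp(−(x−E)²/α²) with
α = 0.24 kcal/mol; the default grid is 0–4 kcal/mol in 0.01 steps, padded
by 5α on each side so the curve integrates to the conformer count
(verified to ±10⁻³). Curve overlap is ∫min/∫max by trapezoid. Boltzmann
weighting is deliberately absent.

The built-in cost table stores the published trial-structure counts for
n = 3..10 (systematic, path-matrix, screened divide-and-conquer). The
published text quotes 4,069 trial structures for the four-residue case
while the table prints 4,096; the table value is carried. Geometric
extrapolation fits the ratio of the first two known points and reports
3 significant figures (known points are returned exactly); growth factors
are geometric means of successive ratios at 2 significant figures. The
screened-search counts for n ≥ 7 were published as estimates (+50
low-energy fragment conformers per residue) whose mapping to trial counts
is not specified; they are stored as data, not recomputed.

## Synthetic data

The generator emulates exactly the structure the pipeline detects: five
basins at αR(−63, −43), β(−120, 130), PPII(−75, 150), αL(57, 47),
γ(−85, 70), σ = 10° each, noise truncated at ±3σ so basins stay disjoint
and planted ground truth is unambiguous. Unit classes are planted through
per-unit basin-weight profiles; the combination rule through an allowed
set of adjacent basin pairs (chains draw continuations only from the
allowed set). Energies are a placeholder — minimum 0, the rest uniform in
(0, 10] — because no energetic claim is tested.

The grammar benchmark draws positives around allowed pair centres and
negatives around *disallowed* basin pairs whose centres are at least
2·3σ + margin (Chebyshev circular distance) from every allowed centre, so
`margin` is the true gap between the supports of the two labels. At
margin 30° the rule is learned to 0% held-out error across seeds and
split fractions; at the default problem size (500 + 500 combos, 500
trees) this comfortably reproduces the < 2% learnability level.

What passing these tests shows — and does not. Synthetic basins are
isotropic, disjoint and noise-truncated; real φ-ψ distributions are
skewed, overlapping and residue-dependent, and real unfavorable
combinations need not be 30° from every favorable one. Recovery of
planted classes (ARI = 1 at σ = 10°, ≥ 200 conformers per unit) and
≥ 99%/99% junction accept/reject rates therefore validate the machinery,
not the chemistry. The published conformer and survivor counts depend on
the original quantum-chemistry ensembles and are not recomputable here;
the cost table carries them as data.

## Problem sizes and determinism

Default experiment sizes — 200 conformers per synthetic ensemble for word
recovery, 500 + 500 combos for grammar benchmarks, ≤ a few hundred trials
for exhaustive screening oracles — are the smallest at which the planted
structure is recovered cleanly and stably. All stochastic steps take
explicit integer seeds; per-pair forest seeds derive from label pairs so
results are independent of input order, and CLI runs write manifests
(seed, config, input digests) sufficient to reproduce outputs
byte-for-byte.
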
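# pepgram

Words-and-grammar analysis of peptide backbone dihedrals, and a
machine-learning-assisted "divide and conquer" conformer search built on it.

## The problem

Finding the low-energy conformations of a peptide is a search over a
high-dimensional torus of backbone dihedrals. Systematic rotor enumeration
is reliable but its cost grows geometrically with chain length (roughly
×12 per added residue), so it dies at four or five residues. Fragment
splicing ("divide and conquer") keeps the search tractable — combine the
low-energy conformers of two overlapping fragments into trial structures of
the target — but naively it needs the exact fragments' ensembles and joins
them combinatorially.

`pepgram` implements the two statistical ideas that fix both problems:

* **Words.** The (φ, ψ) pair of residue *i+1* in peptide X₁…Xₙ is *unit i*
  (written `gfgg2` for unit 2 of GFGG). Two units are compared by the
  out-of-bag error of a random forest trained to tell their (φ, ψ) samples
  apart: error ≈ 0.5 means the distributions are indistinguishable, error
  ≈ 0 means they are disjoint. Classical (Torgerson) MDS of the pairwise
  error-rate matrix (dissimilarity d = 1 − e) embeds all units in 2D, and
  average-linkage clustering groups them into equivalence classes. A
  fragment whose ensemble you don't have can then be *substituted* by a
  class-equivalent peptide's ensemble, with the side chains relabelled.
* **Grammar.** Within one low-energy ensemble, observed unit-*i* and
  unit-*i+1* values are recombined combinatorially; a four-angle
  combination is *favorable* iff it matches some observed conformer within
  3° per angle. A random forest trained on these labels is the combination
  rule. Spliced trial structures are screened at the single junction pair
  (n₁−2, n₁−1), discarding combinations the grammar rejects before any
  expensive geometry optimization.

Fragment lengths default to n₁ = ⌊(n−1)/2⌋ + 2 and n₂ = ⌊n/2⌋ + 1; target
units 1..n₁−2 come from the N-side fragment and n₁−1..n−1 from the C-side
fragment (whose value is authoritative at the shared junction residue).
Supporting modules rebuild Cartesian backbones from dihedral strings (NeRF
with ideal geometry), read/write multi-model PDB / XYZ / CSV ensembles,
compute Gaussian-broadened density-of-states curves
φ(x) = (1/(α√π))·exp(−(x−E)²/α²) with α = 0.24 kcal/mol, and carry the
published trial-structure cost table with its geometric extrapolation.

A synthetic-data generator plants Ramachandran-basin mixtures,
class-dependent basin weights and restricted adjacent-basin combinations,
so the whole pipeline is testable without quantum-chemistry ensembles.

## Worked example

```python
>>> import pepgram as pg
>>> m = pg.load_table1_fixture()          # published 19x19 error-rate matrix
>>> emb = pg.mds_embed(m)                 # classical MDS of d = 1 - e
>>> [float(v) for v in emb.eigenvalues[:5].round(3)]
[1.0, 0.568, 0.355, 0.232, 0.196]
>>> classes = pg.cluster_units(emb, k=3)
>>> sorted(pg.equivalent_units(classes, "gtg1") + ["gtg1"])
['gfgg1', 'gtg1', 'gtgg1', 'gvg1', 'gvgg1']
```

The first two eigenvalues dominate the spectrum, which is what justifies a
2D map of the units; the k = 3 partition of that map groups `gtg1` with
`gvg1, gfgg1, gtgg1, gvgg1` — the units whose flanking residues are both
glycine — exactly the published class A.

```python
>>> combos = pg.make_grammar_benchmark(500, 500, margin=30, seed=1)
>>> train, hold = pg.split_dataset(combos, 0.6, seed=1)
>>> model = pg.train_grammar(train, hold)
>>> model.in_sample_error_, model.out_of_sample_error_
(0.0, 0.0)
```

On combinations separated by a 30° margin the grammar is essentially
perfectly learnable — both error rates sit far below the 2% level at which
screening is useful. An end-to-end search is then three calls:

```python
>>> plan = pg.make_splice_plan(5, 4, 4)   # GGGGG from two tetrapeptides
>>> trials = pg.generate_trials(ens_n, ens_c, plan)   # |N| x |C| trials
>>> survivors = pg.screen_trials(trials, model, plan) # junction (2, 3)
```

The same pipeline is scriptable via the `pepgram` console command
(`synth`, `words`, `grammar`, `search`, `dos`, `cost` subcommands, each
writing a reproducibility manifest).

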
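# Methods

## Model

The predictor scores every (protein, GO class) pair with a number in
[0, 1] built from two components.

*Similarity transfer* assumes functional conservation among homologs: the
score of class *f* for query *q* is the bitscore-weighted fraction of *q*'s
accepted hits (e-value ≤ 0.001 by default) that carry *f* in their
propagated annotation set. The normalization by the total bitscore makes
the score scale-invariant (multiplying every bitscore by a constant changes
nothing) and bounded by 1; because subject annotation sets are closed under
the true path rule before voting, the transferred scores are automatically
monotone along the hierarchy. Multiple HSPs for the same (query, subject)
pair are collapsed to the maximum bitscore — the vote needs a single weight
per subject. Self-hits (subject = query) are excluded by default during
evaluation to prevent label leakage when queries are part of the annotated
corpus; production use can keep them (`--include-self-hits`).

*The CNN* scores sequence directly. One-hot input over 21 symbols (20
standard residues plus an unknown bucket absorbing B, Z, J, U, O, X and
anything else), fixed length with truncation beyond `max_len` (default
2000) and zero padding below it. Parallel 1D convolution banks, kernel
sizes 8–128 in steps of 8 with 512 filters each at full scale; each filter
is globally max-pooled to a single "did this filter fire anywhere" value;
the pooled vectors are concatenated and mapped by one fully connected
sigmoid layer to per-class scores. Convolutions are linear by default —
the max-pool output is the filter-activity value, and a ReLU before the
pool is selectable (`conv_activation="relu"`) but not needed for the
motif-detection behaviour the architecture targets. The network never
predicts outside its vocabulary (classes annotated to at least `min_count`
training proteins, roots excluded); ancestors are filled in afterwards by
the consistency step.

Training-side choices are ours: per-class binary cross-entropy, Adam
(default learning rate 1e-3; the desk-scale benchmark uses 3e-3), an early
stopping split (10% validation, patience 8) with the best-epoch parameters
restored. The whole network is plain NumPy with a seeded generator, so
initialization, training and inference are bit-reproducible on a single
thread, and a saved checkpoint (weights + config + vocabulary) restores
predictions exactly.

*Ensemble:* `S = α·S_similarity + (1−α)·S_cnn` over the union of supports,
missing components contributing 0. α defaults to 0.5 — an uninformative
midpoint; the weighting is exposed per run because its optimum depends on
how well the training corpus covers the query's homologs.

*Consistency:* one reverse-topological pass per protein sets each class's
score to the maximum over itself and its descendants (relations `is_a` and
`part_of` by default; `part_of` is our extension of the subclass rule,
matching common GO propagation practice, and is configurable). The pass
fills unscored ancestors, is idempotent, and never decreases a score.

## Scoring conventions

A stored score of 0 means "not predicted". Thresholding keeps classes with
`score ≥ t` among positive scores; the strict `>` variant is a switch.
This makes the degenerate all-zero predictor yield Fmax = 0 rather than
predicting everything at t = 0, and matches the "minimum confidence"
semantics of the default reporting threshold 0.3. Ties in the report are
broken lexicographically by class identifier.

## Information content and evaluation

`IC(c) = −log₂ N(c)/N(P(c))` where `N(c)` counts corpus proteins carrying
*c* and `N(P(c))` counts proteins carrying *every* parent of *c* (corpus
size for roots). The estimator is maximum likelihood; classes never seen
(or with unseen parent combinations) fall back to the maximum observed IC,
logged. Bits (log base 2) by default, natural log selectable. IC(root) is
0 whenever the root covers the corpus.

The sweep uses exactly 101 thresholds (0.00–1.00, step 0.01). AvgPr
averages over the m(t) proteins with at least one prediction; AvgRc over
all n evaluated proteins; thresholds with m(t) = 0 contribute no F value.
Smin reports the smallest minimizer, Fmax the smallest maximizer, under
ties. Evaluation is restricted to one namespace at a time when a graph is
supplied; namespace roots are excluded by default (they are trivially
correct for every protein), and proteins whose truth set becomes empty
after restriction are dropped from n. AUPR integrates the protein-centric
(AvgRc, AvgPr) points by trapezoid over the observed recall range — it is
not padded to recall 0 or 1, so a sharply peaked score distribution yields
a small area even for an accurate predictor; a micro-averaged pairwise
curve is available (`curve="micro"`) since the community uses both.

## Synthetic benchmark

The generator emulates the structure the method exploits, not protein
biology. Ontology: a complete tree per namespace (default one namespace,
depth 2, branching 3 → 13 classes, 9 leaves), optional extra "diamond"
edges to a second, shallower parent. Each leaf owns a unique random
8-residue motif. Each protein (default 500) draws 1–2 leaf functions, a
background sequence of 100–200 residues with uniform residue frequencies,
and each owned motif is implanted at a random non-overlapping position
with probability 0.9 (`implant_prob`). Hits are simulated by counting
shared motif-length k-mers between sequences — two proteins sharing a leaf
share its motif — scaled by 60 per shared k-mer plus uniform noise in
[0, 3), floored at bitscore 30, with e-value `10^(−bitscore/10)` so the
floor sits exactly at the 1e-3 cutoff. Background 8-mer collisions are
vanishingly rare (≈ 20⁻⁸ per position pair), so unrelated pairs are absent
from the table.

Passing the recovery benchmark therefore shows that each route extracts
planted sequence–function signal and that the full pipeline (parsing,
propagation, transfer, training, ensembling, consistency, evaluation) is
wired correctly. It does not show performance on real proteomes: real
sequences carry domain architecture, phylogenetic correlation and severe
class imbalance that the generator deliberately omits, and the toy CNN
(kernels 8 and 12, 32 filters) is far below the full-scale architecture.

Benchmark problem sizes: 400 training / 100 held-out proteins,
vocabulary = classes with ≥ 5 training proteins, CNN trained up to 60
epochs with early stopping; permuted-label controls shuffle which training
protein carries which annotation set and rerun transfer and training
unchanged. The run completes in well under a minute on one CPU.

## Numerical and degenerate-input choices

- OBO parsing validates acyclicity (reporting the offending cycle) and
  rejects references to undefined or obsolete parents; `alt_id`s resolve
  silently with a log entry; obsolete classes in annotation input are
  dropped with a warning; unknown classes are errors naming protein and
  class.
- Multiple parentless classes in one namespace: the lexicographically
  smallest is the designated root (synthetic graphs; GO has unique roots).
- Hit parsing reports malformed rows with their line number and rejects
  non-positive bitscores.
- A query absent from the hit table gets an empty score map, not an error.
- Sigmoid outputs are clipped to [1e-9, 1−1e-9] so scores are strictly
  inside (0, 1) even when logits saturate in float64.
- The threshold grid is `arange(101)/100`, whose entries are exactly the
  binary doubles nearest each two-decimal value, so `score ≥ t`
  comparisons are stable across re-implementations.

## Known limitations

- The CNN is CPU-bound NumPy: fine at desk scale, not meant for
  Swiss-Prot-scale training.
- Only `is_a` and `part_of` are modelled; OBO intersections,
  cross-products and other relations are out of scope.
- The simulated hit model has no alignment statistics — e-values are a
  monotone transform of the pseudo-bitscore, sufficient to exercise the
  cutoff logic but not calibrated.
- AUPR depends on the curve convention (see above); compare like with
  like.
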
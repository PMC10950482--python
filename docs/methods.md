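# Methods

## Problem

Transformer classifiers for protein function prediction operate on amino
acid sequences, and the question this package operationalizes is whether
what the model *attends to* coincides with what biology already knows about
those sequences: per-residue feature annotations such as transmembrane
regions, active/binding sites, and short sequence motifs. The package
implements (i) integrated-gradients (IG) attribution at the embedding
layer, (ii) an extension of IG that attributes relevance to the individual
attention heads inside the encoder, and (iii) the population-level
statistics that decide, across many proteins, whether attribution maps and
annotations agree more than chance allows.

## Attribution model

For a scalar class score F (by default a logit; probabilities saturate and
starve the gradient) and a straight path gamma(a) = x' + a (x - x') from a
baseline embedding x' to the sample embedding x, the attribution of
embedding feature i is

    IG_i = Integral_0^1  dF/dgamma_i (gamma(a)) * dgamma_i/da  da .

The straight embedding path satisfies the usual IG axioms; completeness
(sum of attributions = F(x) - F(x')) is the quantitative handle used to
validate the discretization.

Head-specific attribution targets the output of a layer's multi-head
self-attention (MHSA) *before* the output projection. At that observation
point the feature axis is the concatenation of per-head outputs, so
contiguous blocks of width d_model/n_heads belong to single heads, and a
seq x d_model layer map reduces to a seq x n_heads map by block summation
(an exactly conservative operation). Targeting the post-projection output
instead would mix heads and make the reduction meaningless.

The path for a layer target is *not* re-anchored at the layer: the same
straight embedding path is pushed through the encoder and becomes a
curvilinear trajectory h(a) at the MHSA output. This keeps one consistent
path for all layers of a sample (the skip-connection input varies
consistently); the only axiom sacrificed is symmetry. The layer integral is
evaluated as a Riemann-Stieltjes sum: gradients of F with respect to the
MHSA output contracted with finite differences of h(a).

Numerical choices:

- **Quadrature.** Trapezoid rule over m = 64 steps by default (left-Riemann
  selectable). Gradients at consecutive alpha nodes are averaged and
  multiplied by the increment of the integrator variable (embedding delta,
  or Delta h for layers). On the trained toy model the relative
  completeness gap decays roughly as m^-2 (about 7e-4 at m=16, 1e-8 at
  m=4096), so m = 64 (gap ~ 4e-5) is ample for the statistics downstream.
- **Baseline.** Padding-token embedding at every residue position (zero
  embedding and custom baselines selectable). Special tokens keep their
  embeddings, so the path never moves them and they receive exactly zero
  embedding attribution; they are additionally excluded from all
  statistics, because annotations exist only for residues.
- **One sweep per protein.** All layers and the embedding map are computed
  from a single batched sweep over the alpha grid (one forward/backward per
  node yields the gradient at the embedding and at every MHSA output), so
  per-layer maps share identical grids and endpoints by construction.

## Statistics

Per protein and head, the per-residue relevance sequence is correlated with
the binary annotation vector with the point-biserial coefficient, which is
numerically the Pearson correlation of a continuous and a 0/1 variable.
Degenerate inputs (annotation all zero/one, constant relevance) are
recorded as missing, not zero. The per-protein coefficients fill an
n_layers x n_heads grid; across proteins each cell is tested with a
one-sided Wilcoxon signed-rank test (median > 0), all cells of one grid are
corrected together with Benjamini-Hochberg (for a ProtBert-scale 30 x 16
grid that is 480 tests per condition; for the toy 2 x 4, eight), the
corrected grid is thresholded at alpha = 0.05, and displayed as -log10 of
the surviving adjusted p-values.

In parallel, the same machinery is applied to sequence-summed head
relevances to ask which heads carry significantly positive relevance at
all. The final overlay keeps a cell's correlation signal only where the
relevance track is also significant — a head that matches annotations but
contributes nothing to the decision is not counted.

Choices a user may care about: zeros are discarded before ranking (Pratt
selectable); the exact signed-rank null is used up to n = 25 without ties,
the normal approximation with continuity correction otherwise; cells with
fewer than 5 contributing proteins stay missing; missing per-protein values
are excluded pairwise per cell. One-sidedness follows from the hypothesis
("significantly positive"), two-sided is available in `TestConfig`.

`HeadAnnotationAnalysis(...).fit()` wraps the whole procedure and returns a
results object with the grids, the joint mask, and a `summary()` table.

## Toy encoder

The attribution code sees models only through a small contract (geometry,
token encoding, batched forward with gradients at the embedding and at
every MHSA output). The bundled reference implementation is a BERT-style
post-layer-norm encoder: 2 layers x 4 heads x 64 dims, GELU feed-forward
(width 128), mean pooling over valid positions, softmax classifier,
trained from scratch with AdamW-style weight decay (0.01) and random
residue masking (p = 0.15) as augmentation. All gradients come from a
small reverse-mode autodiff engine on NumPy arrays written for this
package; its operator gradients are finite-difference-checked in the test
suite.

Two design points deserve explanation because the obvious defaults fail at
this scale (a few hundred training sequences rather than BERT's corpora):

- **Concatenated sinusoidal positions.** Positions occupy their own d/2
  subspace (fixed sinusoids, frequency band adapted to max_seq_len so no
  plane is constant over a sequence); token identity occupies the other
  half at unit scale. Additive low-scale embeddings left first-layer
  attention effectively uniform and untrainable.
- **Locality-biased attention initialization.** Sinusoids satisfy
  PE_{j+delta} = R_delta PE_j for a blockwise rotation R_delta, so each
  head's query/key projections are seeded with the rotation for a small
  relative offset (+-1, +-2, +-3 across heads, gain 2.0). At initialization
  heads therefore attend a few positions up- or downstream — the shift-
  invariant receptive fields needed to learn contiguous-motif detectors —
  while remaining fully trainable and containing no information about any
  class. Without this bias the model solves the task by global residue
  composition (~75-85% held-out accuracy) and memorizes the rest; with it,
  held-out accuracy is 0.95-1.00 across seeds.

Dropout exists in the configuration for completeness and is 0 at analysis
time; analysis forwards are deterministic bit-for-bit given a checkpoint.

A purpose-built degenerate model (single MHSA block, skip connection
severed, linear readout) accompanies the encoder: there the MHSA output is
provably the only path from embeddings to score, so layer-IG completeness
can be asserted against F(x) - F(x') (observed relative error ~1e-16 at
m = 256).

## Synthetic data

The generator emulates the real analysis setting — proteins with class labels
and per-residue annotations — with exact ground truth: each class is
defined by a 6-residue motif (pairwise Hamming distance >= half the
length), planted exactly once at a uniformly random position into an
i.i.d. background (uniform over the 20 residues by default; empirical
frequencies selectable). Backgrounds are rejection-sampled so no class
motif occurs by chance, and cross-class motif hits are excluded, so the
motif span *is* the correct annotation and fully determines the label.
Defaults: 2 classes, 100 sequences per class, lengths 50-100, stratified
50/50 train/test split with duplicate sequences forbidden.

What this emulates and what it does not: it gives the cleanest possible
version of "annotated residues carry the class signal". Real proteins have
correlated backgrounds (homology, composition bias), annotations that are
neither complete nor perfectly aligned with what a model uses, and signals
distributed beyond the annotated span. Passing the recovery tests
therefore shows the method chain is *sound* (it finds planted signal and
stays at the nominal false-positive level under permutation/rotation), not
that any particular real model is faithful.

The six-class variant mirrors a main-enzyme-class setting for clustering
experiments; classes use disjoint default motifs.

## Faithfulness

For each k in a schedule, the k top-relevance residues (or k random ones,
averaged over repetitions) are substituted and the class-probability drop
is recorded; curves are compared by normalized area under the drop curve,
paired across sequences with a one-sided Wilcoxon test. Replacements:
mask token (default), alanine, or draws from the sequence's own residue
composition ("shuffle" — the in-distribution way to delete a signal).

One empirical caveat worth knowing: off the data manifold the toy model's
softmax is uncalibrated — on sequences that carry *no* class signal at all
(pure backgrounds, or test sequences with the whole motif deleted) it
still emits extreme probabilities, arbitrary per sequence rather than 0.5.
Signal removal therefore shows up as classification accuracy collapsing
toward chance (about 0.97 intact vs ~0.6 after motif deletion, while
deleting as many background residues leaves accuracy intact), not as
probabilities dipping below one half; the motif-deletion check asserts the
accuracy form.

## Clustering

Per-protein summed attribution maps (n_layers x n_heads, special tokens
excluded) are flattened row-major — at this point no reference to sequence
positions survives, only the relevance distribution over heads — reduced
by PCA to 50 dimensions (capped at what n and the feature count support,
with a warning), then embedded in 2-D by t-SNE with pinned "defaults"
(perplexity 30, capped below the sample count; learning rate "auto"; PCA
initialization; seeded). Class structure is quantified by the silhouette
score of the class labels in the 2-D plane (the quantity the scatter plot
shows); the silhouette in the 50-D PCA space is also available. The
silhouette is this package's operationalization of "distinct clusters" —
scatter plots alone cannot be asserted in a test.

## Problem sizes used by tests and the acceptance script

The default study conditions (2 x 4 x 64 encoder, 200 sequences, 50/50
split) are used throughout: the trained fixture is shared across checks,
attribution uses m = 64 over the 100 test proteins, the completeness sweep
uses m up to 4096 on one protein, faithfulness uses 60 sequences with
k in {1, 2, 4, 6, 8, 10} and 10 random repetitions, permutation controls
use 50 draws, rotation controls 10 seeds.

## Known limitations

- The toy encoder is a stand-in at desk scale; nothing here loads
  pretrained protein language models, though any model implementing the
  contract can be attributed.
- The curvilinear layer path violates the symmetry axiom (by
  construction); the package reports no diagnostic for the size of that
  violation.
- Attribution to query/key/value matrices, attention-weight analyses
  (rollout/flow), and ontology expansion of annotation tables are out of
  scope; annotation tables are taken as given.
- Layer-level completeness holds only for the severed-skip construction;
  in a full encoder the skip path carries part of F(x) - F(x'), so layer
  maps are interpreted relatively (head vs head), not absolutely.
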
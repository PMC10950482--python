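# headig — head-wise integrated gradients for protein transformers

`headig` asks a concrete interpretability question about transformer
classifiers of amino-acid sequences: **do the residues the model relies on
coincide with annotated sequence features** (transmembrane regions,
active/binding sites, short motifs)? It answers it quantitatively, across
whole test cohorts rather than hand-picked examples, and not only at the
input but *inside* the model, head by head and layer by layer.

## What it computes

1. **Embedding-level integrated gradients.** For a class score `F` and a
   straight path from a baseline embedding `x'` to the sample `x`,

   `IG_i = ∫₀¹ ∂F(γ(α))/∂γ_i · dγ_i/dα dα`,

   discretized with a trapezoid rule; the completeness identity
   `Σᵢ IG_i = F(x) − F(x')` is tracked as the numerical quality control.

2. **Head-specific attribution.** The same embedding-anchored path is
   pushed through the encoder and IG is evaluated at a layer's multi-head
   self-attention output *before* the output projection, where the feature
   axis is the concatenation of per-head outputs. Summing blocks of width
   `d_model/n_heads` turns a `seq × d_model` layer map into a
   `seq × n_heads` map — one relevance sequence per head — exactly
   conserving totals.

3. **Population statistics.** Per protein and head, the point-biserial
   correlation `r` between per-residue relevance and the binary annotation
   track; per `(layer, head)` cell, a one-sided Wilcoxon signed-rank test
   across proteins; Benjamini–Hochberg FDR over the whole grid (a
   30-layer × 16-head encoder means 480 tests per condition); and an
   overlay that keeps annotation-correlated heads only if their total
   relevance is also significantly positive.

4. **Validation instruments.** A planted-motif sequence generator with
   exact per-residue ground truth, a trainable desk-scale transformer
   (2 × 4 × 64) implementing the model contract, a residue-substitution
   faithfulness test, and PCA + t-SNE clustering of sequence-summed
   attribution maps with silhouette scoring.

Everything runs on NumPy (gradients come from a small reverse-mode
autodiff engine inside the package); SciPy/statsmodels/scikit-learn handle
the statistics and embeddings, Biopython the FASTA IO.

## Worked example

```python
import numpy as np
from headig import (make_headwise_fixture, attribute_all, PathSpec,
                    ClassScoreFn, correlate_protein, summed_relevance,
                    point_biserial, HeadAnnotationAnalysis)

fx = make_headwise_fixture(seed=0)          # generate data + train encoder
print(fx.diagnostic)
ds, model = fx.dataset, fx.model

corr, summed, rs = [], [], []
by_id = {r.id: r for r in ds.records}
for pid in ds.test_ids:
    bundle = attribute_all(model, by_id[pid].residues,
                           ClassScoreFn(ds.labels[pid], "logit"),
                           PathSpec(steps=64), sequence_id=pid)
    ann = ds.track_of(pid).to_binary()
    rs.append(point_biserial(bundle.embedding_map.residue_relevance, ann))
    corr.append(correlate_protein(bundle.head_maps, ann))
    summed.append(summed_relevance(bundle.head_maps))

print("embedding-level median r:", np.median(rs))
print(HeadAnnotationAnalysis(corr, summed).fit().summary())
```

Output (abridged):

```
test accuracy 0.970 (floor 0.95); valid fixture
embedding-level median r: 0.4426
Head-annotation agreement analysis
==============================================
grid: 2 layers x 4 heads = 8 hypothesis tests per track
proteins: 100
alpha (BH-FDR): 0.05; sidedness: greater

significant correlation cells: 6
significant positive-relevance cells: 5
jointly significant cells: 3

layer  head  median_r  p_adj(corr)  p_adj(rel)  joint
    0     0     0.309     1.53e-16    7.07e-05  *
    0     3     0.248     3.67e-17    0.000163  *
    1     0     0.154     1.53e-16    0.000399  *
    ...
```

Reading it: the planted motif is recovered at the embedding level (median
`r` 0.44 across 100 held-out proteins), and three specific heads both
track the annotated residues and carry significantly positive relevance —
the toy-scale analogue of identifying specialized transformer heads for an
annotation type. Rotating or permuting the annotations drives all of this
to the nominal false-positive level (see `tests/test_acceptance.py`).

## Command line

`headig synth | train-toy | attribute | stats | cluster-maps | faithfulness
| run-all` — each a thin wrapper over the library; `run-all` executes the
whole workflow (attribute → correlate → aggregate → overlay → cluster →
report) from one YAML config and writes TSVs, figures, and a plain-text
summary. See `headig --help`.

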
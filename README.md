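# celltra

Contrastive cell-name / gene-expression alignment with a pathway-informed
transformer, for supervised and **zero-shot** cell-type annotation of
scRNA-seq data, including entropy-based detection of cell types never seen
in training.

## Who this is for

Annotating single-cell RNA-seq data usually requires either curated marker
genes or a classifier trained on every type it will ever meet. Neither
scales to new or rare cell states. This package treats the *name* of a cell
type as natural language: a text encoder embeds free-text names, an
expression encoder embeds cells, and contrastive training pulls matching
(cell, name) pairs together in a shared space. A cell of a type absent from
training can then be labeled by its similarity to that type's *name*
embedding — zero-shot transfer through the compositional structure of
biomedical nomenclature.

## The model

**Gene-set super tokens.** A transcriptome of *n* genes is too long a
sequence for self-attention. Genes are therefore grouped into *M* gene
sets: each pathway (read from a GMT file) forms one set, and the genes
without pathway membership are chunked, after a seeded shuffle, into random
sets of fixed size (110 by default, so e.g. 14,426 orphan genes form 132
sets). The token embedding of gene set *i* for a cell with expression *x*
is the expression-weighted average over the **full** set,

```
Z_i = (1/n_gene) * sum_{j in set i} x_j * G_j
```

where `G_j ∈ R^D` is a learnable per-gene embedding and zero-expression
genes still count in the denominator. A learnable CLS token is prepended
and the sequence runs through a standard transformer encoder with **no
positional encoding** (gene-set order is biologically meaningless); the CLS
output is the cell embedding. Default production geometry: D = 768, 12
layers, 12 heads, 3072-dim feed-forward. A linear head on the CLS output
covers supervised classification.

**Contrastive alignment.** Cell embeddings `C_i = E_c(c_i)` and name
embeddings `T_i = E_t(t_i)` are linearly projected into a shared space
(512-dim by default). A batch of K cells with pairwise-distinct names forms
a K x K cosine-similarity matrix; the loss is the symmetric softmax
cross-entropy with the matching pairs on the diagonal (rows: each cell
classifies its name; columns: each name classifies its cell). The built-in
text encoder is a trainable bag-of-words model (lowercase, alphanumeric
split, mean-pooled token embeddings); a pretrained language model can be
plugged in through `AdapterTextEncoder` without any bundled weights.

**Inference and unseen-type detection.** Every candidate name (seen or
unseen) is embedded once; each cell takes the argmax-similarity name. The
softmax over candidates, restricted to *seen* candidates and renormalized,
gives a per-cell Shannon entropy (nats): cells of unseen types spread their
mass and score high. Cells above a threshold — by default the median
(second quartile) of the test set's entropies — are reassigned to the most
similar *unseen* candidate.

**Evaluation and clustering augmentation.** Micro-F1 and support-weighted
macro-F1 are reported separately on cells whose true type is seen versus
unseen, combined by harmonic mean ("mixed"); an entropy-sorted 100-bin
curve shows how the seen-cell proportion falls with entropy. Softmax
probability vectors can be concatenated to expression features to improve
unsupervised clustering (k-means, Leiden) of unannotated data, with
accuracy scored by the optimal one-to-one cluster/type assignment.

## Worked example

Everything is testable without downloads through the synthetic generator:
ten compositionally named cell types ("alpha helper cell", "beta memory
cell", ...) whose signatures are fold-elevated expression in the pathways
matching their name tokens, negative-binomial counts with dropout and
library-size noise. Two types are held out of training entirely; their
names recombine seen words, so zero-shot transfer is genuinely learnable.

```bash
python examples/04_zero_shot_annotation.py
```

prints (seed 0):

```
contrastive loss: 2.301 (start, ~ln K) -> 0.0015 (final)
test cells: 540; entropy threshold (median): 0.2458
seen-type micro-F1   : 0.933
unseen-type micro-F1 : 0.897 (chance over 10 candidates = 0.100)
mixed macro-F1       : 0.948
mean seen-entropy: seen cells 0.040, unseen cells 0.720 — ...
```

The loss starts at ln K (uniform similarities) and collapses as the two
spaces align. The two held-out types are recovered at 0.897 micro-F1
against a 0.100 chance level, and their ninefold-higher mean entropy is
what the median-threshold OOD detector exploits. The other examples cover
preprocessing (`01`), tokenization (`02`), the pathway-versus-random
grouping ablation (`03`, supervised accuracy 0.958 vs 0.842 at seed 0) and
prediction-augmented clustering (`05`, k-means accuracy 0.531 → 0.881 at
seed 0).

A thin CLI mirrors the library: `celltra synth | preprocess | train |
predict | evaluate | cluster` (see `--help` on each).

## Layout

- `src/celltra/` — library (`io_formats`, `preprocessing`, `tokenizer`,
  `expression_encoder`, `text_encoder`, `contrastive`, `inference_ood`,
  `evaluation`, `cluster_augment`, `synthetic_data`, `experiments`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, generator and design notes
- `tests/` — pytest suite
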
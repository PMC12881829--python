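# Methods

## Model

### Tokenization

The gene vocabulary is partitioned-with-overlap into gene sets. Each
pathway from the GMT file, intersected with the vocabulary, becomes one
token (pathways with no measured gene are dropped); a gene belonging to
several pathways contributes to each of their tokens. Genes in no pathway
are shuffled with the grouping seed and cut into consecutive blocks of
`orphan_set_size` (default 110); the final block may be short — with
14,426 orphan genes this yields 132 random sets, the only reading
consistent with fixed-size chunks. Group order (pathway-file order, then
random blocks) is fixed for reproducibility but carries no meaning: the
encoder is order-invariant. A grouping serializes to JSON so a trained
model ships with its exact tokenization.

### Expression encoder

Token *i* of a cell with expression profile `x` (normalized-log) is
`Z_i = (1/n_gene) Σ_j x_j G_j`, averaging over the **full** group size:
zero-expression genes participate as zeros rather than being excluded, so
token magnitude encodes how active the set is, not just the mean of its
detected members. The linearity `Z(αx) = αZ(x)` is tested. A learnable CLS
embedding (shared across cells) is prepended and the sequence passes
through a post-norm transformer encoder (GELU feed-forward, standard
scaled dot-product attention) with **no positional encoding**; permutation
invariance of the CLS output under token shuffles is asserted numerically
to 1e-5. All M+1 tokens are always valid — tokenization is
vocabulary-level, so no padding mask exists and batched cells share the
grouping.

Production geometry is 768 dims / 12 layers / 12 heads / 3072 FFN /
512-dim shared space, learning rates 5e-5 (supervised) and 1e-5
(contrastive), batch 32. The desk-scale configuration used by the tests
and examples is 32 dims / 2 layers / 4 heads / 64 FFN / 32-dim shared
space, batch 8, learning rate 3e-3 with cosine decay to 10%, 1600 steps,
temperature 0.1. The decay is a desk-scale stabilizer: without it Adam
oscillates late in training at this learning rate and some seeds plateau
an order of magnitude above the reachable loss. The production default
remains constant-rate, matching the stated training recipe.

### Text encoder

The built-in encoder lowercases, splits on non-alphanumerics, embeds each
word from a trainable table (out-of-vocabulary words share one UNK vector)
and mean-pools. Mean pooling makes name embeddings compositional by
construction — an unseen name made of seen words lands at the centroid of
learned word vectors — which is the desk-scale stand-in for the semantic
space of a pretrained biomedical language model. External models enter
through an adapter (a callable `names -> (n, dim)` array, dimension
checked); adapters are frozen and alignment happens in the projection, so
the package never requires downloaded weights. Whether to freeze the
built-in encoder is a flag (default trainable).

### Contrastive objective

Both modalities are linearly projected into the shared space (both-sided
projection; a config flag collapses the expression side to identity when
dimensions agree). Embeddings are L2-normalized inside the similarity
computation only. For a batch of K cells with pairwise-distinct names
(sampled names-first, uniformly without replacement, then one cell per
name), the loss is the mean of row-wise and column-wise softmax
cross-entropy on `sim/τ` with diagonal targets. Identities used as
oracles: uniform similarities give ln K; K = 1 gives 0; the loss is
invariant to a common rotation of both spaces and non-increasing in any
diagonal entry. Temperature τ is configurable (production default 1.0);
desk scale uses 0.1 because cosine-bounded logits at τ = 1 floor the
attainable loss (≈0.67 at K = 8) and slow convergence.

### Inference and OOD

Candidate names are embedded once and shared across cells; prediction is
argmax cosine similarity, ties to the earliest candidate. Probabilities
are the softmax of `sim/τ` using the model's training temperature — at
τ = 1 the cosine bound compresses all seen-entropies into a sliver below
ln(n_seen) and the OOD statistic loses its resolution, so matching the
training scale is the package's reading of "probability scores". The OOD
statistic is the Shannon entropy (nats; the base only rescales the
data-derived threshold) of the seen-restricted, renormalized distribution.
The default threshold is the median (second quartile, linear-interpolation
convention) of the test set's entropies; cells strictly above it are
reassigned to the most similar unseen candidate, because downstream
scoring needs concrete unseen predictions rather than a bare "unknown".

### Evaluation

Micro-F1 (equal to accuracy in this single-label setting — asserted
against a brute-force count) and support-weighted macro-F1 are computed
over the union of truth and predicted labels, so a prediction-only class
still costs false positives while carrying zero support weight. Cells are
partitioned by their **true** label into seen/unseen; mixed scores are
harmonic means, micro with micro and macro with macro. The entropy-bin
curve sorts cells ascending by entropy (stable ties), cuts them into
`n_bins` contiguous bins with the first `n mod n_bins` bins one cell
larger, and reports the seen proportion per bin.

### Clustering augmentation

`augment_features` concatenates `[expression | probabilities]` with no
rescaling of either block. Clustering accuracy is the optimal one-to-one
cluster/class assignment (Hungarian optimum on the contingency table);
with unequal counts the assignment covers the smaller side and unmatched
clusters contribute nothing. The reference augmentation experiment feeds
per-cell **L2-normalized** expression (cosine feature space, as in
nearest-neighbour cell matching) into the concatenation: probability
vectors live on the unit simplex, and against raw log1p features (whose
pairwise distances are one to two orders of magnitude larger) their
contribution to the k-means metric is a percent-level perturbation lost in
restart noise. On the unit sphere the two blocks are commensurate and the
gain from informative predictions is large and consistent. Leiden
clustering runs on a symmetrized Euclidean kNN graph (defaults: 15
neighbours, resolution 1.0, seeded).

## Synthetic data

The generator emulates the statistical structure the method assumes:
type-specific expression programs organized in pathways, and cell names
whose words correspond to those programs. Default conditions: 600 genes;
20 pathways of 25 genes with 10% consecutive overlap and at least 20% of
genes orphan; ten types named adjective x role ("alpha helper cell" ...),
where each adjective and each role maps to one dedicated pathway and a
type's signature is its two tokens' pathways at fold change 4 over base
mean 1; 150 cells per type; negative-binomial counts (dispersion r = 2,
variance μ + μ²/r) scaled by a log-normal library factor (CV 0.3) and
thinned by independent dropout (rate 0.2); raw integer counts out. Two
types ("beta memory cell", "delta killer cell") are unseen: every word of
an unseen name must occur in some seen name — validated at construction —
so zero-shot transfer is learnable in principle, not by luck.

Splits hold out all unseen-type cells to the test set and divide each
seen type 7:1:2 (train:val:test) within one cell of exact proportions;
types with fewer than three cells go wholly to train with a warning.
Everything is a deterministic function of the spec seed (byte-identical
regeneration is tested).

What the generator does **not** emulate: batch and organ structure,
gene-length/GC bias, doublets, ambient RNA, the heavy type-imbalance of
real atlases, and the breadth of real nomenclature. Passing desk-scale
tests therefore demonstrates that the mechanisms work as specified, not
that atlas-scale accuracy transfers.

## Study sizes and numerical choices

Tests and the reproduction script use the desk-scale model and the default
generator conditions; the zero-shot protocol runs three seeds, the
grouping ablation trains two models per seed (supervised, 300 steps, 60
cells per type) on data where every type is seen, and the augmentation
comparison reuses the zero-shot models over five seeds in the test suite
(three in the script). Raw-count detection treats values within 1e-6 of
an integer as integral (sparse round-off). The gene filter compares
`detecting_cells >= fraction * n_cells` in real arithmetic — no ceiling —
against the post-cell-filter count. Log transform is natural-log1p, the
convention for this normalize-then-log pipeline. Cosine similarity rejects
zero-norm embeddings rather than silently clamping. The preprocessing
thresholds for synthetic data (min 50 detected genes) are scaled to the
600-gene universe; production defaults (200 genes, 0.1% of cells, total
10,000) apply to real data.

## Known limitations

- The numpy autodiff engine is single-threaded and eager; it is built for
  desk-scale models, and the production geometry, while expressible, would
  be impractically slow to train with it.
- The built-in text encoder ignores word order and subword structure;
  names differing only in word order collide.
- The median-entropy threshold assumes roughly half the test set is
  worth flagging; test sets with very skewed seen/unseen composition
  deserve an explicit threshold.
- Highly-variable-gene selection is delegated to scanpy and exposed only
  as an optional flag.
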
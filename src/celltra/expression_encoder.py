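"""Pathway-informed transformer over gene-set super tokens.

Each gene carries a learnable embedding G_j in R^D. A gene-set token is the
expression-weighted average (1/n_gene) * sum_j x_j G_j over the genes of the
set — zero-expression genes participate in the average, so sparse sets yield
attenuated tokens. A learnable CLS embedding is prepended and the sequence
runs through a standard post-norm transformer encoder with NO positional
encoding: gene-set order is biologically meaningless, and the encoder output
at the CLS position is the cell representation.

A linear classification head on the CLS output covers the supervised
cell-type prediction setting.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Adam, Tensor, concat, gelu, softmax
from .io_formats import ExpressionMatrix, NORMALIZED_LOG
from .tokenizer import GeneGrouping

__all__ = [
    "GeneEmbeddingTable",
    "TransformerEncoder",
    "ExpressionEncoder",
    "ClassifierHead",
    "embed_gene_set",
    "build_token_sequence",
]


def _init(rng: np.random.Generator, *shape, scale: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _init(rng, d_in, d_out, scale=d_in**-0.5)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * centered * (var + self.eps) ** -0.5 + self.beta

    def params(self):
        return [self.gamma, self.beta]


class MultiHeadAttention:
    def __init__(self, rng, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * self.d_head**-0.5
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)

    def params(self):
        return [*self.wq.params(), *self.wk.params(), *self.wv.params(),
                *self.wo.params()]


class TransformerLayer:
    """Post-norm encoder layer: LN(x + MHA(x)) then LN(x + FFN(x))."""

    def __init__(self, rng, dim: int, n_heads: int, d_ff: int):
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.fc1 = Linear(rng, dim, d_ff)
        self.fc2 = Linear(rng, d_ff, dim)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, dropout_mask=None) -> Tensor:
        h = self.ln1(x + self.attn(x))
        f = self.fc2(gelu(self.fc1(h)))
        if dropout_mask is not None:
            f = f * dropout_mask
        return self.ln2(h + f)

    def params(self):
        return [*self.attn.params(), *self.ln1.params(), *self.fc1.params(),
                *self.fc2.params(), *self.ln2.params()]


class GeneEmbeddingTable:
    """One learnable D-vector per vocabulary gene."""

    def __init__(self, n_genes: int, dim: int, rng: np.random.Generator):
        self.table = _init(rng, n_genes, dim)
        self.dim = dim
        self.n_genes = n_genes

    def params(self):
        return [self.table]


def _group_weight_matrix(grouping: GeneGrouping) -> np.ndarray:
    """(M x n_genes) matrix W with W[m, j] = 1/|group m| for member genes."""
    W = np.zeros((grouping.n_groups, len(grouping.vocabulary)))
    for m, members in enumerate(grouping.groups):
        W[m, members] = 1.0 / len(members)
    return W


def embed_gene_set(profile: np.ndarray, group: list[int],
                   table: GeneEmbeddingTable) -> np.ndarray:
    """Token embedding of one gene set for one cell.

    Returns (1/n_gene) * sum_{j in group} x_j G_j, averaging over the FULL
    group size: genes with zero expression still count in the denominator.
    """
    if len(group) == 0:
        raise ValueError("empty gene set")
    x = np.asarray(profile, dtype=np.float64)[list(group)]
    G = table.table.data[list(group)]
    return (x[:, None] * G).sum(axis=0) / len(group)


class ExpressionEncoder:
    """Gene-set tokens -> CLS cell embedding, with the classification head
    available for the supervised setting."""

    def __init__(self, grouping: GeneGrouping, dim: int = 32,
                 n_layers: int = 2, n_heads: int = 4,
                 intermediate_dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grouping = grouping
        self.dim = dim
        self.gene_table = GeneEmbeddingTable(len(grouping.vocabulary), dim, rng)
        self.cls = _init(rng, 1, 1, dim)
        self.layers = [TransformerLayer(rng, dim, n_heads, intermediate_dim)
                       for _ in range(n_layers)]
        self._W = _group_weight_matrix(grouping)

    # -- tokenization --------------------------------------------------------

    def token_sequence(self, X: np.ndarray) -> Tensor:
        """Batched token sequences for profiles X (B x n_genes): returns a
        (B, M+1, D) tensor, row 0 the shared CLS embedding."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.grouping.vocabulary):
            raise ValueError(
                f"profile has {X.shape[1]} genes; grouping vocabulary has "
                f"{len(self.grouping.vocabulary)}")
        B = X.shape[0]
        # A[b, m, j] = W[m, j] * x[b, j]; tokens = A @ G
        A = Tensor(X[:, None, :] * self._W[None, :, :])
        tokens = A @ self.gene_table.table  # (B, M, D)
        # broadcast the shared CLS row across the batch (grad sums back)
        cls_rows = self.cls + Tensor(np.zeros((B, 1, self.dim)))
        return concat([cls_rows, tokens], axis=1)

    def encode(self, X: np.ndarray, dropout: float = 0.0,
               rng: np.random.Generator | None = None) -> Tensor:
        """Cell embeddings: (B, D) tensor at the CLS position."""
        h = self.token_sequence(X)
        for layer in self.layers:
            mask = None
            if dropout > 0.0 and rng is not None:
                keep = rng.random(h.shape[-1:]) >= dropout
                mask = Tensor(keep / (1.0 - dropout))
            h = layer(h, dropout_mask=mask)
        return h[:, 0, :]

    def encode_array(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic (eval-mode) embeddings as a plain array."""
        X = np.atleast_2d(X)
        chunks = [self.encode(X[i:i + batch_size]).data
                  for i in range(0, X.shape[0], batch_size)]
        return np.vstack(chunks)

    def params(self):
        out = [*self.gene_table.params(), self.cls]
        for layer in self.layers:
            out.extend(layer.params())
        return out


def build_token_sequence(profile: np.ndarray, grouping: GeneGrouping,
                         encoder: ExpressionEncoder) -> np.ndarray:
    """(M+1) x D token matrix for one cell, CLS first (eval mode)."""
    if grouping is not encoder.grouping and \
            grouping.vocabulary != encoder.grouping.vocabulary:
        missing = set(grouping.vocabulary) ^ set(encoder.grouping.vocabulary)
        raise ValueError(f"grouping/encoder vocabulary mismatch: {sorted(missing)[:5]}")
    return encoder.token_sequence(np.atleast_2d(profile)).data[0]


class ClassifierHead:
    """Linear map from cell embedding to class logits."""

    def __init__(self, dim: int, n_classes: int, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(seed)
        self.linear = Linear(rng, dim, n_classes)
        self.n_classes = n_classes

    def __call__(self, embedding: Tensor) -> Tensor:
        return self.linear(embedding)

    def params(self):
        return self.linear.params()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (B, C) logits against integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    B, C = logits.shape
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=-1).log()
    onehot = Tensor(np.eye(C)[labels])
    picked = (z * onehot).sum(axis=-1)
    return (lse - picked).mean()


def scheduled_lr(lr: float, step: int, n_steps: int,
                 schedule: str = "none") -> float:
    """Cosine decay from lr to 0.1*lr over the run, or constant."""
    if schedule == "none":
        return lr
    if schedule == "cosine":
        frac = step / max(n_steps - 1, 1)
        return lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
    raise ValueError(f"unknown lr_schedule {schedule!r}")


def train_supervised(encoder: ExpressionEncoder, head: ClassifierHead,
                     matrix: ExpressionMatrix, labels: np.ndarray,
                     n_steps: int = 200, batch_size: int = 16,
                     lr: float = 3e-3, seed: int = 0,
                     lr_schedule: str = "none") -> list[float]:
    """Joint encoder+head training with cross-entropy; returns loss trace."""
    if matrix.state != NORMALIZED_LOG:
        raise ValueError("train_supervised expects a normalized-log matrix")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.intp)
    opt = Adam([*encoder.params(), *head.params()], lr=lr)
    trace: list[float] = []
    n = matrix.n_cells
    for step in range(n_steps):
        opt.lr = scheduled_lr(lr, step, n_steps, lr_schedule)
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        emb = encoder.encode(matrix.values[idx])
        loss = cross_entropy_logits(head(emb), labels[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if not np.isfinite(trace[-1]):
            raise RuntimeError(f"training diverged at step {len(trace)}: "
                               f"loss={trace[-1]}")
    return trace
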
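"""Contrastive cell-name / gene-expression alignment.

Both encoders project into a shared space; a training batch of K cells
with pairwise-distinct names forms a K x K cosine-similarity matrix whose
diagonal holds the matching pairs. The objective is the symmetric softmax
cross-entropy with diagonal targets — rows let each cell classify its name,
columns let each name classify its cell — averaged over both directions.
Embeddings are L2-normalized inside the similarity computation, never in
storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .expression_encoder import ExpressionEncoder, Linear, scheduled_lr
from .io_formats import ExpressionMatrix, NORMALIZED_LOG, RunConfig
from .text_encoder import BuiltinTextEncoder, build_vocabulary
from .tokenizer import GeneGrouping

__all__ = ["ProjectionHeads", "AlignmentBatch", "similarity_matrix",
           "contrastive_loss", "sample_batch", "CelltraModel", "train"]


class ProjectionHeads:
    """Linear projections of both modalities into the shared space."""

    def __init__(self, expr_dim: int, text_dim: int, shared_dim: int = 512,
                 seed: int = 0, identity_expr: bool = False):
        rng = np.random.default_rng(seed)
        self.shared_dim = shared_dim
        self.identity_expr = identity_expr
        if identity_expr:
            if expr_dim != shared_dim:
                raise ValueError(
                    "identity expression projection needs expr_dim == shared_dim")
            self.expr_projection = None
        else:
            self.expr_projection = Linear(rng, expr_dim, shared_dim)
        self.name_projection = Linear(rng, text_dim, shared_dim)

    def project_expression(self, C: Tensor) -> Tensor:
        return C if self.expr_projection is None else self.expr_projection(C)

    def project_names(self, T: Tensor) -> Tensor:
        return self.name_projection(T)

    def params(self):
        out = list(self.name_projection.params())
        if self.expr_projection is not None:
            out.extend(self.expr_projection.params())
        return out


@dataclass
class AlignmentBatch:
    """Projected embeddings of K (cell, name) pairs; names are distinct and
    pair i matches on the diagonal."""

    C: Tensor
    T: Tensor
    names: list[str]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("batch names must be pairwise distinct")
        if self.C.shape[0] != self.T.shape[0] or \
                self.C.shape[0] != len(self.names):
            raise ValueError("C, T and names must agree on K")

    @property
    def K(self) -> int:
        return len(self.names)


def _l2_normalize(X: Tensor, eps: float = 1e-12) -> Tensor:
    norms = (X * X).sum(axis=-1, keepdims=True)
    if np.any(norms.data <= eps):
        raise ValueError("zero-norm embedding; cannot take cosine similarity")
    return X * norms**-0.5


def similarity_matrix(batch: AlignmentBatch) -> Tensor:
    """K x K cosine similarities: entry (i, j) = cos(C_i, T_j)."""
    Cn = _l2_normalize(batch.C)
    Tn = _l2_normalize(batch.T)
    return Cn @ Tn.transpose(1, 0)


def _diagonal_cross_entropy(logits: Tensor) -> Tensor:
    """Mean softmax CE of each row against its own index."""
    K = logits.shape[0]
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=-1).log()
    diag = (z * Tensor(np.eye(K))).sum(axis=-1)
    return (lse - diag).mean()


def contrastive_loss(sim: Tensor | np.ndarray,
                     temperature: float = 1.0) -> Tensor:
    """Symmetric diagonal cross-entropy on sim/temperature.

    Averages the row direction (cells classify names) and the column
    direction (names classify cells). For a uniform matrix the loss is
    ln K; it tends to 0 as the diagonal dominates.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    sim = sim if isinstance(sim, Tensor) else Tensor(sim)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {sim.shape}")
    logits = sim * (1.0 / temperature)
    row_ce = _diagonal_cross_entropy(logits)
    col_ce = _diagonal_cross_entropy(logits.transpose(1, 0))
    return (row_ce + col_ce) * 0.5


def sample_batch(cell_names: list[str], K: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Indices of K cells with pairwise-distinct names.

    K names are drawn uniformly without replacement, then one cell
    uniformly per name. Deterministic given the rng state.
    """
    by_name: dict[str, list[int]] = {}
    for i, name in enumerate(cell_names):
        by_name.setdefault(name, []).append(i)
    distinct = sorted(by_name)
    if len(distinct) < K:
        raise ValueError(
            f"only {len(distinct)} distinct names for batch size {K}; "
            "reduce K")
    chosen = rng.choice(len(distinct), size=K, replace=False)
    return np.array([by_name[distinct[j]][rng.integers(len(by_name[distinct[j]]))]
                     for j in chosen], dtype=np.intp)


class CelltraModel:
    """Bundle of expression encoder, text encoder and projection heads."""

    def __init__(self, encoder: ExpressionEncoder, text_encoder,
                 heads: ProjectionHeads, config: RunConfig):
        self.encoder = encoder
        self.text_encoder = text_encoder
        self.heads = heads
        self.config = config

    @classmethod
    def build(cls, grouping: GeneGrouping, train_names: list[str],
              config: RunConfig) -> "CelltraModel":
        encoder = ExpressionEncoder(
            grouping, dim=config.embedding_dim, n_layers=config.n_layers,
            n_heads=config.n_heads, intermediate_dim=config.intermediate_dim,
            seed=config.seed)
        text = BuiltinTextEncoder(build_vocabulary(train_names),
                                  dim=config.text_dim, seed=config.seed + 1,
                                  trainable=not config.freeze_text_encoder)
        heads = ProjectionHeads(config.embedding_dim, text.native_dim,
                                shared_dim=config.shared_dim,
                                seed=config.seed + 2,
                                identity_expr=config.identity_expr_projection)
        return cls(encoder, text, heads, config)

    # -- embedding helpers (eval mode, plain arrays) -------------------------

    def embed_cells(self, X: np.ndarray) -> np.ndarray:
        return self.heads.project_expression(
            Tensor(self.encoder.encode_array(X))).data

    def embed_names(self, names: list[str]) -> np.ndarray:
        return self.heads.project_names(self.text_encoder.encode(names)).data

    def params(self):
        return [*self.encoder.params(), *self.text_encoder.params(),
                *self.heads.params()]

    # -- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2))
        self.encoder.grouping.to_json(directory / "grouping.json")
        (directory / "text_vocabulary.json").write_text(
            json.dumps(self.text_encoder.vocabulary))
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(directory / "params.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "CelltraModel":
        directory = Path(directory)
        config = RunConfig.from_dict(
            json.loads((directory / "config.json").read_text()))
        grouping = GeneGrouping.from_json(directory / "grouping.json")
        vocab = json.loads((directory / "text_vocabulary.json").read_text())
        encoder = ExpressionEncoder(
            grouping, dim=config.embedding_dim, n_layers=config.n_layers,
            n_heads=config.n_heads, intermediate_dim=config.intermediate_dim,
            seed=config.seed)
        text = BuiltinTextEncoder(vocab, dim=config.text_dim,
                                  seed=config.seed + 1,
                                  trainable=not config.freeze_text_encoder)
        heads = ProjectionHeads(config.embedding_dim, text.native_dim,
                                shared_dim=config.shared_dim,
                                seed=config.seed + 2,
                                identity_expr=config.identity_expr_projection)
        model = cls(encoder, text, heads, config)
        with np.load(directory / "params.npz") as data:
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"p{i}"]
        return model


def train(matrix: ExpressionMatrix, grouping: GeneGrouping,
          config: RunConfig) -> tuple[CelltraModel, list[float]]:
    """Contrastive pretraining; returns the model and the per-step loss trace.

    The matrix must be preprocessed (normalized-log) and labeled. Each step
    samples a distinct-name batch, computes the symmetric contrastive loss
    at ``config.temperature`` and takes one Adam step at
    ``config.lr_contrastive``. Fully seeded.
    """
    if matrix.state != NORMALIZED_LOG:
        raise ValueError("train expects a normalized-log matrix; run "
                         "preprocessing first")
    if matrix.cell_names is None:
        raise ValueError("train requires per-cell names")
    model = CelltraModel.build(grouping, sorted(set(matrix.cell_names)),
                               config)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr_contrastive)
    trace: list[float] = []
    for step in range(config.n_steps):
        opt.lr = scheduled_lr(config.lr_contrastive, step, config.n_steps,
                              config.lr_schedule)
        idx = sample_batch(matrix.cell_names, config.batch_size, rng)
        names = [matrix.cell_names[i] for i in idx]
        C = model.heads.project_expression(
            model.encoder.encode(matrix.values[idx],
                                 dropout=config.dropout, rng=rng))
        T = model.heads.project_names(model.text_encoder.encode(names))
        batch = AlignmentBatch(C=C, T=T, names=names)
        loss = contrastive_loss(similarity_matrix(batch), config.temperature)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(f"contrastive loss became {value} at step "
                               f"{step}; lower the learning rate")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(value)
    return model, trace
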
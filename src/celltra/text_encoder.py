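"""Cell-name encoders: a trainable bag-of-words builtin plus an adapter
slot for external pretrained language models.

The builtin lowercases, splits on non-alphanumerics, embeds each word from
a trainable table (out-of-vocabulary words share an UNK vector) and
mean-pools. Because unseen cell names are usually recombinations of seen
words ("beta memory cell" from "beta killer cell" + "alpha memory cell"),
mean-pooled word embeddings give compositional generalization — the
desk-scale counterpart of a biomedical language model's semantic space.
External models plug in through :class:`AdapterTextEncoder`, a callable
mapping names to fixed-dimension vectors; nothing in the package downloads
or requires pretrained weights.
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

import numpy as np

from ._autodiff import Tensor, concat, gather_rows
from .io_formats import normalize_name

__all__ = ["tokenize_name", "build_vocabulary", "BuiltinTextEncoder",
           "AdapterTextEncoder"]

_SPLIT = re.compile(r"[^0-9a-z]+")
UNK = "<unk>"


def tokenize_name(name: str) -> list[str]:
    """Lowercase word tokens of a cell name (alphanumeric runs)."""
    name = normalize_name(name).lower()
    return [t for t in _SPLIT.split(name) if t]


def build_vocabulary(names: Sequence[str]) -> list[str]:
    """Sorted unique lowercase tokens across names, plus the UNK slot.

    Deterministic and order-independent; UNK is always the last entry.
    """
    if not names:
        raise ValueError("no names given")
    tokens: set[str] = set()
    for name in names:
        toks = tokenize_name(name)
        if not toks:
            raise ValueError(f"name {name!r} has no tokens")
        tokens.update(toks)
    return sorted(tokens) + [UNK]


class BuiltinTextEncoder:
    """Trainable mean-pooled word-embedding encoder."""

    kind = "builtin"

    def __init__(self, vocabulary: list[str], dim: int = 32, seed: int = 0,
                 trainable: bool = True):
        if dim <= 0:
            raise ValueError("dim must be positive")
        rng = np.random.default_rng(seed)
        self.vocabulary = list(vocabulary)
        if UNK not in self.vocabulary:
            self.vocabulary.append(UNK)
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        self.dim = dim
        self.native_dim = dim
        self.trainable = trainable
        self.table = Tensor(rng.normal(0.0, 0.02,
                                       size=(len(self.vocabulary), dim)),
                            requires_grad=trainable)

    def _token_ids(self, name: str) -> list[int]:
        toks = tokenize_name(name)
        if not toks:
            raise ValueError(f"cell name {name!r} is empty after tokenization")
        unk = self._index[UNK]
        return [self._index.get(t, unk) for t in toks]

    def encode(self, names: Sequence[str]) -> Tensor:
        """(K, dim) tensor of mean-pooled name embeddings (differentiable)."""
        if not names:
            raise ValueError("no names to encode")
        rows = []
        for name in names:
            ids = self._token_ids(name)
            emb = gather_rows(self.table, ids).mean(axis=0)
            rows.append(emb.reshape(1, self.dim))
        return concat(rows, axis=0)

    def encode_array(self, names: Sequence[str]) -> np.ndarray:
        return self.encode(names).data

    def params(self) -> list[Tensor]:
        return [self.table] if self.trainable else []


class AdapterTextEncoder:
    """Wrap an external names->vectors callable (e.g. a pretrained LM).

    The callable must return an array of shape (len(names), native_dim);
    a wrong dimension is rejected. Adapter encoders are frozen — they
    expose no trainable parameters; alignment happens in the projection.
    """

    kind = "external-adapter"

    def __init__(self, fn: Callable[[Sequence[str]], np.ndarray],
                 native_dim: int):
        if native_dim <= 0:
            raise ValueError("native_dim must be positive")
        self.fn = fn
        self.dim = native_dim
        self.native_dim = native_dim

    def encode(self, names: Sequence[str]) -> Tensor:
        return Tensor(self.encode_array(names))

    def encode_array(self, names: Sequence[str]) -> np.ndarray:
        if not names:
            raise ValueError("no names to encode")
        for name in names:
            if not normalize_name(name):
                raise ValueError("empty cell name")
        out = np.asarray(self.fn(list(names)), dtype=np.float64)
        if out.shape != (len(names), self.native_dim):
            raise ValueError(
                f"adapter returned shape {out.shape}; expected "
                f"({len(names)}, {self.native_dim})")
        return out

    def params(self) -> list[Tensor]:
        return []
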
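"""Seeded generator of desk-scale scRNA-seq datasets with pathway-structured
type signatures and compositional cell names.

Cells of a named type elevate the genes of that type's signature pathways
by a fold change over a shared baseline; counts are negative-binomial with
per-cell log-normal library-size variation and independent dropout. Names
are compositional ("alpha helper cell", "beta memory cell"): each word
token corresponds to one signature pathway, so an unseen type named from
seen words has a genuinely inferable expression program — the desk-scale
counterpart of the semantic generalization a biomedical language model
provides at atlas scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, PathwayCollection
from .text_encoder import tokenize_name

__all__ = ["CellTypeSpec", "SyntheticSpec", "SplitManifest",
           "generate_pathways", "generate_cells", "make_split",
           "default_spec", "compositional_names"]


@dataclass
class CellTypeSpec:
    name: str
    signature_pathways: list[str]
    fold_change: float = 4.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset; a seed pins every draw."""

    n_genes: int = 600
    n_pathways: int = 20
    genes_per_pathway: int = 25
    pathway_overlap_fraction: float = 0.1
    orphan_fraction: float = 0.2
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    n_cells_per_type: int = 150
    base_mean: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    library_size_cv: float = 0.3
    seed: int = 0
    unseen_types: list[str] = field(default_factory=list)
    train_frac: float = 0.7
    val_frac: float = 0.1
    test_frac: float = 0.2

    def __post_init__(self):
        if not self.cell_types:
            return
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique")
        unknown = set(self.unseen_types) - set(names)
        if unknown:
            raise ValueError(f"unseen types not defined: {sorted(unknown)}")
        seen_tokens: set[str] = set()
        for t in self.cell_types:
            if t.fold_change < 1:
                raise ValueError(
                    f"fold_change must be >= 1, got {t.fold_change}")
            if t.name not in self.unseen_types:
                seen_tokens.update(tokenize_name(t.name))
        for name in self.unseen_types:
            extra = set(tokenize_name(name)) - seen_tokens
            if extra:
                raise ValueError(
                    f"unseen type {name!r} uses tokens {sorted(extra)} that "
                    "appear in no seen type name; zero-shot transfer would "
                    "be impossible")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def seen_types(self) -> list[str]:
        return [t.name for t in self.cell_types
                if t.name not in self.unseen_types]


def generate_pathways(spec: SyntheticSpec) -> PathwayCollection:
    """Draw the pathway collection over the gene universe.

    Genes are shuffled by seed; an orphan block of
    ``round(orphan_fraction * n_genes)`` genes is reserved outside all
    pathways; consecutive pathways share
    ``round(overlap_fraction * genes_per_pathway)`` genes. Pool genes the
    pathways do not reach stay orphan too, so ``orphan_fraction`` is a
    floor, not an exact count.
    """
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    n_orphan = round(spec.orphan_fraction * spec.n_genes)
    pool_size = spec.n_genes - n_orphan
    overlap = round(spec.pathway_overlap_fraction * spec.genes_per_pathway)
    fresh_needed = (spec.n_pathways * spec.genes_per_pathway
                    - (spec.n_pathways - 1) * overlap)
    if fresh_needed > pool_size:
        raise ValueError(
            f"{spec.n_pathways} pathways x {spec.genes_per_pathway} genes "
            f"(overlap {overlap}) need {fresh_needed} genes but only "
            f"{pool_size} are outside the orphan block")
    rng = np.random.default_rng(spec.seed)
    shuffled = [gene_ids[i] for i in rng.permutation(spec.n_genes)]
    pool = shuffled[:pool_size]

    pathways: dict[str, list[str]] = {}
    cursor = 0
    previous: list[str] = []
    for k in range(spec.n_pathways):
        shared = previous[-overlap:] if overlap and previous else []
        fresh = pool[cursor:cursor + spec.genes_per_pathway - len(shared)]
        cursor += len(fresh)
        members = shared + fresh
        pathways[f"P{k:02d}"] = members
        previous = members
    return PathwayCollection(pathways)


def generate_cells(spec: SyntheticSpec,
                   pathways: PathwayCollection) -> ExpressionMatrix:
    """Sample the count matrix with per-cell type labels.

    Gene means are ``base_mean`` times the type's fold change when the gene
    lies in any signature pathway of the type; counts follow a negative
    binomial with the given dispersion, scaled by a log-normal library-size
    factor (CV as specified) and thinned by independent dropout.
    """
    if not spec.cell_types:
        raise ValueError("spec defines no cell types")
    for t in spec.cell_types:
        missing = set(t.signature_pathways) - set(pathways.pathways)
        if missing:
            raise ValueError(f"type {t.name!r} references unknown pathways "
                             f"{sorted(missing)}")
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rng = np.random.default_rng(spec.seed + 1)

    rows: list[np.ndarray] = []
    names: list[str] = []
    sigma = np.sqrt(np.log(1.0 + spec.library_size_cv**2))
    for t in spec.cell_types:
        signature = np.zeros(spec.n_genes, dtype=bool)
        for pid in t.signature_pathways:
            signature[[gene_index[g] for g in pathways[pid]]] = True
        means = np.where(signature, spec.base_mean * t.fold_change,
                         spec.base_mean)
        for _ in range(spec.n_cells_per_type):
            lib = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            mu = np.maximum(means * lib, 1e-12)
            r = spec.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            if spec.dropout_rate > 0:
                counts = counts * (rng.random(spec.n_genes)
                                   >= spec.dropout_rate)
            rows.append(counts.astype(np.float64))
            names.append(t.name)

    values = np.vstack(rows)
    cell_ids = [f"C{i:05d}" for i in range(values.shape[0])]
    return ExpressionMatrix(values, gene_ids, cell_ids, names,
                            state="raw_counts")


@dataclass
class SplitManifest:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seen_types: list[str]
    unseen_types: list[str]

    def to_dict(self) -> dict:
        return {
            "train_idx": [int(i) for i in self.train_idx],
            "val_idx": [int(i) for i in self.val_idx],
            "test_idx": [int(i) for i in self.test_idx],
            "seen_types": self.seen_types,
            "unseen_types": self.unseen_types,
            "n_seen_types": len(self.seen_types),
            "n_unseen_types": len(self.unseen_types),
        }


def make_split(spec: SyntheticSpec, matrix: ExpressionMatrix) -> SplitManifest:
    """Train/val/test split with unseen types held out entirely.

    Every cell of an unseen type goes to test. Seen-type cells are split
    per type at the configured ratio (default 7:1:2) with counts within
    one cell of the exact proportions; a seen type with fewer than three
    cells goes wholly to train with a warning. Seeded and deterministic.
    """
    if matrix.cell_names is None:
        raise ValueError("matrix has no cell names to split on")
    rng = np.random.default_rng(spec.seed + 2)
    unseen = set(spec.unseen_types)
    train, val, test = [], [], []
    by_type: dict[str, list[int]] = {}
    for i, name in enumerate(matrix.cell_names):
        by_type.setdefault(name, []).append(i)
    for name in sorted(by_type):
        idx = np.array(by_type[name])
        if name in unseen:
            test.extend(idx.tolist())
            continue
        if idx.size < 3:
            warnings.warn(f"seen type {name!r} has only {idx.size} cells; "
                          "assigning all to train")
            train.extend(idx.tolist())
            continue
        perm = idx[rng.permutation(idx.size)]
        n_train = round(spec.train_frac * idx.size)
        n_val = round(spec.val_frac * idx.size)
        n_val = min(n_val, idx.size - n_train)
        train.extend(perm[:n_train].tolist())
        val.extend(perm[n_train:n_train + n_val].tolist())
        test.extend(perm[n_train + n_val:].tolist())
    seen_types = sorted(set(matrix.cell_names) - unseen)
    return SplitManifest(
        train_idx=np.array(sorted(train), dtype=np.intp),
        val_idx=np.array(sorted(val), dtype=np.intp),
        test_idx=np.array(sorted(test), dtype=np.intp),
        seen_types=seen_types,
        unseen_types=sorted(n for n in unseen if n in by_type),
    )


# -- default study conditions ------------------------------------------------

_ADJECTIVES = ["alpha", "beta", "gamma", "delta"]
_ROLES = ["helper", "killer", "memory"]


def default_spec(seed: int = 0, fold_change: float = 4.0) -> SyntheticSpec:
    """The default desk-scale conditions: 600 genes, 20 pathways, 10
    compositionally named types (2 unseen), 150 cells per type.

    Word tokens map to pathways — adjective k to pathway P0k, role k to
    P0(4+k) — and each type's signature is the union of its two tokens'
    pathways, so unseen combinations remain predictable from seen ones.
    """
    adj_pathway = {a: f"P{k:02d}" for k, a in enumerate(_ADJECTIVES)}
    role_pathway = {r: f"P{4 + k:02d}" for k, r in enumerate(_ROLES)}
    combos = [
        ("alpha", "helper"), ("alpha", "killer"), ("alpha", "memory"),
        ("beta", "helper"), ("beta", "killer"),
        ("gamma", "helper"), ("gamma", "memory"),
        ("delta", "helper"),
        ("beta", "memory"), ("delta", "killer"),  # the two unseen combos
    ]
    types = [CellTypeSpec(
        name=f"{a} {r} cell",
        signature_pathways=[adj_pathway[a], role_pathway[r]],
        fold_change=fold_change,
    ) for a, r in combos]
    return SyntheticSpec(
        cell_types=types,
        unseen_types=["beta memory cell", "delta killer cell"],
        seed=seed,
    )


def compositional_names(n_adj: int, n_role: int) -> list[str]:
    """An n_adj x n_role grid of compositional names ("tok3 tok5 cell")."""
    return [f"kind{a} state{r} cell"
            for a in range(n_adj) for r in range(n_role)]
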
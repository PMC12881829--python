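"""Standard-format I/O and the run-configuration contract.

Readers for GMT gene-set files, expression matrices (h5ad, MatrixMarket
directory, dense CSV) and candidate-name lists; the TSV prediction writer;
and :class:`RunConfig`, which holds every tunable with its production
default.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "RunConfig",
    "read_gmt",
    "read_expression",
    "write_expression",
    "read_name_list",
    "write_predictions",
    "read_predictions",
    "normalize_name",
]

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG = "normalized_log"

_INT_TOL = 1e-6  # values this close to an integer count as integers


def normalize_name(name: str) -> str:
    """Canonical form for free-text cell names: NFC + trimmed whitespace."""
    return unicodedata.normalize("NFC", name).strip()


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifiers and optional labels.

    ``state`` tracks processing: ``raw_counts`` (non-negative integers) or
    ``normalized_log`` (non-negative reals after total-count normalization
    and log1p).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_names: list[str] | None = None
    state: str = RAW_COUNTS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.cell_names is not None:
            self.cell_names = [normalize_name(n) for n in self.cell_names]
        self.validate()

    def validate(self):
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns")
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        if self.cell_names is not None and len(self.cell_names) != n_cells:
            raise ValueError("cell_names length must match cell count")
        if self.state not in (RAW_COUNTS, NORMALIZED_LOG):
            raise ValueError(f"unknown state {self.state!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.state == RAW_COUNTS and not _is_integral(self.values):
            raise ValueError("state=raw_counts requires integer values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        indices = np.arange(self.n_cells)[np.asarray(mask)]
        return ExpressionMatrix(
            values=self.values[indices],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in indices],
            cell_names=None if self.cell_names is None
            else [self.cell_names[i] for i in indices],
            state=self.state,
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        indices = np.arange(self.n_genes)[np.asarray(mask)]
        return ExpressionMatrix(
            values=self.values[:, indices],
            gene_ids=[self.gene_ids[i] for i in indices],
            cell_ids=list(self.cell_ids),
            cell_names=None if self.cell_names is None else list(self.cell_names),
            state=self.state,
        )


def _is_integral(values: np.ndarray) -> bool:
    return bool(np.all(np.abs(values - np.round(values)) <= _INT_TOL))


@dataclass
class PathwayCollection:
    """Named gene sets; a gene may belong to several pathways."""

    pathways: dict[str, list[str]]

    def __post_init__(self):
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene list")

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> list[str]:
        return self.pathways[pid]

    def items(self):
        return self.pathways.items()

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out.update(genes)
        return out


@dataclass
class RunConfig:
    """Every tunable with its default.

    The model defaults are the production scale (768-dim gene embeddings,
    12 layers / 12 heads, 3072-dim feed-forward, 512-dim shared space,
    batch 32, learning rates 5e-5 supervised / 1e-5 contrastive).
    ``desk_scale()`` returns the small configuration used for tests and
    examples.
    """

    embedding_dim: int = 768
    n_layers: int = 12
    n_heads: int = 12
    intermediate_dim: int = 3072
    shared_dim: int = 512
    text_dim: int = 768
    orphan_set_size: int = 110
    batch_size: int = 32
    lr_pretrain: float = 5e-5
    lr_contrastive: float = 1e-5
    temperature: float = 1.0
    lr_schedule: str = "none"  # "none" or "cosine" decay to 10% of lr
    dropout: float = 0.1
    n_steps: int = 1000
    seed: int = 0
    min_genes: int = 200
    min_cell_fraction: float = 0.001
    target_sum: float = 10_000.0
    identity_expr_projection: bool = False
    freeze_text_encoder: bool = False

    def __post_init__(self):
        positive = {
            "embedding_dim": self.embedding_dim,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "intermediate_dim": self.intermediate_dim,
            "shared_dim": self.shared_dim,
            "text_dim": self.text_dim,
            "orphan_set_size": self.orphan_set_size,
            "batch_size": self.batch_size,
            "temperature": self.temperature,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ValueError(f"{key} must be positive, got {value}")
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError(
                f"embedding_dim {self.embedding_dim} not divisible by "
                f"n_heads {self.n_heads}")

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Small configuration for tests/examples: D=32, 2 layers, 4 heads."""
        base = dict(
            embedding_dim=32, n_layers=2, n_heads=4, intermediate_dim=64,
            shared_dim=32, text_dim=32, batch_size=8, temperature=0.1,
            lr_pretrain=3e-3, lr_contrastive=3e-3, lr_schedule="cosine",
            dropout=0.0, n_steps=1600,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "RunConfig":
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# -- GMT ---------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file: one tab-separated line per gene set.

    Line layout is ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a line are dropped (first occurrence kept);
    genes may recur across lines. Blank lines and trailing whitespace are
    tolerated.
    """
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene")
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{path}: duplicate pathway id {name!r} "
                                 f"at line {lineno}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}: line {lineno} has no genes")
            pathways[name] = genes
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for pid, genes in collection.items():
            desc = (descriptions or {}).get(pid, "na")
            fh.write("\t".join([pid, desc, *genes]) + "\n")


# -- expression matrices -----------------------------------------------------


def read_expression(path, format: str = "h5ad",
                    name_column: str = "cell_name") -> ExpressionMatrix:
    """Read an expression matrix from h5ad, an MTX directory, or dense CSV.

    CSV orientation is cells-as-rows with a header row of gene ids and the
    first column holding cell ids. ``name_column`` selects the per-cell
    annotation carrying the free-text cell name where one exists.
    State is inferred: raw counts iff every value is a non-negative integer.
    """
    path = Path(path)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        values = np.asarray(
            adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X,
            dtype=np.float64)
        names = (list(adata.obs[name_column].astype(str))
                 if name_column in adata.obs.columns else None)
        state = adata.uns.get("celltra_state") or _infer_state(values)
        return ExpressionMatrix(values, list(adata.var_names),
                                list(adata.obs_names), names, state)
    if format == "mtx_dir":
        from scipy.io import mmread

        matrix = np.asarray(mmread(path / "matrix.mtx").todense(),
                            dtype=np.float64)
        genes = _read_tsv_column(path / "genes.tsv")
        barcodes = _read_tsv_column(path / "barcodes.tsv")
        # MTX convention is genes x cells; transpose to cells x genes.
        if matrix.shape == (len(genes), len(barcodes)):
            matrix = matrix.T
        elif matrix.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {matrix.shape} matches neither "
                f"(genes={len(genes)}, cells={len(barcodes)}) orientation")
        names = None
        labels_path = path / "labels.tsv"
        if labels_path.exists():
            names = _read_tsv_column(labels_path)
        return ExpressionMatrix(matrix, genes, barcodes, names,
                                _infer_state(matrix))
    if format == "csv":
        frame = pd.read_csv(path, index_col=0)
        names = None
        if name_column in frame.columns:
            names = list(frame[name_column].astype(str))
            frame = frame.drop(columns=[name_column])
        if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
            bad = [c for c, dt in zip(frame.columns, frame.dtypes)
                   if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric expression columns: {bad}")
        values = frame.to_numpy(dtype=np.float64)
        return ExpressionMatrix(values, list(frame.columns),
                                [str(i) for i in frame.index], names,
                                _infer_state(values))
    raise ValueError(f"unknown format {format!r}; use h5ad, mtx_dir or csv")


def write_expression(matrix: ExpressionMatrix, path,
                     format: str = "h5ad",
                     name_column: str = "cell_name") -> None:
    path = Path(path)
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(matrix.cell_ids, name="cell_id"))
        if matrix.cell_names is not None:
            obs[name_column] = matrix.cell_names
        adata = ad.AnnData(
            X=matrix.values.copy(), obs=obs,
            var=pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene_id")))
        adata.uns["celltra_state"] = matrix.state
        adata.write_h5ad(path)
        return
    if format == "csv":
        frame = pd.DataFrame(matrix.values, index=matrix.cell_ids,
                             columns=matrix.gene_ids)
        if matrix.cell_names is not None:
            frame.insert(0, name_column, matrix.cell_names)
        frame.to_csv(path, index_label="cell_id")
        return
    raise ValueError(f"unsupported write format {format!r}")


def _infer_state(values: np.ndarray) -> str:
    return RAW_COUNTS if _is_integral(values) else NORMALIZED_LOG


def _read_tsv_column(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0]
                for line in fh if line.strip()]


# -- name lists and predictions ---------------------------------------------


def read_name_list(path) -> list[str]:
    """Candidate cell names: UTF-8 plain text, one per line."""
    with open(path, encoding="utf-8") as fh:
        names = [normalize_name(line) for line in fh if line.strip()]
    if not names:
        raise ValueError(f"{path} contains no names")
    return names


def write_predictions(results: Sequence, path) -> None:
    """Write prediction results as a TSV with a header row."""
    if not results:
        raise ValueError("no prediction results to write")
    frame = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "predicted_name": [r.final_name for r in results],
            "top_similarity": [r.top_similarity for r in results],
            "seen_entropy": [r.seen_entropy for r in results],
            "ood_flag": [bool(r.ood_flag) for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
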
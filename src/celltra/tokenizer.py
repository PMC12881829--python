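"""Gene-set tokenization: partition the gene vocabulary into super tokens.

Each pathway intersected with the vocabulary becomes one group; genes with
no pathway membership ("orphans") are shuffled by seed and chunked into
fixed-size random groups, whose last chunk may be short. A gene in several
pathways appears in each of those groups; orphan genes appear in exactly
one random group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import PathwayCollection

__all__ = ["GeneGrouping", "build_grouping", "tokens_per_profile"]

PATHWAY = "pathway"
RANDOM = "random"


@dataclass
class GeneGrouping:
    """Ordered grouping of a gene vocabulary into gene-set tokens.

    ``groups`` holds indices into ``vocabulary``; ``source`` flags each
    group as pathway-derived or random (orphan chunk).
    """

    groups: list[list[int]]
    group_ids: list[str]
    source: list[str]
    seed: int
    vocabulary: list[str]

    def __post_init__(self):
        self.validate()

    def validate(self):
        if len(self.groups) != len(self.group_ids) or \
                len(self.groups) != len(self.source):
            raise ValueError("groups, group_ids and source lengths differ")
        n = len(self.vocabulary)
        covered: set[int] = set()
        orphan_seen: set[int] = set()
        pathway_members: set[int] = set()
        for members, src in zip(self.groups, self.source):
            if not members:
                raise ValueError("empty group")
            if any(not (0 <= g < n) for g in members):
                raise ValueError("group index outside vocabulary")
            covered.update(members)
            if src == PATHWAY:
                pathway_members.update(members)
            else:
                dup = orphan_seen.intersection(members)
                if dup:
                    raise ValueError(
                        f"genes {sorted(dup)} in more than one random group")
                orphan_seen.update(members)
        if covered != set(range(n)):
            missing = sorted(set(range(n)) - covered)
            raise ValueError(f"vocabulary genes not covered: {missing[:5]}...")
        overlap = pathway_members & orphan_seen
        if overlap:
            raise ValueError(
                f"pathway genes also in random groups: {sorted(overlap)[:5]}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_random_groups(self) -> int:
        return sum(1 for s in self.source if s == RANDOM)

    @property
    def n_pathway_groups(self) -> int:
        return sum(1 for s in self.source if s == PATHWAY)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "group_ids": self.group_ids,
                "source": self.source,
                "groups": [[self.vocabulary[i] for i in g]
                           for g in self.groups],
                "seed": self.seed,
                "vocabulary": self.vocabulary,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload_or_path) -> "GeneGrouping":
        text = payload_or_path
        p = Path(str(payload_or_path))
        if p.exists():
            text = p.read_text()
        d = json.loads(text)
        index = {g: i for i, g in enumerate(d["vocabulary"])}
        return cls(
            groups=[[index[g] for g in group] for group in d["groups"]],
            group_ids=d["group_ids"],
            source=d["source"],
            seed=d["seed"],
            vocabulary=d["vocabulary"],
        )


def build_grouping(vocabulary: list[str], pathways: PathwayCollection,
                   orphan_set_size: int = 110, seed: int = 0) -> GeneGrouping:
    """Group ``vocabulary`` genes by pathway, chunking orphans randomly.

    Pathway groups come first in pathway-collection order, restricted to
    vocabulary genes (pathways with no measured gene are dropped). Orphans
    are shuffled with ``seed`` and cut into consecutive blocks of
    ``orphan_set_size``; the number of random groups is
    ``ceil(n_orphan / orphan_set_size)`` and only the last block may be
    short. Deterministic given (vocabulary order, pathways, size, seed).
    """
    if not vocabulary:
        raise ValueError("empty gene vocabulary")
    if orphan_set_size < 1:
        raise ValueError(f"orphan_set_size must be >= 1, got {orphan_set_size}")
    index = {g: i for i, g in enumerate(vocabulary)}

    groups: list[list[int]] = []
    group_ids: list[str] = []
    source: list[str] = []
    in_pathway: set[int] = set()
    for pid, genes in pathways.items():
        members = [index[g] for g in genes if g in index]
        if not members:
            continue
        groups.append(members)
        group_ids.append(pid)
        source.append(PATHWAY)
        in_pathway.update(members)

    orphans = [i for i in range(len(vocabulary)) if i not in in_pathway]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(orphans))
    shuffled = [orphans[i] for i in order]
    n_random = math.ceil(len(shuffled) / orphan_set_size)
    for k in range(n_random):
        chunk = shuffled[k * orphan_set_size:(k + 1) * orphan_set_size]
        groups.append(chunk)
        group_ids.append(f"random_{k}")
        source.append(RANDOM)

    return GeneGrouping(groups=groups, group_ids=group_ids, source=source,
                        seed=seed, vocabulary=list(vocabulary))


def build_random_grouping(vocabulary: list[str], group_sizes: list[int],
                          seed: int = 0) -> GeneGrouping:
    """Size-matched random control grouping: shuffle the whole vocabulary
    and cut it into blocks of the given sizes (must sum to the vocabulary
    size). Used for the pathway-vs-random ablation."""
    if sum(group_sizes) != len(vocabulary):
        raise ValueError("group sizes must sum to the vocabulary size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vocabulary))
    groups: list[list[int]] = []
    start = 0
    for size in group_sizes:
        groups.append([int(order[i]) for i in range(start, start + size)])
        start += size
    return GeneGrouping(
        groups=groups,
        group_ids=[f"random_{k}" for k in range(len(groups))],
        source=[RANDOM] * len(groups),
        seed=seed,
        vocabulary=list(vocabulary),
    )


def tokens_per_profile(grouping: GeneGrouping) -> int:
    """Number of gene-set input tokens M (the CLS token is added by the
    encoder, not counted here)."""
    return grouping.n_groups
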
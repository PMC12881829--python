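"""Shared fixtures. Heavy trained-model fixtures are session-scoped and
lazily cached so several tests can share one training run per seed."""

from __future__ import annotations

import numpy as np
import pytest

from celltra.io_formats import ExpressionMatrix, PathwayCollection
from celltra.tokenizer import build_grouping


@pytest.fixture()
def tiny_counts() -> ExpressionMatrix:
    values = np.array([[1, 0, 3, 0],
                       [2, 2, 0, 1],
                       [0, 5, 1, 1]], dtype=float)
    return ExpressionMatrix(values, ["G1", "G2", "G3", "G4"],
                            ["c1", "c2", "c3"],
                            ["alpha cell", "beta cell", "alpha cell"],
                            state="raw_counts")


@pytest.fixture()
def tiny_pathways() -> PathwayCollection:
    return PathwayCollection({"P1": ["G1", "G2"], "P2": ["G2", "G3"]})


@pytest.fixture()
def tiny_grouping(tiny_pathways):
    return build_grouping(["G1", "G2", "G3", "G4"], tiny_pathways,
                          orphan_set_size=2, seed=0)


class _OutcomeCache:
    """Train-once cache of full zero-shot runs keyed by seed."""

    def __init__(self):
        self._runs = {}

    def get(self, seed: int):
        if seed not in self._runs:
            from celltra.experiments import run_zero_shot

            self._runs[seed] = run_zero_shot(seed=seed)
        return self._runs[seed]


@pytest.fixture(scope="session")
def zero_shot_cache() -> _OutcomeCache:
    return _OutcomeCache()
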
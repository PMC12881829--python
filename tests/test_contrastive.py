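"""Similarity matrix, symmetric contrastive loss, batch sampling, training."""

import numpy as np
import pytest
from scipy.stats import chisquare

from celltra._autodiff import Tensor
from celltra.contrastive import (AlignmentBatch, contrastive_loss,
                                 sample_batch, similarity_matrix, train)
from celltra.io_formats import RunConfig
from celltra.preprocessing import preprocess
from celltra.synthetic_data import default_spec, generate_cells, \
    generate_pathways
from celltra.tokenizer import build_grouping


def _batch(C, T, names=None):
    C = np.asarray(C, dtype=float)
    names = names or [f"name {i}" for i in range(C.shape[0])]
    return AlignmentBatch(C=Tensor(C), T=Tensor(np.asarray(T, dtype=float)),
                          names=names)


class TestSimilarityMatrix:
    def test_orthonormal_identical_rows_give_identity(self):
        C = np.eye(3)
        sim = similarity_matrix(_batch(C, C)).data
        np.testing.assert_allclose(sim, np.eye(3), atol=1e-12)

    def test_negated_rows_give_minus_one_diagonal(self):
        C = np.eye(2)
        sim = similarity_matrix(_batch(C, -C)).data
        np.testing.assert_allclose(np.diag(sim), [-1.0, -1.0])

    def test_hand_cosine_case(self):
        C = [[1, 0], [0, 1]]
        T = [[1 / np.sqrt(2), 1 / np.sqrt(2)], [0, 1]]
        sim = similarity_matrix(_batch(C, T)).data
        np.testing.assert_allclose(sim, [[0.7071, 0.0], [0.7071, 1.0]],
                                   atol=1e-4)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            similarity_matrix(_batch([[0, 0], [1, 0]], np.eye(2)))

    def test_entries_bounded_by_one(self):
        rng = np.random.default_rng(0)
        sim = similarity_matrix(_batch(rng.normal(size=(5, 4)),
                                       rng.normal(size=(5, 4)))).data
        assert np.all(np.abs(sim) <= 1 + 1e-12)


def _oracle_symmetric_ce(sim: np.ndarray, temperature: float) -> float:
    """Independent reference: per-element softmax cross-entropy, written
    directly from the definition."""
    z = sim / temperature
    K = z.shape[0]

    def ce_rows(m):
        total = 0.0
        for i in range(K):
            row = np.exp(m[i] - m[i].max())
            p = row / row.sum()
            total += -np.log(p[i])
        return total / K

    return 0.5 * (ce_rows(z) + ce_rows(z.T))


class TestContrastiveLoss:
    def test_uniform_matrix_gives_ln_k(self):
        for K in (2, 5, 8):
            loss = contrastive_loss(np.full((K, K), 0.3)).data
            np.testing.assert_allclose(loss, np.log(K), rtol=1e-12)

    def test_single_pair_gives_zero(self):
        assert contrastive_loss(np.array([[0.9]])).data == pytest.approx(0.0)

    def test_dominant_diagonal_closed_form(self):
        sim = np.diag([10.0, 10.0])
        loss = contrastive_loss(sim, temperature=1.0).data
        np.testing.assert_allclose(loss, np.log(1 + np.exp(-10.0)),
                                   rtol=1e-9)

    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            sim = rng.normal(size=(3, 3))
            tau = float(rng.uniform(0.05, 2.0))
            ours = float(contrastive_loss(sim, temperature=tau).data)
            assert ours == pytest.approx(_oracle_symmetric_ce(sim, tau),
                                         abs=1e-6)

    def test_invariant_to_common_rotation(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(4, 6))
        T = rng.normal(size=(4, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = contrastive_loss(similarity_matrix(_batch(C, T))).data
        b = contrastive_loss(similarity_matrix(_batch(C @ Q, T @ Q))).data
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_increasing_a_diagonal_entry_never_increases_loss(self):
        rng = np.random.default_rng(2)
        sim = rng.normal(size=(4, 4))
        base = float(contrastive_loss(sim).data)
        for bump in (0.1, 1.0, 5.0):
            sim2 = sim.copy()
            sim2[2, 2] += bump
            assert float(contrastive_loss(sim2).data) <= base + 1e-12

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            contrastive_loss(np.ones((2, 3)))

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.eye(2), temperature=0.0)


class TestAlignmentBatch:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            _batch(np.eye(2), np.eye(2), names=["same", "same"])


class TestSampleBatch:
    NAMES = (["alpha cell"] * 5 + ["beta cell"] * 3 + ["gamma cell"] * 2
             + ["delta cell"] * 4)

    def test_names_pairwise_distinct(self):
        rng = np.random.default_rng(0)
        idx = sample_batch(self.NAMES, 4, rng)
        chosen = [self.NAMES[i] for i in idx]
        assert len(set(chosen)) == 4

    def test_k_equal_to_name_count_uses_each_once(self):
        rng = np.random.default_rng(0)
        idx = sample_batch(self.NAMES, 4, rng)
        assert sorted({self.NAMES[i] for i in idx}) == sorted(
            set(self.NAMES))

    def test_deterministic_for_fixed_seed(self):
        a = sample_batch(self.NAMES, 3, np.random.default_rng(7))
        b = sample_batch(self.NAMES, 3, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_too_few_distinct_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sample_batch(["one cell"] * 10, 2, np.random.default_rng(0))

    def test_name_selection_frequencies_uniform(self):
        rng = np.random.default_rng(3)
        counts = {n: 0 for n in set(self.NAMES)}
        for _ in range(2000):
            for i in sample_batch(self.NAMES, 2, rng):
                counts[self.NAMES[i]] += 1
        observed = np.array(list(counts.values()))
        _, p = chisquare(observed)
        assert p > 0.001


@pytest.fixture(scope="module")
def small_run():
    spec = default_spec(seed=0)
    spec.n_cells_per_type = 12
    pathways = generate_pathways(spec)
    matrix = preprocess(generate_cells(spec, pathways), min_genes=50,
                        min_cell_fraction=0.0)
    grouping = build_grouping(matrix.gene_ids, pathways, seed=0)
    config = RunConfig.desk_scale(seed=0, n_steps=60, batch_size=8)
    model, trace = train(matrix, grouping, config)
    return matrix, grouping, config, trace


class TestTraining:
    def test_initial_loss_near_ln_k(self, small_run):
        _, _, config, trace = small_run
        assert trace[0] == pytest.approx(np.log(config.batch_size), rel=0.2)

    def test_loss_decreases_on_separable_data(self, small_run):
        _, _, _, trace = small_run
        assert np.mean(trace[-10:]) < 0.5 * np.mean(trace[:5])

    def test_same_seed_identical_trace(self, small_run):
        matrix, grouping, config, trace = small_run
        _, trace2 = train(matrix, grouping, config)
        np.testing.assert_array_equal(trace, trace2)

    def test_requires_normalized_matrix(self, tiny_counts, tiny_grouping):
        with pytest.raises(ValueError, match="normalized"):
            train(tiny_counts, tiny_grouping, RunConfig.desk_scale())
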
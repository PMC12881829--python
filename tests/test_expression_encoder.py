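"""Token embedding, transformer invariances, classification head."""

import numpy as np
import pytest

from celltra._autodiff import Tensor, softmax
from celltra.expression_encoder import (ClassifierHead, ExpressionEncoder,
                                        GeneEmbeddingTable,
                                        cross_entropy_logits, embed_gene_set,
                                        train_supervised)
from celltra.io_formats import ExpressionMatrix, PathwayCollection
from celltra.tokenizer import build_grouping


@pytest.fixture()
def encoder(tiny_grouping):
    return ExpressionEncoder(tiny_grouping, dim=8, n_layers=2, n_heads=2,
                             intermediate_dim=16, seed=0)


class TestEmbedGeneSet:
    def test_zero_profile_gives_zero_vector(self):
        rng = np.random.default_rng(0)
        table = GeneEmbeddingTable(4, 3, rng)
        out = embed_gene_set(np.zeros(4), [0, 1, 2], table)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_single_gene_unit_expression_returns_its_row(self):
        rng = np.random.default_rng(0)
        table = GeneEmbeddingTable(4, 3, rng)
        out = embed_gene_set(np.array([0, 1.0, 0, 0]), [1], table)
        np.testing.assert_allclose(out, table.table.data[1])

    def test_hand_computed_average(self):
        # group {g1,g2}, x=(2,0), G1=(1,1), G2=(5,5) -> (2*(1,1)+0)/2 = (1,1)
        rng = np.random.default_rng(0)
        table = GeneEmbeddingTable(2, 2, rng)
        table.table.data[:] = [[1.0, 1.0], [5.0, 5.0]]
        out = embed_gene_set(np.array([2.0, 0.0]), [0, 1], table)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_average_divides_by_full_group_size(self):
        rng = np.random.default_rng(0)
        table = GeneEmbeddingTable(3, 2, rng)
        table.table.data[:] = [[1, 0], [0, 1], [1, 1]]
        # two of three genes silent: denominator is still 3
        out = embed_gene_set(np.array([3.0, 0.0, 0.0]), [0, 1, 2], table)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            embed_gene_set(np.ones(3), [], GeneEmbeddingTable(3, 2, rng))

    def test_linear_in_expression(self):
        rng = np.random.default_rng(1)
        table = GeneEmbeddingTable(5, 4, rng)
        x = rng.random(5)
        a = embed_gene_set(3.0 * x, [0, 2, 4], table)
        b = embed_gene_set(x, [0, 2, 4], table)
        np.testing.assert_allclose(a, 3.0 * b)


class TestTokenSequence:
    def test_cls_prepended(self, encoder, tiny_grouping):
        seq = encoder.token_sequence(np.ones(4)).data
        assert seq.shape == (1, tiny_grouping.n_groups + 1, 8)
        np.testing.assert_array_equal(seq[0, 0], encoder.cls.data[0, 0])

    def test_cls_identical_across_cells(self, encoder):
        seq = encoder.token_sequence(np.vstack([np.ones(4),
                                                2 * np.ones(4)])).data
        np.testing.assert_array_equal(seq[0, 0], seq[1, 0])

    def test_vocabulary_mismatch_rejected(self, encoder):
        with pytest.raises(ValueError, match="genes"):
            encoder.token_sequence(np.ones(7))


class TestEncode:
    def test_deterministic_in_eval_mode(self, encoder):
        x = np.random.default_rng(0).random((3, 4))
        a = encoder.encode_array(x)
        b = encoder.encode_array(x)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 8)

    def test_cls_output_invariant_to_token_permutation(self):
        # no positional encoding: shuffling gene-set tokens must not move
        # the CLS representation
        vocab = [f"G{i}" for i in range(30)]
        coll = PathwayCollection({f"P{k}": vocab[3 * k:3 * k + 3]
                                  for k in range(10)})
        rng = np.random.default_rng(5)
        x = rng.random(30)
        base_grouping = build_grouping(vocab, coll, orphan_set_size=5, seed=0)
        enc = ExpressionEncoder(base_grouping, dim=8, n_layers=2, n_heads=2,
                                intermediate_dim=16, seed=0)
        reference = enc.encode_array(x)[0]
        for trial in range(20):
            perm = rng.permutation(base_grouping.n_groups)
            enc._W = enc._W[perm]  # permute token order only
            out = enc.encode_array(x)[0]
            np.testing.assert_allclose(out, reference, atol=1e-5)

    def test_gradients_reach_every_parameter_family(self, encoder,
                                                    tiny_grouping):
        head = ClassifierHead(8, 3, seed=1)
        x = np.random.default_rng(2).random((4, 4))
        logits = head(encoder.encode(x))
        loss = cross_entropy_logits(logits, np.array([0, 1, 2, 0]))
        loss.backward()
        for p in [encoder.gene_table.table, encoder.cls,
                  encoder.layers[0].attn.wq.W, head.linear.W]:
            assert p.grad is not None
            assert np.any(p.grad != 0)


class TestClassifierHead:
    def test_logit_length_and_softmax_sums(self, encoder):
        head = ClassifierHead(8, 5, seed=0)
        x = np.random.default_rng(0).random((2, 4))
        logits = head(encoder.encode(x))
        assert logits.shape == (2, 5)
        probs = softmax(logits, axis=-1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-9)

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            ClassifierHead(8, 1)

    def test_separable_types_fit_to_perfect_training_accuracy(self):
        # three types with disjoint marker blocks; a tiny encoder + head
        # must fit the training set exactly
        rng = np.random.default_rng(0)
        n_per, n_genes = 20, 12
        vocab = [f"G{i}" for i in range(n_genes)]
        coll = PathwayCollection({"P0": vocab[0:4], "P1": vocab[4:8],
                                  "P2": vocab[8:12]})
        grouping = build_grouping(vocab, coll, orphan_set_size=4, seed=0)
        X, y = [], []
        for t in range(3):
            block = np.full((n_per, n_genes), 0.1)
            block[:, 4 * t:4 * t + 4] = 3.0
            X.append(block + 0.05 * rng.random((n_per, n_genes)))
            y.extend([t] * n_per)
        X = np.vstack(X)
        matrix = ExpressionMatrix(X, vocab,
                                  [f"c{i}" for i in range(len(y))],
                                  state="normalized_log")
        enc = ExpressionEncoder(grouping, dim=16, n_layers=1, n_heads=2,
                                intermediate_dim=32, seed=0)
        head = ClassifierHead(16, 3, seed=0)
        train_supervised(enc, head, matrix, np.array(y), n_steps=150,
                         batch_size=15, lr=5e-3, seed=0,
                         lr_schedule="cosine")
        logits = head(Tensor(enc.encode_array(X))).data
        assert (np.argmax(logits, axis=1) == np.array(y)).mean() == 1.0
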
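"""Synthetic pathway/count generator and the seen/unseen split."""

import dataclasses

import numpy as np
import pytest

from celltra.synthetic_data import (CellTypeSpec, SyntheticSpec,
                                    compositional_names, default_spec,
                                    generate_cells, generate_pathways,
                                    make_split)


class TestGeneratePathways:
    def test_zero_overlap_gives_disjoint_pathways(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=5, genes_per_pathway=10,
                             pathway_overlap_fraction=0.0,
                             orphan_fraction=0.2, seed=0)
        coll = generate_pathways(spec)
        seen = set()
        for _, genes in coll.items():
            assert seen.isdisjoint(genes)
            seen.update(genes)

    def test_orphan_fraction_reserved(self):
        spec = SyntheticSpec(n_genes=1000, n_pathways=4,
                             genes_per_pathway=50,
                             pathway_overlap_fraction=0.0,
                             orphan_fraction=0.5, seed=0)
        coll = generate_pathways(spec)
        assert len(coll.all_genes) <= 500

    def test_consecutive_overlap_fraction(self):
        spec = SyntheticSpec(n_genes=200, n_pathways=4,
                             genes_per_pathway=20,
                             pathway_overlap_fraction=0.2,
                             orphan_fraction=0.1, seed=1)
        coll = generate_pathways(spec)
        ids = sorted(coll.pathways)
        for a, b in zip(ids, ids[1:]):
            shared = set(coll[a]) & set(coll[b])
            assert len(shared) == 4  # 0.2 * 20

    def test_same_seed_identical_collection(self):
        spec = SyntheticSpec(seed=9)
        assert generate_pathways(spec).pathways == \
            generate_pathways(spec).pathways

    def test_infeasible_sizes_rejected(self):
        spec = SyntheticSpec(n_genes=50, n_pathways=10,
                             genes_per_pathway=10,
                             pathway_overlap_fraction=0.0,
                             orphan_fraction=0.5)
        with pytest.raises(ValueError, match="orphan block"):
            generate_pathways(spec)


class TestGenerateCells:
    def test_dropout_one_gives_all_zero_matrix(self):
        spec = default_spec(seed=0)
        spec = dataclasses.replace(spec, dropout_rate=1.0,
                                   n_cells_per_type=3)
        matrix = generate_cells(spec, generate_pathways(spec))
        assert np.all(matrix.values == 0)

    def test_signature_to_background_mean_ratio_near_fold_change(self):
        spec = default_spec(seed=1)
        spec = dataclasses.replace(spec, n_cells_per_type=250,
                                   dropout_rate=0.0, library_size_cv=0.0)
        pathways = generate_pathways(spec)
        matrix = generate_cells(spec, pathways)
        t = spec.cell_types[0]
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        sig = {gene_index[g] for p in t.signature_pathways
               for g in pathways[p]}
        bg_pathways = {g for tt in spec.cell_types
                       for p in tt.signature_pathways for g in pathways[p]}
        bg = [i for g, i in gene_index.items() if g not in bg_pathways]
        cells = matrix.values[np.array(matrix.cell_names) == t.name]
        ratio = cells[:, sorted(sig)].mean() / cells[:, bg].mean()
        assert ratio == pytest.approx(t.fold_change, rel=0.05)

    def test_unit_fold_change_removes_signal(self):
        spec = default_spec(seed=2, fold_change=1.0)
        spec = dataclasses.replace(spec, n_cells_per_type=200,
                                   dropout_rate=0.0, library_size_cv=0.0)
        pathways = generate_pathways(spec)
        matrix = generate_cells(spec, pathways)
        t = spec.cell_types[0]
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        sig = sorted({gene_index[g] for p in t.signature_pathways
                      for g in pathways[p]})
        cells = matrix.values[np.array(matrix.cell_names) == t.name]
        others = matrix.values[np.array(matrix.cell_names) != t.name]
        # signature genes are no longer elevated relative to other types
        ratio = cells[:, sig].mean() / others[:, sig].mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_generator_determinism_byte_identical(self):
        spec = default_spec(seed=3)
        spec = dataclasses.replace(spec, n_cells_per_type=5)
        pathways = generate_pathways(spec)
        a = generate_cells(spec, pathways)
        b = generate_cells(spec, pathways)
        assert a.values.tobytes() == b.values.tobytes()
        assert a.cell_names == b.cell_names

    def test_state_is_raw_counts(self):
        spec = dataclasses.replace(default_spec(seed=0), n_cells_per_type=2)
        matrix = generate_cells(spec, generate_pathways(spec))
        assert matrix.state == "raw_counts"


class TestSpecValidation:
    def test_unseen_type_with_novel_token_rejected(self):
        types = [CellTypeSpec("alpha helper cell", ["P00"]),
                 CellTypeSpec("weird novel cell", ["P01"])]
        with pytest.raises(ValueError, match="zero-shot"):
            SyntheticSpec(cell_types=types,
                          unseen_types=["weird novel cell"])

    def test_unseen_from_seen_tokens_accepted(self):
        types = [CellTypeSpec("alpha helper cell", ["P00"]),
                 CellTypeSpec("beta killer cell", ["P01"]),
                 CellTypeSpec("alpha killer cell", ["P02"])]
        spec = SyntheticSpec(cell_types=types,
                             unseen_types=["alpha killer cell"])
        assert spec.seen_types == ["alpha helper cell", "beta killer cell"]

    def test_fold_change_below_one_rejected(self):
        with pytest.raises(ValueError, match="fold_change"):
            SyntheticSpec(cell_types=[CellTypeSpec("a cell", [], 0.5)])


class TestMakeSplit:
    def _matrix(self, spec):
        return generate_cells(spec, generate_pathways(spec))

    def test_unseen_cells_all_in_test(self):
        spec = dataclasses.replace(default_spec(seed=0), n_cells_per_type=10)
        matrix = self._matrix(spec)
        split = make_split(spec, matrix)
        names = np.array(matrix.cell_names)
        for unseen in spec.unseen_types:
            idx = np.flatnonzero(names == unseen)
            assert set(idx).issubset(set(split.test_idx.tolist()))

    def test_seen_ratio_within_one_cell_per_type(self):
        spec = dataclasses.replace(default_spec(seed=1), n_cells_per_type=37)
        matrix = self._matrix(spec)
        split = make_split(spec, matrix)
        names = np.array(matrix.cell_names)
        for t in spec.seen_types:
            idx = set(np.flatnonzero(names == t).tolist())
            n_train = len(idx & set(split.train_idx.tolist()))
            n_val = len(idx & set(split.val_idx.tolist()))
            n_test = len(idx & set(split.test_idx.tolist()))
            assert n_train + n_val + n_test == 37
            assert abs(n_train - 0.7 * 37) <= 1
            assert abs(n_val - 0.1 * 37) <= 1
            assert abs(n_test - 0.2 * 37) <= 1

    def test_no_unseen_types_plain_ratio_split(self):
        spec = dataclasses.replace(default_spec(seed=2), unseen_types=[],
                                   n_cells_per_type=20)
        matrix = self._matrix(spec)
        split = make_split(spec, matrix)
        assert split.unseen_types == []
        assert len(split.train_idx) + len(split.val_idx) + \
            len(split.test_idx) == matrix.n_cells

    def test_tiny_seen_type_goes_to_train_with_warning(self):
        types = [CellTypeSpec("alpha helper cell", ["P00"]),
                 CellTypeSpec("beta helper cell", ["P01"])]
        spec = SyntheticSpec(n_genes=60, n_pathways=4, genes_per_pathway=8,
                             orphan_fraction=0.2, cell_types=types,
                             n_cells_per_type=2, seed=0)
        matrix = self._matrix(spec)
        with pytest.warns(UserWarning, match="assigning all to train"):
            split = make_split(spec, matrix)
        assert len(split.train_idx) == matrix.n_cells

    def test_split_is_deterministic(self):
        spec = dataclasses.replace(default_spec(seed=3), n_cells_per_type=11)
        matrix = self._matrix(spec)
        a = make_split(spec, matrix)
        b = make_split(spec, matrix)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)


def test_compositional_names_grid():
    names = compositional_names(17, 8)
    assert len(names) == 136
    assert len(set(names)) == 136
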
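"""Loading, standardization, Dudoit preprocessing and the Fisher prescreen."""

import numpy as np
import pytest

from kernelselect import (
    ExpressionDataset,
    dudoit_preprocess,
    fisher_prescreen,
    load_expression_matrix,
    load_mat_dataset,
    standardize_rows_then_columns,
)
from kernelselect.datasets import (
    DimensionError,
    LabelError,
    ParseError,
    ZeroVarianceError,
    recode_labels,
)

from _oracles import oracle_two_pass_zscore


class TestLoading:
    def test_first_seen_label_becomes_positive(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,label,g1,g2\ns1,A,1,2\ns2,A,3,4\ns3,B,5,7\n")
        ds = load_expression_matrix(path, label_source="label")
        assert ds.labels.tolist() == [1, 1, -1]
        assert ds.gene_ids == ["g1", "g2"]
        assert ds.values.shape == (3, 2)

    def test_genes_in_rows_orientation(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("id\ts1\ts2\ts3\ng1\t1\t3\t5\ng2\t2\t4\t7\n")
        ds = load_expression_matrix(
            path, orientation="genes_in_rows", labels=["x", "x", "y"]
        )
        assert ds.values.shape == (3, 2)
        assert ds.values[2].tolist() == [5.0, 7.0]

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,label,g1,g2\ns1,A,1,2\ns2,B,oops,4\n")
        with pytest.raises(ParseError, match="s2.*g1"):
            load_expression_matrix(path, label_source="label")

    def test_more_than_two_classes_rejected(self):
        with pytest.raises(LabelError, match="3"):
            recode_labels(["A", "B", "C"])

    def test_label_length_mismatch(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("id,g1\ns1,1\ns2,2\ns3,4\n")
        with pytest.raises(LabelError):
            load_expression_matrix(path, labels=["A", "B"])

    def test_mat_roundtrip(self, tmp_path):
        from scipy.io import savemat

        values = np.arange(12.0).reshape(4, 3)
        labels = np.array([1, 1, 2, 2])
        path = tmp_path / "d.mat"
        savemat(path, {"X": values, "Y": labels})
        ds = load_mat_dataset(path)
        assert ds.values.shape == (4, 3)
        assert ds.labels.tolist() == [1, 1, -1, -1]


class TestValidation:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionDataset(
                values=np.array([[1.0, np.nan], [2.0, 3.0]]),
                labels=np.array([1, -1]),
            )

    def test_gene_id_mismatch(self):
        with pytest.raises(DimensionError):
            ExpressionDataset(
                values=np.ones((2, 3)), labels=np.array([1, -1]), gene_ids=["a"]
            )


class TestStandardize:
    def test_matches_independent_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            matrix = rng.standard_normal((5, 4)) * 3 + 1
            ds = ExpressionDataset(
                values=matrix, labels=np.array([1, 1, 1, -1, -1])
            )
            got = standardize_rows_then_columns(ds).values
            np.testing.assert_allclose(got, oracle_two_pass_zscore(matrix), atol=1e-12)

    def test_fixed_2x2_matches_oracle(self):
        matrix = [[1.0, 2.0], [4.0, 3.0]]
        ds = ExpressionDataset(values=np.array(matrix), labels=np.array([1, -1]))
        np.testing.assert_allclose(
            standardize_rows_then_columns(ds).values,
            oracle_two_pass_zscore(matrix),
            atol=1e-12,
        )

    def test_output_columns_standardized(self):
        rng = np.random.default_rng(1)
        ds = ExpressionDataset(
            values=rng.standard_normal((8, 5)) * 7 - 2,
            labels=np.array([1] * 4 + [-1] * 4),
        )
        out = standardize_rows_then_columns(ds).values
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_gene_column_raises(self):
        # identical increasing rows -> constant columns after the row pass
        values = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        ds = ExpressionDataset(values=values, labels=np.array([1, 1, -1]))
        with pytest.raises(ZeroVarianceError, match="column"):
            standardize_rows_then_columns(ds)


class TestDudoit:
    def _toy(self):
        # 3 samples x 4 genes; genes 1 and 3 violate the filters
        values = np.array(
            [
                [50.0, 120.0, 300.0, 7000.0],
                [2000.0, 180.0, 4000.0, 7400.0],
                [18000.0, 140.0, 900.0, 7600.0],
            ]
        )
        return ExpressionDataset(values=values, labels=np.array([1, 1, -1]))

    def test_toy_matches_arithmetic_oracle(self):
        ds = self._toy()
        out = dudoit_preprocess(ds)
        # independent per-gene check with plain arithmetic
        clamped = np.clip(ds.values, 100, 16000)
        keep = []
        for g in range(4):
            col = clamped[:, g]
            if col.max() / col.min() > 5 and col.max() - col.min() > 500:
                keep.append(g)
        assert keep == [0, 2]
        assert out.gene_ids == [ds.gene_ids[g] for g in keep]
        np.testing.assert_allclose(out.values, np.log10(clamped[:, keep]), atol=1e-12)

    def test_low_ratio_gene_removed(self):
        values = np.array([[50.0, 1000.0], [200.0, 8000.0]])
        ds = ExpressionDataset(values=values, labels=np.array([1, -1]))
        out = dudoit_preprocess(ds)
        # gene 0 clamps to {100, 200}: ratio 2 <= 5 -> dropped
        assert out.gene_ids == ["g1"]

    def test_filter_is_idempotent_on_survivors(self):
        ds = self._toy()
        clamped = np.clip(ds.values, 100, 16000)
        survivors = dudoit_preprocess(ds)
        # re-applying the filter predicate to surviving (clamped) genes
        # removes nothing
        kept = [ds.gene_ids.index(g) for g in survivors.gene_ids]
        for g in kept:
            col = clamped[:, g]
            assert col.max() / col.min() > 5 and col.max() - col.min() > 500


class TestFisherPrescreen:
    def _ds(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((10, 6))
        labels = np.array([1] * 5 + [-1] * 5)
        values[:5, 2] += 5.0  # gene 2 clearly top
        return ExpressionDataset(values=values, labels=labels)

    def test_identity_when_k_equals_m(self):
        ds = self._ds()
        out = fisher_prescreen(ds, ds.n_genes)
        assert out.gene_ids == ds.gene_ids

    def test_top_gene_retained(self):
        out = fisher_prescreen(self._ds(), 1)
        assert out.gene_ids == ["g2"]

    def test_tie_goes_to_lower_index(self):
        values = np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0], [-2.0, -2.0]])
        ds = ExpressionDataset(values=values, labels=np.array([1, 1, -1, -1]))
        out = fisher_prescreen(ds, 1)
        assert out.gene_ids == ["g0"]

    def test_k_too_large_raises(self):
        with pytest.raises(DimensionError):
            fisher_prescreen(self._ds(), 7)

    def test_nested_for_increasing_k(self):
        ds = self._ds()
        g3 = set(fisher_prescreen(ds, 3).gene_ids)
        g5 = set(fisher_prescreen(ds, 5).gene_ids)
        assert g3 <= g5
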
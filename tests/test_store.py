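"""Unified table: insertion, projection, distinct values, persistence."""

import numpy as np
import pytest
import scipy.sparse as sp

import cellensemble as ce


def _meta(n, **overrides):
    base = {"organ": "Heart", "cell_type": "T cell"}
    return [dict(base, cell_id=f"c{i}", **overrides) for i in range(n)]


class TestInsert:
    def test_contiguous_cids_from_empty(self):
        table = ce.UnifiedTable(["A", "B", "C"])
        table.insert_cells(np.zeros((3, 3)), _meta(3))
        assert table.get_all_rows() == [0, 1, 2]

    def test_offset_continuation(self):
        table = ce.UnifiedTable(["A"])
        table.insert_cells(np.zeros((5, 1)), _meta(5))
        table.insert_cells(np.ones((2, 1)), _meta(2))
        assert table.get_all_rows() == [0, 1, 2, 3, 4, 5, 6]
        assert table.metadata.index.tolist() == list(range(7))

    def test_gene_axis_mismatch(self):
        table = ce.UnifiedTable(["A", "B", "C", "D", "E"])
        with pytest.raises(ce.SchemaError):
            table.insert_cells(np.zeros((2, 4)), _meta(2))

    def test_unknown_metadata_field(self):
        table = ce.UnifiedTable(["A"])
        with pytest.raises(ce.SchemaError):
            table.insert_cells(np.zeros((1, 1)), [{"not_a_field": "x"}])

    def test_record_count_mismatch(self):
        table = ce.UnifiedTable(["A"])
        with pytest.raises(ce.SchemaError):
            table.insert_cells(np.zeros((2, 1)), _meta(1))

    def test_negative_values_rejected(self):
        table = ce.UnifiedTable(["A"])
        with pytest.raises(ce.SchemaError):
            table.insert_cells(np.array([[-1.0]]), _meta(1))

    def test_missing_fields_become_empty_strings(self):
        table = ce.UnifiedTable(["A"])
        table.insert_cells(np.zeros((1, 1)), [{"organ": "Lung"}])
        assert table.metadata.loc[0, "donor_age"] == ""
        assert list(table.metadata.columns) == list(ce.METADATA_FIELDS)


class TestFetch:
    def test_projection(self, five_cell_table):
        out = five_cell_table.fetch(rows=[0, 1], cols=["PTPRC"])
        assert out.shape == (2, 1)
        assert out.index.tolist() == [0, 1]
        np.testing.assert_allclose(out["PTPRC"], [1.0, 0.2])

    def test_gene_threshold_filter_matches_listed_values(self, five_cell_table):
        # CD3D = (0.7, 0.9, 0.1, 0.5, 0.0); threshold 0.5 keeps rows 0, 1, 3
        out = five_cell_table.fetch(cols=["CD3D"], row_filter="CD3D>=0.5")
        assert out.index.tolist() == [0, 1, 3]

    def test_unknown_column(self, five_cell_table):
        with pytest.raises(ce.ColumnError):
            five_cell_table.fetch(cols=["NOT_A_GENE"])

    def test_mixed_columns_carry_types(self, five_cell_table):
        out = five_cell_table.fetch(cols=["organ", "CD3D"])
        assert out["organ"].dtype == object
        assert out["CD3D"].dtype == np.float64

    def test_all_columns(self, five_cell_table):
        out = five_cell_table.fetch()
        assert out.shape == (5, len(ce.METADATA_FIELDS) + 2)


class TestGetColumnSet:
    def test_distinct_organs(self, five_cell_table):
        assert five_cell_table.get_column_set([0, 1, 2], "organ") == {"Heart", "Lung"}

    def test_empty_rows(self, five_cell_table):
        assert five_cell_table.get_column_set([], "organ") == set()

    def test_constant_column_is_singleton(self, five_cell_table):
        assert five_cell_table.get_column_set(None, "sample_status") == {""}

    def test_unknown_column(self, five_cell_table):
        with pytest.raises(ce.ColumnError):
            five_cell_table.get_column_set([0], "nope")


class TestPersistence:
    def test_round_trip_random_tables(self, tmp_path):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n, g = int(rng.integers(1, 15)), int(rng.integers(1, 25))
            values = sp.random(n, g, density=0.4, random_state=int(rng.integers(2**31)))
            meta = [
                {"organ": f"O{rng.integers(3)}", "donor_age": str(rng.integers(90)),
                 "original_name": 'quoted, "tricky" value'}
                for _ in range(n)
            ]
            table = ce.UnifiedTable([f"G{j}" for j in range(g)], values, meta)
            path = tmp_path / f"atlas{trial}"
            ce.save_atlas(table, path)
            assert ce.load_atlas(path) == table

    def test_round_trip_empty_table(self, tmp_path):
        table = ce.UnifiedTable(["A", "B"])
        ce.save_atlas(table, tmp_path / "empty")
        loaded = ce.load_atlas(tmp_path / "empty")
        assert loaded == table and loaded.n_cells == 0

    def test_row_count_mismatch_is_format_error(self, tmp_path, five_cell_table):
        path = tmp_path / "broken"
        ce.save_atlas(five_cell_table, path)
        (path / "rows.txt").write_text("0\n1\n")
        with pytest.raises(ce.FormatError, match="rows.txt"):
            ce.load_atlas(path)

    def test_missing_file_is_format_error(self, tmp_path, five_cell_table):
        path = tmp_path / "missing"
        ce.save_atlas(five_cell_table, path)
        (path / "matrix.mtx").unlink()
        with pytest.raises(ce.FormatError, match="matrix.mtx"):
            ce.load_atlas(path)

    def test_cids_stable_under_save_load(self, tmp_path, five_cell_table):
        path = tmp_path / "stable"
        ce.save_atlas(five_cell_table, path)
        loaded = ce.load_atlas(path)
        assert loaded.get_all_rows() == five_cell_table.get_all_rows()
        out = loaded.fetch(rows=[1, 3], cols=["organ"])
        assert out.index.tolist() == [1, 3]


def test_to_anndata_mirrors_table(five_cell_table):
    adata = five_cell_table.to_anndata()
    assert adata.shape == (5, 2)
    assert list(adata.var_names) == ["PTPRC", "CD3D"]
    np.testing.assert_allclose(
        np.asarray(adata.X.todense()), five_cell_table.values.toarray()
    )


def test_duplicate_gene_axis_rejected():
    with pytest.raises(ce.SchemaError):
        ce.UnifiedTable(["A", "A"])
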
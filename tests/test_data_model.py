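"""Expression I/O, series construction and gene quality filtering."""

import numpy as np
import pandas as pd
import pytest

from dtwscore import (
    CellMetadata,
    GeneTimeSeries,
    build_cell_series,
    filter_low_quality_genes,
    read_expression_table,
    write_expression_table,
)
from dtwscore.exceptions import EmptyResultError, ValidationError

from conftest import make_set


class TestGeneTimeSeries:
    def test_valid(self):
        ts = GeneTimeSeries("g", "c", [0, 1, 2], [1.0, 0.0, 3.5])
        assert len(ts) == 3

    @pytest.mark.parametrize(
        "times, values, msg",
        [
            ([0, 1], [1.0], "times but"),
            ([1, 0], [1.0, 2.0], "strictly increasing"),
            ([0, 0], [1.0, 2.0], "strictly increasing"),
            ([0, 1], [1.0, -2.0], "negative"),
            ([0, 1], [1.0, np.inf], "non-finite"),
            ([], [], "empty"),
        ],
    )
    def test_invalid(self, times, values, msg):
        with pytest.raises(ValidationError, match=msg):
            GeneTimeSeries("g", "c", times, values)


class TestReadWrite:
    def test_round_trip(self, tiny_matrix_files, tmp_path):
        mpath, mdpath, matrix, _ = tiny_matrix_files
        sset = read_expression_table(mpath, mdpath)
        assert sset.n_genes == 2 and sset.n_cells == 2
        out_m, out_md = tmp_path / "out.csv", tmp_path / "out_meta.csv"
        write_expression_table(sset, out_m, out_md)
        again = read_expression_table(out_m, out_md)
        assert again.gene_ids == sset.gene_ids
        assert again.cell_ids == sset.cell_ids
        for key, ts in sset.series.items():
            np.testing.assert_array_equal(again.series[key].values, ts.values)

    def test_tsv_autodetect_and_gzip(self, tiny_matrix_files, tmp_path):
        mpath, mdpath, matrix, _ = tiny_matrix_files
        tsv = tmp_path / "m.tsv.gz"
        matrix.to_csv(tsv, sep="\t", compression="gzip")
        sset = read_expression_table(tsv, mdpath)
        assert sset.n_genes == 2

    def test_mtx_input(self, tiny_matrix_files, tmp_path):
        import scipy.io, scipy.sparse

        mpath, mdpath, matrix, _ = tiny_matrix_files
        mtx = tmp_path / "m.mtx"
        scipy.io.mmwrite(str(mtx), scipy.sparse.coo_matrix(matrix.to_numpy()))
        (tmp_path / "m.genes.txt").write_text("\n".join(matrix.index))
        (tmp_path / "m.cells.txt").write_text("\n".join(matrix.columns))
        sset = read_expression_table(mtx, mdpath)
        np.testing.assert_array_equal(
            sset.series[("geneA", "c1")].values, [1.0, 2.0]
        )

    def test_negative_value_names_offender(self, tiny_matrix_files, tmp_path):
        mpath, mdpath, matrix, _ = tiny_matrix_files
        bad = matrix.copy()
        bad.loc["geneB", "c2t0"] = -1.0
        bpath = tmp_path / "bad.csv"
        bad.to_csv(bpath)
        with pytest.raises(ValidationError, match="geneB.*c2t0"):
            read_expression_table(bpath, mdpath)

    def test_missing_metadata_lists_cell(self, tiny_matrix_files, tmp_path):
        mpath, mdpath, _, meta = tiny_matrix_files
        short = meta.iloc[:-1]
        spath = tmp_path / "short.csv"
        short.to_csv(spath, index=False)
        with pytest.raises(ValidationError, match="c2t1"):
            read_expression_table(mpath, spath)

    def test_empty_file_rejected(self, tmp_path, tiny_matrix_files):
        _, mdpath, _, _ = tiny_matrix_files
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        with pytest.raises(ValidationError, match="empty"):
            read_expression_table(empty, mdpath)

    def test_log1p_flag(self, tiny_matrix_files):
        mpath, mdpath, matrix, _ = tiny_matrix_files
        sset = read_expression_table(mpath, mdpath, log1p=True)
        np.testing.assert_allclose(
            sset.series[("geneA", "c1")].values, np.log1p([1.0, 2.0])
        )


class TestBuildCellSeries:
    def _matrix_meta(self):
        matrix = pd.DataFrame(
            {"a": [1.0], "b": [2.0], "c": [3.0], "d": [4.0]}, index=["g1"]
        )
        meta = [
            CellMetadata("a", 48.0, "grp"),
            CellMetadata("b", 0.0, "grp"),
            CellMetadata("c", 72.0, "grp"),
            CellMetadata("d", 24.0, "grp"),
        ]
        return matrix, meta

    def test_per_cell_series_verbatim(self, tiny_matrix_files):
        mpath, mdpath, _, _ = tiny_matrix_files
        sset = read_expression_table(mpath, mdpath, pairing="per_cell_series")
        assert len(sset.series[("geneA", "c1")]) == 2
        assert len(sset.series[("geneA", "c2")]) == 2
        assert sset.group_of_cell == {"c1": "p1", "c2": "p2"}

    def test_ordered_within_group_sorts_by_time(self):
        matrix, meta = self._matrix_meta()
        # second pseudo-cell so the 2-cell minimum holds
        matrix["e"] = [9.0]
        meta = meta + [CellMetadata("e", 0.0, "grp2")]
        sset = build_cell_series(matrix, meta, pairing="ordered_within_group")
        np.testing.assert_array_equal(
            sset.series[("g1", "grp")].values, [2.0, 4.0, 1.0, 3.0]
        )  # times 0,24,48,72 -> columns b,d,a,c

    def test_tie_broken_by_cell_id(self):
        matrix = pd.DataFrame({"x2": [5.0], "x1": [6.0], "y": [0.0]}, index=["g"])
        meta = [
            CellMetadata("x2", 0.0, "G"),
            CellMetadata("x1", 0.0, "G"),
            CellMetadata("y", 0.0, "H"),
        ]
        sset = build_cell_series(matrix, meta, pairing="ordered_within_group")
        np.testing.assert_array_equal(sset.series[("g", "G")].values, [6.0, 5.0])

    def test_unknown_strategy(self):
        matrix, meta = self._matrix_meta()
        with pytest.raises(ValidationError, match="pairing"):
            build_cell_series(matrix, meta, pairing="zigzag")


class TestFilter:
    def _set_with_fraction(self, n_pos, n_cells=10):
        vals = {}
        for i in range(n_cells):
            v = 1.0 if i < n_pos else 0.0
            vals[f"cell{i:02d}"] = {"g_test": [v, v], "g_keep": [1.0, 2.0]}
        return make_set(vals)

    def test_boundary_inclusive(self):
        sset = filter_low_quality_genes(self._set_with_fraction(8), 0.8)
        assert "g_test" in sset.gene_ids

    def test_below_boundary_removed(self):
        sset = filter_low_quality_genes(self._set_with_fraction(7), 0.8)
        assert sset.gene_ids == ["g_keep"]
        assert sset.n_cells == 10  # cells unchanged

    def test_all_positive_identity(self):
        base = self._set_with_fraction(10)
        out = filter_low_quality_genes(base, 0.8)
        assert out.gene_ids == base.gene_ids

    def test_idempotent_and_monotone(self):
        base = self._set_with_fraction(6)
        once = filter_low_quality_genes(base, 0.5)
        twice = filter_low_quality_genes(once, 0.5)
        assert once.gene_ids == twice.gene_ids
        low = filter_low_quality_genes(base, 0.3)
        assert set(once.gene_ids) <= set(low.gene_ids)

    def test_input_not_modified(self):
        base = self._set_with_fraction(7)
        filter_low_quality_genes(base, 0.5)
        assert "g_test" in base.gene_ids

    def test_empty_result_error(self):
        vals = {"c1": {"g": [0.0]}, "c2": {"g": [0.0]}}
        with pytest.raises(EmptyResultError, match="lower"):
            filter_low_quality_genes(make_set(vals), 0.8)
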
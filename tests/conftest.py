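import numpy as np
import pandas as pd
import pytest

from dtwscore import build_cell_series, CellMetadata, condition_preset, simulate_dataset


@pytest.fixture
def tiny_matrix_files(tmp_path):
    """2 genes x 4 single-time columns (two cells x two times) on disk."""
    matrix = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 5.0, 0.0, 7.0]],
        index=["geneA", "geneB"],
        columns=["c1t0", "c1t1", "c2t0", "c2t1"],
    )
    meta = pd.DataFrame(
        {
            "cell_id": ["c1t0", "c1t1", "c2t0", "c2t1"],
            "time": [0.0, 24.0, 0.0, 24.0],
            "group": ["p1", "p1", "p2", "p2"],
            "cell": ["c1", "c1", "c2", "c2"],
        }
    )
    mpath = tmp_path / "matrix.csv"
    mdpath = tmp_path / "meta.csv"
    matrix.to_csv(mpath)
    meta.to_csv(mdpath, index=False)
    return mpath, mdpath, matrix, meta


def make_set(values, times=None, groups=None):
    """Build a small ExpressionSeriesSet from {cell: {gene: [v,...]}}."""
    cells = sorted(values)
    genes = sorted(values[cells[0]])
    meta = []
    cols = {}
    for cell in cells:
        n = len(values[cell][genes[0]])
        for j in range(n):
            cid = f"{cell}_{j}"
            meta.append(
                CellMetadata(
                    cell_id=cid,
                    time_label=float(times[cell][j] if times else j),
                    group=(groups or {}).get(cell, cell),
                    cell=cell,
                )
            )
            cols[cid] = [values[cell][g][j] for g in genes]
    matrix = pd.DataFrame(cols, index=genes)
    return build_cell_series(matrix, meta, pairing="per_cell_series")


@pytest.fixture
def two_identical_cells():
    vals = {"cellA": {"g1": [1.0, 2.0, 3.0]}, "cellB": {"g1": [1.0, 2.0, 3.0]}}
    return make_set(vals)


@pytest.fixture(scope="session")
def small_condition1():
    """Scaled-down condition-1 dataset reused across tests."""
    cfg = condition_preset(1, n_genes_same=60, n_genes_diff=60, seed=42)
    return simulate_dataset(cfg)
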
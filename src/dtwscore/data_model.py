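"""Domain types and expression-matrix I/O.

The central container is :class:`ExpressionSeriesSet`: for every gene and
every cell it stores an ordered time series of non-negative, FPKM-scale
expression values.  Input is a dense delimited-text matrix (genes as rows,
cells/observations as columns) or a Matrix Market sparse triplet with
companion id files, plus a cell metadata table mapping each matrix column
to a time label and a group (time-period) label.

Quality filtering follows the usual single-cell convention of keeping only
genes expressed (strictly positive in at least one time point) in at least
a given fraction of cells — 80% by default.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import EmptyResultError, ValidationError

__all__ = [
    "GeneTimeSeries",
    "CellMetadata",
    "ExpressionSeriesSet",
    "read_expression_table",
    "read_metadata",
    "build_cell_series",
    "filter_low_quality_genes",
    "write_expression_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTimeSeries:
    """Expression of one gene in one cell, ordered by time.

    Attributes
    ----------
    gene_id, cell_id
        Identifiers of the gene and the cell the series belongs to.
    times
        Strictly increasing time labels (real units or ordinal ranks).
    values
        Non-negative expression values (FPKM scale), one per time point.
    """

    gene_id: str
    cell_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValidationError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValidationError(
                f"gene {self.gene_id!r} cell {self.cell_id!r}: "
                f"{len(times)} times but {len(values)} values"
            )
        if len(times) < 1:
            raise ValidationError(
                f"gene {self.gene_id!r} cell {self.cell_id!r}: empty series"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise ValidationError(
                f"gene {self.gene_id!r} cell {self.cell_id!r}: non-finite entry"
            )
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"gene {self.gene_id!r} cell {self.cell_id!r}: "
                "times must be strictly increasing"
            )
        if np.any(values < 0):
            raise ValidationError(
                f"gene {self.gene_id!r} cell {self.cell_id!r}: negative value"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CellMetadata:
    """One observation (matrix column): its id, time, group and owning cell.

    ``cell_id`` is the matrix column header.  ``cell`` optionally names the
    physical cell the column belongs to when one cell was observed at
    several times (several columns); when absent the column is its own
    cell.  ``group`` is the group/time-period label used for cross-group
    scoring.
    """

    cell_id: str
    time_label: float
    group: str
    known_type: str | None = None
    cell: str | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValidationError(f"cell {self.cell_id!r}: empty group label")


@dataclass
class ExpressionSeriesSet:
    """Per-gene, per-cell expression time series with group labels.

    Invariants checked at construction: at least two cells, every listed
    (gene, cell) pair has a valid series, and a cell's time grid is the
    same for all genes of that cell.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    group_of_cell: dict[str, str]
    series: dict[tuple[str, str], GeneTimeSeries]
    known_type_of_cell: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cell_ids) < 2:
            raise ValidationError("an ExpressionSeriesSet needs at least 2 cells")
        missing = [c for c in self.cell_ids if c not in self.group_of_cell]
        if missing:
            raise ValidationError(f"cells without group label: {missing}")
        grids: dict[str, np.ndarray] = {}
        for gene in self.gene_ids:
            for cell in self.cell_ids:
                ts = self.series.get((gene, cell))
                if ts is None:
                    raise ValidationError(f"missing series for gene {gene!r}, cell {cell!r}")
                if cell in grids:
                    if not np.array_equal(grids[cell], ts.times):
                        raise ValidationError(
                            f"cell {cell!r}: time grid differs between genes"
                        )
                else:
                    grids[cell] = ts.times

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def get(self, gene_id: str, cell_id: str) -> GeneTimeSeries:
        return self.series[(gene_id, cell_id)]

    def values_matrix(self) -> pd.DataFrame:
        """Flatten back to a dense genes x (cell, time) table.

        Columns are labelled ``<cell_id>@<time>`` when a cell carries more
        than one time point, or just ``<cell_id>`` for single-point cells.
        """
        cols: dict[str, np.ndarray] = {}
        for cell in self.cell_ids:
            grid = self.series[(self.gene_ids[0], cell)].times
            for j, t in enumerate(grid):
                name = cell if len(grid) == 1 else f"{cell}@{t:g}"
                cols[name] = np.array(
                    [self.series[(g, cell)].values[j] for g in self.gene_ids]
                )
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene_id"))

    def subset_genes(self, keep: Iterable[str]) -> "ExpressionSeriesSet":
        keep = [g for g in self.gene_ids if g in set(keep)]
        return ExpressionSeriesSet(
            gene_ids=keep,
            cell_ids=list(self.cell_ids),
            group_of_cell=dict(self.group_of_cell),
            series={
                (g, c): self.series[(g, c)] for g in keep for c in self.cell_ids
            },
            known_type_of_cell=dict(self.known_type_of_cell),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma vs tab; gzip ok."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        head = fh.read(65536)
    if not head.strip():
        raise ValidationError(f"{path}: empty file")
    first_line = head.splitlines()[0]
    sep = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_metadata(path: str | Path) -> list[CellMetadata]:
    """Read a cell metadata table with columns cell_id, time, group[, known_type]."""
    path = Path(path)
    df = _read_delimited(path).reset_index()
    required = {"cell_id", "time", "group"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: metadata needs columns cell_id, time, group "
            f"(found {list(df.columns)})"
        )
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"{path}: duplicate cell_id entries {dupes}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CellMetadata(
                cell_id=str(row["cell_id"]),
                time_label=float(row["time"]),
                group=str(row["group"]),
                known_type=(
                    str(row["known_type"])
                    if "known_type" in df.columns and pd.notna(row["known_type"])
                    else None
                ),
                cell=(
                    str(row["cell"])
                    if "cell" in df.columns and pd.notna(row["cell"])
                    else None
                ),
            )
        )
    return out


def _read_matrix(path: Path) -> pd.DataFrame:
    """Read a genes x columns matrix: dense delimited text or MTX triplet.

    For MTX input, companion ``<stem>.genes.txt`` and ``<stem>.cells.txt``
    id files (one id per line) must sit next to the matrix file.
    """
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = (path.parent / (path.stem + ".genes.txt")).read_text().split()
        cells = (path.parent / (path.stem + ".cells.txt")).read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(genes)} gene ids x {len(cells)} cell ids"
            )
        return pd.DataFrame(dense, index=genes, columns=cells)
    return _read_delimited(path)


def _validate_matrix(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene, cell = next(
            (g, c) for g in df.index for c in df.columns if bad.at[g, c]
        )
        raise ValidationError(
            f"{origin}: non-numeric value at gene {gene!r}, cell {cell!r}"
        )
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValidationError(f"{origin}: missing value in gene {gene!r}")
    arr = numeric.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{origin}: non-finite value in matrix")
    if (arr < 0).any():
        gi, ci = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{origin}: negative value {arr[gi, ci]} at gene "
            f"{numeric.index[gi]!r}, cell {numeric.columns[ci]!r}"
        )
    return numeric.astype(float)


def read_expression_table(
    path: str | Path,
    metadata_path: str | Path,
    *,
    pairing: str = "per_cell_series",
    log1p: bool = False,
) -> ExpressionSeriesSet:
    """Read an expression matrix + metadata into an :class:`ExpressionSeriesSet`.

    Parameters
    ----------
    path
        Dense CSV/TSV (genes as rows, header row of column/cell ids;
        ``.gz`` accepted) or ``.mtx`` sparse matrix with companion id files.
    metadata_path
        Delimited table with columns ``cell_id, time, group[, known_type]``,
        one row per matrix column.
    pairing
        How matrix columns are assembled into per-cell series; see
        :func:`build_cell_series`.
    log1p
        Apply ``log(1 + x)`` to values after validation.  Off by default:
        scores are defined on the FPKM scale.
    """
    df = _validate_matrix(_read_matrix(Path(path)), str(path))
    meta = read_metadata(metadata_path)
    if log1p:
        df = np.log1p(df)
    return build_cell_series(df, meta, pairing=pairing)


def build_cell_series(
    matrix: pd.DataFrame,
    metadata: Sequence[CellMetadata],
    pairing: str = "per_cell_series",
) -> ExpressionSeriesSet:
    """Assemble per-cell time series from a genes x columns table.

    Two strategies are supported because single-cell time-course designs
    differ in whether a physical cell is observed repeatedly:

    ``per_cell_series``
        Matrix columns already belong to multi-time cells: the metadata
        ``cell`` field names the owning cell of each column (a column with
        no ``cell`` entry is its own single-time cell).  A cell's columns,
        ordered by time label, form its series verbatim; time labels within
        a cell must be distinct, and all of a cell's columns must share one
        ``group``.

    ``ordered_within_group``
        Each column is a single-time observation of a distinct cell (the
        cross-sectional design where every cell is captured once).  Within
        each group, observations are sorted by time label — ties broken by
        cell_id lexicographic order — and concatenated into one
        pseudo-series per group; the pseudo-series is re-timed on an
        ordinal 0..n-1 grid so tied time labels remain valid.
    """
    by_id = {m.cell_id: m for m in metadata}
    unmapped = [c for c in matrix.columns if str(c) not in by_id]
    if unmapped:
        raise ValidationError(f"metadata missing for cells: {unmapped}")

    if pairing not in ("per_cell_series", "ordered_within_group"):
        raise ValidationError(
            f"unknown pairing strategy {pairing!r}; expected "
            "'per_cell_series' or 'ordered_within_group'"
        )

    gene_ids = [str(g) for g in matrix.index]
    # Bucket columns by owning cell.
    buckets: dict[str, list[CellMetadata]] = {}
    for col in matrix.columns:
        m = by_id[str(col)]
        if pairing == "per_cell_series":
            owner = m.cell if m.cell is not None else m.cell_id
        else:
            owner = m.group
        buckets.setdefault(owner, []).append(m)

    series: dict[tuple[str, str], GeneTimeSeries] = {}
    group_of_cell: dict[str, str] = {}
    known: dict[str, str] = {}
    cell_ids: list[str] = []
    for owner, members in buckets.items():
        members = sorted(members, key=lambda m: (m.time_label, m.cell_id))
        cols = [m.cell_id for m in members]
        times = np.array([m.time_label for m in members], dtype=float)
        groups = {m.group for m in members}
        if len(groups) != 1:
            raise ValidationError(
                f"cell {owner!r}: columns span multiple groups {sorted(groups)}"
            )
        if pairing == "per_cell_series":
            if len(np.unique(times)) != len(times):
                raise ValidationError(
                    f"cell {owner!r}: duplicate time labels in per_cell_series mode"
                )
        else:
            times = np.arange(len(members), dtype=float)
        cell_ids.append(owner)
        group_of_cell[owner] = groups.pop()
        types = {m.known_type for m in members if m.known_type is not None}
        if len(types) == 1:
            known[owner] = types.pop()
        sub = matrix.loc[:, cols].to_numpy(dtype=float)
        for i, gene in enumerate(gene_ids):
            series[(gene, owner)] = GeneTimeSeries(gene, owner, times, sub[i])

    return ExpressionSeriesSet(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        group_of_cell=group_of_cell,
        series=series,
        known_type_of_cell=known,
    )


def write_expression_table(
    sset: ExpressionSeriesSet,
    path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = ",",
) -> None:
    """Write the dense matrix (and optionally metadata) back to delimited text."""
    df = sset.values_matrix()
    df.to_csv(path, sep=sep)
    if metadata_path is not None:
        rows = []
        for cell in sset.cell_ids:
            grid = sset.series[(sset.gene_ids[0], cell)].times
            for j, t in enumerate(grid):
                name = cell if len(grid) == 1 else f"{cell}@{t:g}"
                rows.append(
                    {
                        "cell_id": name,
                        "time": t,
                        "group": sset.group_of_cell[cell],
                        "known_type": sset.known_type_of_cell.get(cell, ""),
                        "cell": cell,
                    }
                )
        pd.DataFrame(rows).to_csv(metadata_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def filter_low_quality_genes(
    sset: ExpressionSeriesSet, min_fraction: float = 0.8
) -> ExpressionSeriesSet:
    """Keep genes expressed in at least ``min_fraction`` of cells.

    A gene counts as expressed in a cell when at least one of its time
    points in that cell is strictly positive (an FPKM of exactly 0 means
    not expressed).  The boundary is inclusive: a gene expressed in
    exactly ``min_fraction`` of cells is kept.  Returns a new set; the
    input is not modified.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in [0, 1], got {min_fraction}")
    n = sset.n_cells
    keep = []
    for gene in sset.gene_ids:
        expressed = sum(
            1 for cell in sset.cell_ids if np.any(sset.series[(gene, cell)].values > 0)
        )
        if expressed / n >= min_fraction:
            keep.append(gene)
    if not keep:
        raise EmptyResultError(
            f"no gene is expressed in at least {min_fraction:.0%} of cells; "
            "lower min_fraction"
        )
    return sset.subset_genes(keep)
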
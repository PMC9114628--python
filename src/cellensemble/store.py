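"""The unified table: one queryable structure holding expression and metadata.

Every cell is a row keyed by a contiguous integer ``cid``. Columns are the
fixed gene axis (sparse, non-negative normalized expression) plus 17 free-text
metadata fields describing the dataset- and cell-level provenance. Storing all
cells from all studies in one flat structure is what makes cross-study
"in data" sorting possible: a query never needs to know which file a cell
came from.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ColumnError, FormatError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from anndata import AnnData

#: The 17 per-cell metadata fields, in canonical column order.
METADATA_FIELDS: tuple[str, ...] = (
    "user_id",
    "study_id",
    "cell_id",
    "organ",
    "region",
    "subregion",
    "seq_tech",
    "sample_status",
    "donor_id",
    "donor_gender",
    "donor_age",
    "original_name",
    "cl_name",
    "uhaf_name",
    "tissue_type",
    "cell_type",
    "marker_gene",
)

_SAVE_FILES = ("metadata.csv", "matrix.mtx", "rows.txt", "cols.txt")


def _as_metadata_frame(meta, n_rows: int) -> pd.DataFrame:
    """Coerce records/DataFrame to the canonical 17-column string frame."""
    if isinstance(meta, pd.DataFrame):
        records = meta.to_dict("records")
    else:
        records = list(meta)
    if len(records) != n_rows:
        raise SchemaError(
            f"got {len(records)} metadata records for {n_rows} expression rows"
        )
    for rec in records:
        unknown = set(rec) - set(METADATA_FIELDS)
        if unknown:
            raise SchemaError(f"unknown metadata field(s): {sorted(unknown)}")
    frame = pd.DataFrame(
        {f: [str(rec.get(f, "") or "") for rec in records] for f in METADATA_FIELDS},
    )
    return frame


def _as_sparse(expr, n_genes: int) -> sp.csr_matrix:
    mat = sp.csr_matrix(expr, dtype=np.float64)
    if mat.shape[1] != n_genes:
        raise SchemaError(
            f"expression has {mat.shape[1]} gene columns, gene axis has {n_genes}"
        )
    if mat.nnz and not np.all(np.isfinite(mat.data)):
        raise SchemaError("expression values must be finite")
    if mat.nnz and mat.data.min() < 0:
        raise SchemaError("expression values must be non-negative")
    return mat


class UnifiedTable:
    """Sparse cells-by-genes expression plus per-cell metadata, keyed by cid.

    Parameters
    ----------
    gene_axis
        Ordered, unique list of approved gene symbols; fixed for the lifetime
        of the table.
    values
        Optional initial expression matrix (cells x genes), any scipy-sparse
        or dense array over exactly ``gene_axis``.
    metadata
        Per-cell records (mapping or DataFrame) restricted to the 17-field
        schema; missing fields become empty strings.
    """

    def __init__(self, gene_axis: Sequence[str], values=None, metadata=None):
        gene_axis = [str(g) for g in gene_axis]
        if len(set(gene_axis)) != len(gene_axis):
            raise SchemaError("gene axis entries must be unique")
        self.gene_axis: list[str] = gene_axis
        self._gene_index = {g: i for i, g in enumerate(gene_axis)}
        if values is None:
            self.values = sp.csr_matrix((0, len(gene_axis)), dtype=np.float64)
            self.metadata = _as_metadata_frame([], 0)
        else:
            self.values = _as_sparse(values, len(gene_axis))
            self.metadata = _as_metadata_frame(
                metadata if metadata is not None else [], self.values.shape[0]
            )
        self.metadata.index = pd.RangeIndex(self.values.shape[0])

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_axis)

    def is_gene(self, name: str) -> bool:
        return name in self._gene_index

    def gene_position(self, name: str) -> int:
        try:
            return self._gene_index[name]
        except KeyError:
            raise ColumnError(f"unknown gene symbol: {name!r}") from None

    def __repr__(self) -> str:
        return f"UnifiedTable({self.n_cells} cells x {self.n_genes} genes)"

    def __eq__(self, other) -> bool:
        if not isinstance(other, UnifiedTable):
            return NotImplemented
        return (
            self.gene_axis == other.gene_axis
            and self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and self.metadata.equals(other.metadata)
        )

    # -- operations ----------------------------------------------------------

    def insert_cells(self, expr, meta) -> "UnifiedTable":
        """Append cells; new rows receive the next contiguous cids.

        ``expr`` columns must already be in gene-axis order (use
        :func:`cellensemble.genes.unify_symbols` upstream to get there).
        Returns the table itself for chaining.
        """
        expr = _as_sparse(expr, self.n_genes)
        frame = _as_metadata_frame(meta, expr.shape[0])
        self.values = sp.vstack([self.values, expr], format="csr")
        self.metadata = pd.concat([self.metadata, frame], ignore_index=True)
        self.metadata.index = pd.RangeIndex(self.n_cells)
        return self

    def get_all_rows(self) -> list[int]:
        """The cid list of every cell in the table: 0..n-1."""
        return list(range(self.n_cells))

    def _check_cids(self, rows: Iterable[int] | None) -> np.ndarray:
        if rows is None:
            return np.arange(self.n_cells)
        cids = np.asarray(sorted(set(int(r) for r in rows)), dtype=np.int64)
        if cids.size and (cids[0] < 0 or cids[-1] >= self.n_cells):
            raise ColumnError(
                f"cid out of range for table of {self.n_cells} cells"
            )
        return cids

    def column(self, name: str, rows: Iterable[int] | None = None):
        """One column over the given rows: ndarray for genes, Series for metadata."""
        cids = self._check_cids(rows)
        if name in METADATA_FIELDS:
            return self.metadata[name].iloc[cids].reset_index(drop=True)
        if name in self._gene_index:
            j = self._gene_index[name]
            return np.asarray(self.values[cids, j].todense()).ravel()
        raise ColumnError(f"unknown column: {name!r}")

    def fetch(
        self,
        rows: Iterable[int] | None = None,
        cols: Sequence[str] | str = "ALL",
        row_filter=None,
        ontology=None,
        include_children: bool = False,
    ) -> pd.DataFrame:
        """Project columns for the selected rows, optionally filtered.

        ``cols`` mixes gene symbols and metadata field names (or the string
        ``"ALL"``). ``row_filter`` is a query expression (text or AST); rows
        failing it are dropped. The returned DataFrame is indexed by cid, in
        increasing order; gene columns are float, metadata columns str.
        """
        cids = self._check_cids(rows)
        if row_filter is not None:
            from .query import query_cells  # local import to avoid a cycle

            kept = query_cells(
                self,
                row_filter,
                rows=cids,
                ontology=ontology,
                include_children=include_children,
            )
            cids = np.asarray(kept, dtype=np.int64)
        if isinstance(cols, str):
            if cols != "ALL":
                cols = [cols]
            else:
                cols = list(METADATA_FIELDS) + self.gene_axis
        data = {}
        for name in cols:
            if name in METADATA_FIELDS:
                data[name] = self.metadata[name].iloc[cids].to_numpy()
            elif name in self._gene_index:
                j = self._gene_index[name]
                data[name] = np.asarray(self.values[cids, j].todense()).ravel()
            else:
                raise ColumnError(f"unknown column: {name!r}")
        return pd.DataFrame(data, index=pd.Index(cids, name="cid"))

    def get_column_set(self, rows: Iterable[int] | None, column: str) -> set:
        """All distinct values of one column over the given rows."""
        cids = self._check_cids(rows)
        if cids.size == 0:
            # existence check still applies
            if column not in METADATA_FIELDS and column not in self._gene_index:
                raise ColumnError(f"unknown column: {column!r}")
            return set()
        col = self.column(column, cids)
        if isinstance(col, pd.Series):
            return set(col)
        return set(col.tolist())

    # -- interchange ---------------------------------------------------------

    def to_anndata(self) -> "AnnData":
        """View the table as an :class:`anndata.AnnData` (cells = obs)."""
        import anndata

        obs = self.metadata.copy()
        obs.index = obs.index.map(str)
        return anndata.AnnData(
            X=self.values.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_axis, name="gene")),
        )


def save_atlas(table: UnifiedTable, directory: str | os.PathLike) -> list[str]:
    """Write the four-file atlas directory.

    ``metadata.csv`` (UTF-8, minimal quoting), ``matrix.mtx`` (MatrixMarket
    coordinate real general, 1-based indices), ``rows.txt`` (cids) and
    ``cols.txt`` (gene symbols). Returns the file paths written.
    """
    os.makedirs(directory, exist_ok=True)
    paths = [os.path.join(directory, f) for f in _SAVE_FILES]
    table.metadata.to_csv(paths[0], index=False, encoding="utf-8")
    scipy.io.mmwrite(paths[1], sp.coo_matrix(table.values))
    with open(paths[2], "w", encoding="utf-8") as fh:
        fh.writelines(f"{cid}\n" for cid in range(table.n_cells))
    with open(paths[3], "w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\n" for g in table.gene_axis)
    return paths


def load_atlas(directory: str | os.PathLike) -> UnifiedTable:
    """Reconstruct a table saved by :func:`save_atlas` (exact round trip)."""
    paths = {f: os.path.join(directory, f) for f in _SAVE_FILES}
    for name, path in paths.items():
        if not os.path.exists(path):
            raise FormatError(f"missing atlas file: {name}")
    try:
        matrix = sp.csr_matrix(scipy.io.mmread(paths["matrix.mtx"]))
    except Exception as exc:
        raise FormatError(f"corrupt matrix.mtx: {exc}") from exc
    with open(paths["rows.txt"], encoding="utf-8") as fh:
        row_lines = [ln.strip() for ln in fh if ln.strip()]
    with open(paths["cols.txt"], encoding="utf-8") as fh:
        genes = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(row_lines) != matrix.shape[0]:
        raise FormatError(
            f"rows.txt lists {len(row_lines)} cids but matrix.mtx has "
            f"{matrix.shape[0]} rows"
        )
    if len(genes) != matrix.shape[1]:
        raise FormatError(
            f"cols.txt lists {len(genes)} genes but matrix.mtx has "
            f"{matrix.shape[1]} columns"
        )
    try:
        meta = pd.read_csv(
            paths["metadata.csv"], dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except Exception as exc:
        raise FormatError(f"corrupt metadata.csv: {exc}") from exc
    if len(meta) != matrix.shape[0]:
        raise FormatError(
            f"metadata.csv has {len(meta)} records but matrix.mtx has "
            f"{matrix.shape[0]} rows"
        )
    return UnifiedTable(genes, matrix, meta)
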
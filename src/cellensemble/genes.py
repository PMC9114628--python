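"""Gene-symbol unification onto a fixed approved-symbol axis.

Heterogeneous datasets name genes inconsistently (previous, withdrawn and
alias symbols). Before cells can share one table, every input matrix is
re-indexed onto the closed list of approved symbols: aliases are translated,
names resolving to the same approved symbol are summed, unrecognized names
are dropped (and reported), and approved genes never sequenced become
all-zero columns so the axis is identical across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError


@dataclass(frozen=True)
class GeneSymbolTable:
    """Approved symbol list plus alias -> approved map.

    Invariants (checked on construction): every alias target is approved and
    no approved symbol doubles as an alias key.
    """

    approved: tuple[str, ...]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        approved_set = set(self.approved)
        if len(approved_set) != len(self.approved):
            raise FormatError("duplicate approved symbol")
        bad_target = [a for a, t in self.alias_map.items() if t not in approved_set]
        if bad_target:
            raise FormatError(
                f"alias(es) point to unknown approved symbol: {sorted(bad_target)[:5]}"
            )
        shadow = approved_set & set(self.alias_map)
        if shadow:
            raise FormatError(
                f"approved symbol(s) also used as alias: {sorted(shadow)[:5]}"
            )

    def resolve(self, name: str) -> str | None:
        """Approved symbol for ``name`` (case-sensitive exact match), or None."""
        if name in set(self.approved):
            return name
        return self.alias_map.get(name)


def load_symbol_table(path) -> GeneSymbolTable:
    """Read an approved-symbol TSV with columns ``approved`` and ``alias``.

    One row per approved symbol; the alias cell may be empty or hold several
    alias symbols separated by ``|``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("approved", "alias"):
        if col not in frame.columns:
            raise FormatError(f"symbol table is missing column {col!r}")
    approved = tuple(frame["approved"])
    alias_map: dict[str, str] = {}
    for sym, aliases in zip(frame["approved"], frame["alias"]):
        for alias in filter(None, (a.strip() for a in aliases.split("|"))):
            if alias in alias_map and alias_map[alias] != sym:
                raise FormatError(f"alias {alias!r} maps to multiple approved symbols")
            alias_map[alias] = sym
    return GeneSymbolTable(approved, alias_map)


@dataclass
class UnifyReport:
    """What happened during unification.

    ``unmapped`` are input names dropped (with the total counts they carried);
    ``collisions`` maps an approved symbol to the >=2 input names merged into
    it by summation.
    """

    unmapped: list[str]
    unmapped_total: float
    collisions: dict[str, list[str]]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def unify_symbols(matrix, gene_names, symbols: GeneSymbolTable):
    """Re-index a cells-by-genes count matrix onto the full approved axis.

    Parameters
    ----------
    matrix
        Cells x genes, dense or sparse, non-negative.
    gene_names
        Column names of ``matrix`` (arbitrary symbols, aliases included).
    symbols
        The approved-symbol table driving the mapping.

    Returns
    -------
    (csr_matrix over the approved axis in table order, UnifyReport)
    """
    matrix = sp.csr_matrix(matrix, dtype=np.float64)
    gene_names = [str(g) for g in gene_names]
    if matrix.shape[1] != len(gene_names):
        raise FormatError(
            f"{matrix.shape[1]} matrix columns vs {len(gene_names)} gene names"
        )
    if matrix.nnz and matrix.data.min() < 0:
        raise FormatError("counts must be non-negative")
    approved_index = {g: i for i, g in enumerate(symbols.approved)}

    src, dst = [], []
    unmapped: list[str] = []
    hits: dict[str, list[str]] = {}
    for j, name in enumerate(gene_names):
        target = name if name in approved_index else symbols.alias_map.get(name)
        if target is None:
            unmapped.append(name)
            continue
        src.append(j)
        dst.append(approved_index[target])
        hits.setdefault(target, []).append(name)

    n_in, n_out = len(gene_names), len(symbols.approved)
    projector = sp.csr_matrix(
        (np.ones(len(src)), (src, dst)), shape=(n_in, n_out), dtype=np.float64
    )
    out = sp.csr_matrix(matrix @ projector)
    unmapped_total = 0.0
    if unmapped:
        cols = [j for j, name in enumerate(gene_names) if name in set(unmapped)]
        unmapped_total = float(matrix[:, cols].sum())
    collisions = {t: names for t, names in hits.items() if len(names) > 1}
    return out, UnifyReport(unmapped, unmapped_total, collisions)
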
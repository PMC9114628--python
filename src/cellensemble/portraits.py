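"""Quantitative portraits: multi-statistic summaries of genes, cell types and
organs across the assembled atlas.

A gene portrait reports, per organ or per cell type, how often the gene is
detected and the distribution of its non-zero normalized values (zeros are
dropped before the distribution summary, as in the atlas's ridge plots, since
scRNA-seq zero inflation would otherwise dominate). A cell-type portrait
ranks marker genes by comparing the type against all other cells with a
Wilcoxon rank-sum test. An organ portrait reports the cell-type composition
observed in that organ's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GroupingError, NameLookupError
from .store import UnifiedTable
from .uhaf import UHAFOntology

_QUANTILES = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class GroupPortrait:
    """Per-group statistics of one gene's expression."""

    group: str
    n_cells: int
    n_nonzero: int
    pct_expr: float
    median_nonzero: float | None
    quantiles_nonzero: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MarkerRecord:
    """One retained marker gene of a cell type."""

    gene: str
    log_fc: float
    p_value: float
    p_adj: float
    pct_in: float
    pct_out: float


def gene_portrait(
    table: UnifiedTable, gene: str, group_by: str = "cell_type"
) -> dict[str, GroupPortrait]:
    """Expression summary of ``gene`` per group (``organ`` or ``cell_type``).

    Cells with an empty grouping label are not counted; groups with zero
    cells are omitted.
    """
    if group_by not in ("organ", "cell_type"):
        raise GroupingError(f"group_by must be 'organ' or 'cell_type', got {group_by!r}")
    values = table.column(gene)  # raises ColumnError for unknown genes
    labels = table.metadata[group_by].to_numpy()
    out: dict[str, GroupPortrait] = {}
    for group in sorted(set(labels) - {""}):
        vals = values[labels == group]
        nonzero = vals[vals > 0]
        out[group] = GroupPortrait(
            group=group,
            n_cells=int(vals.size),
            n_nonzero=int(nonzero.size),
            pct_expr=float(nonzero.size / vals.size),
            median_nonzero=float(np.median(nonzero)) if nonzero.size else None,
            quantiles_nonzero=(
                {q: float(np.quantile(nonzero, q)) for q in _QUANTILES}
                if nonzero.size
                else {}
            ),
        )
    return out


def _rank_sum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum per gene column (normal approximation with
    tie correction). Genes constant across both groups get p = 1."""
    combined_min = np.minimum(x_in.min(axis=0), x_out.min(axis=0))
    combined_max = np.maximum(x_in.max(axis=0), x_out.max(axis=0))
    constant = combined_min == combined_max
    pvals = np.ones(x_in.shape[1])
    varying = ~constant
    if varying.any():
        res = stats.mannwhitneyu(
            x_in[:, varying],
            x_out[:, varying],
            alternative="two-sided",
            method="asymptotic",
            axis=0,
        )
        pvals[varying] = res.pvalue
    return pvals


def celltype_markers(
    table: UnifiedTable,
    cell_type: str,
    ontology: UHAFOntology | None = None,
    include_children: bool = False,
    max_markers: int = 50,
    p_threshold: float = 0.05,
    min_pct_in: float = 0.25,
    adjust: str = "bonferroni",
) -> list[MarkerRecord]:
    """Marker genes of ``cell_type`` versus all other cells.

    Genes are tested with a two-sided rank-sum test, p-values adjusted over
    all tested genes (Bonferroni by default, ``adjust="fdr_bh"`` for
    Benjamini-Hochberg). Retained records have adjusted p <= ``p_threshold``,
    are expressed (value > 0) in at least ``min_pct_in`` of in-group cells and
    have positive log fold change; the top ``max_markers`` by log_fc are
    returned, descending.

    log_fc is the natural-log ratio of de-logged group means with a unit
    pseudo-count, so fold changes read on the expression scale.
    """
    labels = table.metadata["cell_type"].to_numpy()
    if include_children:
        if ontology is None:
            raise GroupingError("include_children requires an ontology")
        wanted = sorted(ontology.descendants(cell_type, ("is_a",)))
        in_mask = np.isin(labels, wanted)
    else:
        in_mask = labels == cell_type
    out_mask = ~in_mask
    if not in_mask.any() or not out_mask.any():
        raise GroupingError(
            f"both groups must be non-empty for {cell_type!r} "
            f"({int(in_mask.sum())} in-group of {labels.size} cells)"
        )
    x_in = np.asarray(table.values[np.flatnonzero(in_mask)].todense())
    x_out = np.asarray(table.values[np.flatnonzero(out_mask)].todense())

    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)
    log_fc = np.log(
        (np.expm1(x_in).mean(axis=0) + 1.0) / (np.expm1(x_out).mean(axis=0) + 1.0)
    )
    pvals = _rank_sum_pvalues(x_in, x_out)
    method = "bonferroni" if adjust == "bonferroni" else "fdr_bh"
    p_adj = multipletests(pvals, method=method)[1]

    keep = (p_adj <= p_threshold) & (pct_in >= min_pct_in) & (log_fc > 0)
    order = np.flatnonzero(keep)
    order = order[np.argsort(-log_fc[order], kind="stable")][:max_markers]
    return [
        MarkerRecord(
            gene=table.gene_axis[j],
            log_fc=float(log_fc[j]),
            p_value=float(pvals[j]),
            p_adj=float(min(p_adj[j], 1.0)),
            pct_in=float(pct_in[j]),
            pct_out=float(pct_out[j]),
        )
        for j in order
    ]


def organ_composition(table: UnifiedTable, organ: str) -> pd.DataFrame:
    """Counts and fractions of cell types observed in one organ's cells.

    Fractions are over cells with a non-empty cell-type label and sum to 1.
    """
    organs = table.metadata["organ"].to_numpy()
    if organ not in set(organs):
        raise NameLookupError(f"no cells from organ {organ!r}")
    labels = table.metadata["cell_type"].to_numpy()[organs == organ]
    labels = labels[labels != ""]
    if labels.size == 0:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = pd.Series(labels).value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    ).rename_axis("cell_type")
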
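"""Reference creation, KNN label transfer, and is-a-aware evaluation.

A labeled reference is carved out of the atlas with any sorting condition
("customized reference creation"), query cells are annotated by majority vote
of their k nearest reference cells in a shared embedding, and the transfer is
scored with a confusion matrix, accuracy (optionally granting credit when the
prediction is an is-a ancestor of the truth — predicting "Dendritic cell" for
a cDC1 cell is biologically correct), an exact binomial confidence interval,
and Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.neighbors import NearestNeighbors

from .errors import DimensionError, GroupingError
from .store import UnifiedTable
from .uhaf import UHAFOntology


@dataclass
class ReferenceSet:
    """Expression slice + labels + per-cell provenance for label transfer."""

    values: object  # sparse cells x genes slice over the table's gene axis
    labels: list[str]
    study_ids: list[str]
    cids: list[int]

    def __len__(self) -> int:
        return len(self.labels)


def build_reference(
    table: UnifiedTable,
    condition,
    include_children: bool = False,
    ontology: UHAFOntology | None = None,
    label_field: str = "uhaf_name",
) -> ReferenceSet:
    """Select reference cells by a sorting condition and attach their labels.

    Cells whose label field is empty are excluded with a warning; an empty
    selection is an error.
    """
    from .query import query_cells

    cids = query_cells(
        table, condition, include_children=include_children, ontology=ontology
    )
    if not cids:
        raise GroupingError(f"reference condition matched no cells: {condition!r}")
    labels = table.metadata[label_field].to_numpy()[cids]
    unlabeled = [cid for cid, lab in zip(cids, labels) if lab == ""]
    if unlabeled:
        warnings.warn(
            f"excluding {len(unlabeled)} unlabeled cell(s) from reference: "
            f"cids {unlabeled[:10]}{'...' if len(unlabeled) > 10 else ''}",
            stacklevel=2,
        )
        cids = [cid for cid in cids if cid not in set(unlabeled)]
        if not cids:
            raise GroupingError("all selected cells are unlabeled")
        labels = table.metadata[label_field].to_numpy()[cids]
    return ReferenceSet(
        values=table.values[np.asarray(cids)],
        labels=[str(x) for x in labels],
        study_ids=[str(x) for x in table.metadata["study_id"].to_numpy()[cids]],
        cids=list(cids),
    )


def knn_transfer(
    reference_embedding,
    reference_labels,
    query_embedding,
    k: int = 10,
) -> list[str]:
    """Annotate query cells by majority vote of their k nearest reference
    cells (Euclidean distance in the shared embedding).

    Ties are broken by the smallest summed distance among the tied labels,
    then lexicographically.
    """
    ref = np.asarray(reference_embedding, dtype=np.float64)
    qry = np.asarray(query_embedding, dtype=np.float64)
    labels = np.asarray(list(reference_labels), dtype=object)
    if ref.ndim != 2 or qry.ndim != 2 or ref.shape[1] != qry.shape[1]:
        raise DimensionError(
            f"embedding dimensionality mismatch: reference {ref.shape} vs "
            f"query {qry.shape}"
        )
    if labels.size != ref.shape[0]:
        raise DimensionError("one label per reference cell required")
    if not 1 <= k <= ref.shape[0]:
        raise DimensionError(f"k={k} exceeds reference size {ref.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(ref)
    dist, idx = nn.kneighbors(qry)
    predictions = []
    for drow, irow in zip(dist, idx):
        votes: dict[str, int] = {}
        summed: dict[str, float] = {}
        for d, i in zip(drow, irow):
            lab = labels[i]
            votes[lab] = votes.get(lab, 0) + 1
            summed[lab] = summed.get(lab, 0.0) + float(d)
        best = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == best]
        tied.sort(key=lambda lab: (summed[lab], lab))
        predictions.append(tied[0])
    return predictions


@dataclass
class TransferResult:
    """Outcome of a label-transfer evaluation."""

    predicted: list[str]
    confusion: pd.DataFrame  # truth (rows) x predicted (columns), raw labels
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float
    n_correct: int

    @property
    def n(self) -> int:
        return len(self.predicted)


def cohen_kappa(confusion: pd.DataFrame | np.ndarray) -> float:
    """Chance-corrected agreement from a (square) confusion matrix:
    kappa = (p_o - p_e) / (1 - p_e), p_e from the marginals."""
    mat = np.asarray(confusion, dtype=np.float64)
    n = mat.sum()
    if n == 0:
        raise GroupingError("empty confusion matrix")
    p_o = np.trace(mat) / n
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def evaluate_transfer(
    predicted,
    truth,
    ontology: UHAFOntology | None = None,
    allow_is_a: bool = False,
    confidence: float = 0.95,
) -> TransferResult:
    """Score predictions against true labels.

    A prediction is correct iff it equals the truth, or — with
    ``allow_is_a`` — is an is-a ancestor of it in the ontology. Accuracy and
    its exact (Clopper-Pearson) binomial CI use this lenient count; the
    confusion matrix and Cohen's kappa are always computed on the raw labels,
    since folding hierarchy credit into chance correction is ill-defined.
    """
    predicted = [str(x) for x in predicted]
    truth = [str(x) for x in truth]
    if len(predicted) != len(truth):
        raise DimensionError(
            f"{len(predicted)} predictions for {len(truth)} true labels"
        )
    if not predicted:
        raise GroupingError("nothing to evaluate")
    if allow_is_a:
        if ontology is None:
            raise GroupingError("allow_is_a requires an ontology")
        correct = sum(
            p == t or p in ontology.ancestors(t, ("is_a",))
            for p, t in zip(predicted, truth)
        )
    else:
        correct = sum(p == t for p, t in zip(predicted, truth))
    n = len(predicted)

    labels = sorted(set(predicted) | set(truth))
    confusion = pd.crosstab(
        pd.Categorical(truth, categories=labels),
        pd.Categorical(predicted, categories=labels),
        rownames=["truth"],
        colnames=["predicted"],
        dropna=False,
    )
    ci = binomtest(correct, n).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return TransferResult(
        predicted=predicted,
        confusion=confusion,
        accuracy=correct / n,
        accuracy_ci=(float(ci.low), float(ci.high)),
        kappa=cohen_kappa(confusion),
        n_correct=int(correct),
    )
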
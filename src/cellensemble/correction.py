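"""Batch correction by inverse transformation from a corrected embedding.

Embedding-space integration methods align batches in a low-dimensional PCA
space but do not return a corrected expression matrix. This module closes
that gap: fit per-gene scaling and PCA loadings on the normalized data, hand
the embedding to any external integration tool (the atlas used Harmony,
applied per organ), then invert — corrected embedding -> loadings -> undo the
per-gene scaling ("multiply by the original standard deviation, add the
original mean") — to recover a corrected matrix on the expression scale.
The inverse step takes *any* corrected embedding, so the integration
algorithm itself stays a caller-supplied black box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import DimensionError

#: Components used by the atlas pipeline.
DEFAULT_N_COMPONENTS = 100


@dataclass
class CorrectionModel:
    """Per-gene mean/std and orthonormal PCA loadings (genes x k).

    Zero-variance genes get std clamped to 1 so scaling is always defined.
    """

    gene_mean: np.ndarray
    gene_std: np.ndarray
    loadings: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_genes(self) -> int:
        return self.loadings.shape[0]


def _dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=np.float64)
    return np.asarray(matrix, dtype=np.float64)


def fit_correction_model(
    normalized, k: int = DEFAULT_N_COMPONENTS
) -> tuple[CorrectionModel, np.ndarray]:
    """Scale per gene, fit top-k PCA loadings, and embed the cells.

    Returns ``(model, embedding)`` where the embedding Z = S @ loadings of the
    scaled matrix S = (X - mean) / std. Loadings are the top right singular
    vectors of S with a deterministic sign convention (the entry of largest
    magnitude in each component is positive, lowest index winning ties).
    """
    x = _dense(normalized)
    n_cells, n_genes = x.shape
    if not 1 <= k <= min(n_cells, n_genes):
        raise DimensionError(
            f"k={k} must be within 1..min(n_cells={n_cells}, n_genes={n_genes})"
        )
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    scaled = (x - mean) / std
    _, _, vt = np.linalg.svd(scaled, full_matrices=False)
    loadings = vt[:k].T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(k)] < 0
    loadings[:, flip] *= -1.0
    model = CorrectionModel(gene_mean=mean, gene_std=std, loadings=loadings)
    return model, scaled @ loadings


def inverse_correct(
    model: CorrectionModel, corrected_embedding
) -> tuple[np.ndarray, int]:
    """Map a (corrected) embedding back to a normalized expression matrix.

    X_hat = (Z @ loadings.T) * std + mean, gene-wise. Reconstructed values
    below zero are clipped to zero (expression is non-negative); the number of
    clipped entries is returned alongside the matrix.
    """
    z = np.asarray(corrected_embedding, dtype=np.float64)
    if z.ndim != 2 or z.shape[1] != model.k:
        raise DimensionError(
            f"embedding has {z.shape[1] if z.ndim == 2 else '?'} columns, "
            f"model expects {model.k}"
        )
    x_hat = (z @ model.loadings.T) * model.gene_std + model.gene_mean
    n_clipped = int((x_hat < 0).sum())
    np.clip(x_hat, 0.0, None, out=x_hat)
    return x_hat, n_clipped


def correct_per_organ(
    table,
    corrected_embeddings: dict[str, np.ndarray] | None = None,
    k: int = DEFAULT_N_COMPONENTS,
):
    """Fit one correction model per organ (cross-organ correction is not
    attempted: organs need not share cell types).

    ``corrected_embeddings`` maps organ -> externally corrected embedding for
    that organ's cells (in cid order); organs absent from the mapping are
    round-tripped through their own uncorrected embedding. Returns
    ``{organ: (model, corrected_matrix, cids)}``.
    """
    organs = table.metadata["organ"].to_numpy()
    out = {}
    for organ in sorted(set(organs) - {""}):
        cids = np.flatnonzero(organs == organ)
        x = table.values[cids]
        k_organ = min(k, len(cids), table.n_genes)
        model, z = fit_correction_model(x, k_organ)
        if corrected_embeddings and organ in corrected_embeddings:
            z = corrected_embeddings[organ]
        corrected, _ = inverse_correct(model, z)
        out[organ] = (model, corrected, cids.tolist())
    return out
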
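"""Reverse-log transformation and library-size normalization.

Incoming datasets arrive either as raw counts or already log-transformed;
:func:`delog` takes log-scale data back to the raw scale. All cells are then
made comparable across sequencing depths by rescaling each cell's counts to a
common total (10,000 reads by default) followed by log1p — the
depth-adjusted, log-normalized representation the unified table stores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import CellEnsembleError


@dataclass(frozen=True)
class NormalizationConfig:
    """``scale_factor``: target reads per cell; ``log_base``: base of a
    dataset's incoming log transform (pseudo-count assumed 1)."""

    scale_factor: float = 10_000.0
    log_base: float = math.e

    def __post_init__(self):
        if not self.scale_factor > 0:
            raise CellEnsembleError("scale_factor must be positive")


def delog(matrix, log_base: float = math.e) -> sp.csr_matrix:
    """Map each value v -> base**v - 1; zeros stay zero.

    Inverts a log(1 + x) transform of the given base, recovering raw-scale
    values from datasets deposited in log space.
    """
    mat = sp.csr_matrix(matrix, dtype=np.float64)
    if mat.nnz and not np.all(np.isfinite(mat.data)):
        raise ValueError("delog input must be finite")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("delog input must be non-negative")
    out = mat.copy()
    if out.nnz:
        out.data = np.power(float(log_base), out.data) - 1.0
    return out


def normalize_library_size(counts, config: NormalizationConfig | None = None):
    """Depth-adjust and log-normalize a cells-by-genes count matrix.

    For cell i with library size L_i = sum_g counts_ig > 0 the stored value is
    ln(1 + counts_ig * scale / L_i), so expm1 of a cell's values always sums
    back to ``scale_factor``. Zero-library cells are kept as all-zero rows and
    reported rather than dropped — discarding them is a QC decision left to
    the caller.

    Returns
    -------
    (normalized csr_matrix, list of zero-library cids)
    """
    config = config or NormalizationConfig()
    mat = sp.csr_matrix(counts, dtype=np.float64)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("counts must be non-negative")
    lib = np.asarray(mat.sum(axis=1)).ravel()
    zero_cells = np.flatnonzero(lib == 0).tolist()
    scale = np.zeros_like(lib)
    nonzero = lib > 0
    scale[nonzero] = config.scale_factor / lib[nonzero]
    out = sp.csr_matrix(sp.diags(scale) @ mat)
    out.data = np.log1p(out.data)
    return out, zero_cells
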
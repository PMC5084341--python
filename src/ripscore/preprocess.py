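"""Turn tumor expression matrices into per-gene relative expression.

One-channel (absolute intensity) data are log2-transformed, quantile
normalized across samples, then median-centered per gene. Two-channel
(log-ratio) data are already relative and pass through untouched.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    ONE_CHANNEL,
    TWO_CHANNEL,
    ExpressionMatrix,
    KnockdownWeights,
    RipscoreWarning,
)


def log_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset) for one-channel matrices."""
    if m.dialect != ONE_CHANNEL:
        raise ValueError("log_transform applies to one-channel data only")
    shifted = m.data.values + offset
    if np.any(shifted <= 0):
        raise ValueError(
            "nonpositive values after offset; increase offset or clean input"
        )
    return m.with_data(pd.DataFrame(np.log2(shifted), index=m.gene_ids, columns=m.sample_ids))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic across-sample quantile normalization.

    Every sample's values are replaced by the mean order statistics
    across samples, so all samples end with an identical distribution.
    Tied values within a sample receive the mean of the reference values
    their ranks span.
    """
    if m.data.shape[1] < 2:
        warnings.warn(
            "quantile normalization needs >=2 samples; returning input unchanged",
            RipscoreWarning,
            stacklevel=2,
        )
        return m
    values = m.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    # reference distribution: mean of per-sample order statistics
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average the assigned reference values over tied spans
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return m.with_data(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median; yields relative levels."""
    centered = m.data.sub(m.data.median(axis=1), axis=0)
    return m.with_data(centered, is_relative=True)


def to_relative(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Dialect-aware wrapper producing relative expression levels.

    Two-channel inputs are log-ratios already and need no processing;
    one-channel inputs run log2 -> quantile normalization -> per-gene
    median centering.
    """
    if m.dialect == TWO_CHANNEL:
        return m.with_data(m.data, is_relative=True)
    return median_center(quantile_normalize(log_transform(m, offset=offset)))


def align_genes(
    w: KnockdownWeights,
    m: ExpressionMatrix,
    min_coverage: float = 0.5,
) -> tuple[KnockdownWeights, ExpressionMatrix, float]:
    """Restrict weights and matrix to their shared genes, same order.

    Returns the aligned pair plus the coverage fraction (share of weight
    genes found in the matrix); warns when coverage falls below
    ``min_coverage``.
    """
    shared = w.gene_ids.intersection(m.gene_ids)
    if len(shared) == 0:
        raise ValueError("weights and matrix share no genes")
    # preserve the weight vector's gene order
    shared = w.gene_ids[w.gene_ids.isin(shared)]
    coverage = len(shared) / len(w.gene_ids)
    if coverage < min_coverage:
        warnings.warn(
            f"only {coverage:.1%} of weight genes found in the matrix",
            RipscoreWarning,
            stacklevel=2,
        )
    return w.reindex(shared), m.with_data(m.data.loc[shared]), coverage
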
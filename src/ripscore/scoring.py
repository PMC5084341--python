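"""Modified BASE single-sample scoring against knockdown weight vectors.

For one sample, genes are sorted by decreasing relative expression and
two CDF-like running sums are accumulated along that order: a foreground
sum ``h(i)`` of the weights and a background sum ``b(i)`` of their
complements (1 - w), each normalized to end at 1. When highly expressed
genes carry high weight, h rises faster than b; the signed maximum
deviation d = h(i*) - b(i*) (i* the first index maximizing |h - b|)
summarizes the bias. d is normalized against an empirical permutation
null (weights randomly reassigned to genes) to give a score; the score
from w_plus minus the score from w_minus is the similarity to the
knockdown profile, and the proliferation score is its negation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    KnockdownWeights,
    RipscoreWarning,
    SampleScore,
    scores_to_frame,
)

MIN_PERMUTATIONS = 100


@dataclass
class RunningSums:
    """Foreground/background running sums along the expression sort."""

    order: np.ndarray          # gene positions sorted by decreasing expression
    h: np.ndarray              # foreground CDF-like values
    b: np.ndarray              # background CDF-like values
    d: float                   # signed maximum deviation h(i*) - b(i*)
    degenerate: bool = False   # all-equal weights: d is 0 by construction


@dataclass
class NullDistribution:
    """Signed max deviations under random weight-to-gene reassignment."""

    deviations: np.ndarray
    n_perm: int
    seed: int


def _sort_order(e: np.ndarray, gene_ids: pd.Index) -> np.ndarray:
    """Decreasing expression; ties broken by gene id for determinism."""
    tie_rank = np.argsort(np.argsort(gene_ids.to_numpy().astype(str)))
    return np.lexsort((tie_rank, -e))


def _check_inputs(e: np.ndarray, w: np.ndarray) -> None:
    if e.shape != w.shape:
        raise ValueError("expression and weights must be aligned")
    if len(e) < 2:
        raise ValueError("need at least 2 genes to score")
    if w.sum() == 0:
        raise ValueError("weight vector sums to zero")
    if (1.0 - w).sum() == 0:
        raise ValueError("complement weight vector sums to zero")


def _deviation_from_sorted(w_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    h = np.cumsum(w_sorted)
    h /= h[-1]
    b = np.cumsum(1.0 - w_sorted)
    b /= b[-1]
    diff = h - b
    i_star = int(np.argmax(np.abs(diff)))  # first index on ties
    return h, b, float(diff[i_star])


def running_sums(
    e: np.ndarray | pd.Series,
    w: np.ndarray,
    gene_ids: pd.Index | None = None,
) -> RunningSums:
    """Compute h, b and the signed maximum deviation for one sample.

    ``e`` holds the sample's relative expression, ``w`` one weight
    vector (w_plus or w_minus magnitudes) aligned to the same genes.
    """
    if isinstance(e, pd.Series):
        gene_ids = e.index if gene_ids is None else gene_ids
        e = e.to_numpy(dtype=float)
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    _check_inputs(e, w)
    if gene_ids is None:
        gene_ids = pd.RangeIndex(len(e))
    if np.allclose(w, w[0]):
        order = _sort_order(e, pd.Index(gene_ids))
        h, b, _ = _deviation_from_sorted(w[order])
        return RunningSums(order=order, h=h, b=b, d=0.0, degenerate=True)
    order = _sort_order(e, pd.Index(gene_ids))
    h, b, d = _deviation_from_sorted(w[order])
    return RunningSums(order=order, h=h, b=b, d=d)


def permutation_null(
    e: np.ndarray | pd.Series,
    w: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> NullDistribution:
    """Empirical null of the max deviation under weight reassignment.

    Each permutation uniformly shuffles which gene carries which weight
    (equivalent to shuffling the expression ranks) and records the
    signed maximum deviation.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}")
    if isinstance(e, pd.Series):
        e = e.to_numpy(dtype=float)
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    _check_inputs(e, w)
    rng = np.random.default_rng(seed)
    n = len(w)
    seed_repr = seed if isinstance(seed, int) else -1
    if np.allclose(w, w[0]):
        # permuting an all-equal weight vector cannot move h off b
        return NullDistribution(deviations=np.zeros(n_perm), n_perm=n_perm,
                                seed=seed_repr)
    # The weight sums are permutation-invariant, so h(i) - b(i) reduces to
    # cumsum(w)*(1/sum_w + 1/sum_1mw) - rank/sum_1mw, needing one cumsum per
    # permutation. Accumulation runs in float32: the null only feeds the
    # mean same-sign deviation, where ~1e-4 relative error is immaterial.
    dtype = np.float32
    w32 = w.astype(dtype)
    sum_w = float(w32.sum())
    sum_b = n - sum_w
    perm = np.tile(w32, (n_perm, 1))
    rng.permuted(perm, axis=1, out=perm)
    diff = np.cumsum(perm, axis=1)
    np.multiply(diff, np.asarray(1.0 / sum_w + 1.0 / sum_b, dtype=dtype), out=diff)
    diff -= np.arange(1, n + 1, dtype=dtype) / np.asarray(sum_b, dtype=dtype)
    np.abs(diff, out=perm)
    idx = np.argmax(perm, axis=1)
    deviations = np.take_along_axis(diff, idx[:, None], axis=1).ravel().astype(float)
    return NullDistribution(deviations=deviations, n_perm=n_perm, seed=seed_repr)


def normalize_score(d: float, null: NullDistribution) -> float:
    """Sign-preserving normalization of d against the permutation null.

    Nonnegative deviations are divided by the mean of the nonnegative
    null deviations; negative ones by the mean magnitude of the negative
    null deviations. If the same-sign null subset is empty, the mean
    absolute null deviation is used instead.
    """
    dev = np.asarray(null.deviations, dtype=float)
    if len(dev) == 0:
        raise ValueError("empty null distribution")
    if np.all(dev == 0):
        warnings.warn("all null deviations are zero; score set to 0",
                      RipscoreWarning, stacklevel=2)
        return 0.0
    same_sign = dev[dev >= 0] if d >= 0 else np.abs(dev[dev < 0])
    denom = same_sign.mean() if len(same_sign) else np.abs(dev).mean()
    if denom == 0:
        denom = np.abs(dev).mean()
    return float(d / denom) if d >= 0 else float(-abs(d) / denom)


def score_sample(
    e: pd.Series,
    weights: KnockdownWeights,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sample",
) -> SampleScore:
    """Score one sample against both weight vectors.

    Separate permutation streams (derived from ``seed``) normalize the
    w_plus and w_minus deviations; the similarity is their difference
    and the proliferation score its negation.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_plus, seed_minus = ss.spawn(2)
    e_values = e.to_numpy(dtype=float)
    if np.allclose(e_values, e_values[0]):
        warnings.warn(f"sample {sample_id!r} has constant expression; score 0",
                      RipscoreWarning, stacklevel=2)
        return SampleScore(sample_id=sample_id, score_plus=0.0, score_minus=0.0)
    scores = {}
    for key, w, child in (("plus", weights.w_plus, seed_plus),
                          ("minus", weights.w_minus, seed_minus)):
        rs = running_sums(e_values, w, gene_ids=e.index)
        null = permutation_null(e_values, w, n_perm=n_perm, seed=child)
        scores[key] = normalize_score(rs.d, null)
    return SampleScore(sample_id=sample_id,
                       score_plus=scores["plus"], score_minus=scores["minus"])


def _sample_seed(master_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Per-sample seed from the master seed and a stable id hash.

    Hashing the sample id (not its column position) makes scores
    invariant to sample ordering in the matrix.
    """
    return np.random.SeedSequence([master_seed, zlib.crc32(str(sample_id).encode())])


def score_cohort(
    m: ExpressionMatrix,
    weights: KnockdownWeights,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every sample of a relative expression matrix.

    Returns a DataFrame indexed by sample id with columns score_plus,
    score_minus, similarity and rips. Fully deterministic under ``seed``.
    """
    if not m.is_relative:
        raise ValueError("matrix must hold relative expression (run to_relative)")
    from .preprocess import align_genes

    weights, m, _ = align_genes(weights, m)
    results = []
    for sample_id in m.sample_ids:
        e = m.data[sample_id]
        results.append(
            score_sample(e, weights, n_perm=n_perm,
                         seed=_sample_seed(seed, sample_id),
                         sample_id=str(sample_id))
        )
    return scores_to_frame(results)
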
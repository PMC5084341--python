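"""Derive knockdown weight vectors from a knockdown-vs-control comparison.

The transform runs: replicate averaging -> per-gene log-ratios
(knockdown minus control, both already on log scale) -> z-scoring of the
log-ratio vector -> conversion of each z to a standard-normal tail
p-value -> -log10(p), trimmed at a cap (default 10) and rescaled to
[0, 1]. Positive z feed ``w_plus`` (genes up in the knockdown), negative
z feed ``w_minus`` (genes down in the knockdown).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import KnockdownWeights, validate_profile


@dataclass
class ZVector:
    """Standardized log-ratios split by sign.

    ``z_plus`` keeps positive entries (negatives zeroed); ``z_minus``
    keeps negatives (positives zeroed); their sum reconstructs ``z``.
    """

    gene_ids: pd.Index
    z: np.ndarray

    @property
    def z_plus(self) -> np.ndarray:
        return np.where(self.z > 0, self.z, 0.0)

    @property
    def z_minus(self) -> np.ndarray:
        return np.where(self.z < 0, self.z, 0.0)


def average_replicates(profiles: list[pd.Series]) -> pd.Series:
    """Average replicate expression profiles gene-wise (log scale).

    All profiles must cover the identical gene set.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    first = validate_profile(profiles[0], "profile 0")
    for i, p in enumerate(profiles[1:], start=1):
        p = validate_profile(p, f"profile {i}")
        if not first.index.equals(p.index):
            missing = first.index.symmetric_difference(p.index).tolist()
            raise ValueError(
                f"profile {i} gene set mismatch; offending genes: {missing[:10]}"
            )
    stacked = pd.concat(profiles, axis=1)
    return stacked.mean(axis=1)


def log_ratios(knockdown: pd.Series, control: pd.Series) -> pd.Series:
    """Per-gene log-ratio of knockdown over control on the shared genes.

    Inputs are log-scale, so the ratio is the elementwise difference.
    """
    knockdown = validate_profile(knockdown, "knockdown")
    control = validate_profile(control, "control")
    shared = knockdown.index.intersection(control.index)
    if len(shared) == 0:
        raise ValueError("knockdown and control share no genes")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    return knockdown.loc[shared] - control.loc[shared]


def standardize(f: pd.Series, ddof: int = 1) -> ZVector:
    """Z-score the log-ratio vector (subtract mean, divide by sd).

    ``ddof=1`` (sample sd) by default; pass ``ddof=0`` for population sd.
    """
    f = validate_profile(f, "log-ratio vector")
    if len(f) < 3:
        raise ValueError("need at least 3 genes to standardize")
    sd = float(np.std(f.values, ddof=ddof))
    if sd == 0:
        raise ValueError("zero variance in log-ratio vector")
    z = (f.values - float(np.mean(f.values))) / sd
    return ZVector(gene_ids=f.index, z=z)


def weights_from_z(
    zv: ZVector,
    trim_cap: float = 10.0,
    two_sided: bool = False,
    rescale: str = "cap",
) -> KnockdownWeights:
    """Convert z-scores to [0, 1] weights via the normal-tail transform.

    For each gene, ``p = P(Z > |z|)`` under the standard normal
    (doubled when ``two_sided``); the raw weight ``-log10(p)`` is trimmed
    at ``trim_cap`` and rescaled to [0, 1] — by dividing by the cap
    (``rescale="cap"``, default) or by the observed maximum
    (``rescale="max"``). Genes with z == 0 get zero weight in both
    directions.
    """
    if trim_cap <= 0:
        raise ValueError("trim_cap must be positive")
    if rescale not in ("cap", "max"):
        raise ValueError("rescale must be 'cap' or 'max'")
    z = np.asarray(zv.z, dtype=float)
    # logsf avoids underflow for large |z|; convert to -log10(p)
    neglog10p = -stats.norm.logsf(np.abs(z)) / np.log(10)
    if two_sided:
        neglog10p = neglog10p - np.log10(2.0)
        neglog10p = np.maximum(neglog10p, 0.0)
    raw = np.minimum(neglog10p, trim_cap)
    denom = trim_cap if rescale == "cap" else max(raw.max(), np.finfo(float).tiny)
    w = raw / denom
    w_plus = np.where(z > 0, w, 0.0)
    w_minus = np.where(z < 0, w, 0.0)
    return KnockdownWeights(
        gene_ids=zv.gene_ids, w_plus=w_plus, w_minus=w_minus, trim_cap=trim_cap
    )


def derive_weights(
    control_replicates: list[pd.Series],
    knockdown_replicates: list[pd.Series],
    trim_cap: float = 10.0,
    two_sided: bool = False,
) -> KnockdownWeights:
    """Full pipeline: replicates -> log-ratios -> z -> weights."""
    control = average_replicates(control_replicates)
    knockdown = average_replicates(knockdown_replicates)
    f = log_ratios(knockdown, control)
    zv = standardize(f)
    return weights_from_z(zv, trim_cap=trim_cap, two_sided=two_sided)


def top_k_genes(f: pd.Series, k: int = 300) -> tuple[list[str], list[str]]:
    """Genes with the k largest (up) and k smallest (down) log-ratios.

    Ties are broken by gene id for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(f):
        raise ValueError(f"k={k} exceeds the {len(f)} available genes")
    order = pd.DataFrame({"f": f.values, "gene": f.index.astype(str)})
    up = order.sort_values(["f", "gene"], ascending=[False, True])["gene"].head(k)
    down = order.sort_values(["f", "gene"], ascending=[True, True])["gene"].head(k)
    return up.tolist(), down.tolist()
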
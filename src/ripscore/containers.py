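"""Core data containers shared across the pipeline.

Expression data is held in pandas objects (Series for single profiles,
DataFrame for gene x sample matrices) wrapped in light dataclasses that
carry the metadata the scoring contract needs (dialect, relative-ness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ONE_CHANNEL = "one_channel"
TWO_CHANNEL = "two_channel"


class RipscoreWarning(UserWarning):
    """Base warning class for this package."""


def harmonize_gene_index(obj: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Uppercase gene identifiers and collapse duplicates by mean.

    Gene symbols are matched case-insensitively throughout; duplicate
    probes mapping to one symbol are averaged before any other step.
    """
    out = obj.copy()
    out.index = out.index.astype(str).str.upper()
    if out.index.has_duplicates:
        out = out.groupby(level=0, sort=False).mean()
    return out


def validate_profile(profile: pd.Series, name: str = "profile") -> pd.Series:
    """Check an expression profile: unique gene ids, finite values."""
    if profile.index.has_duplicates:
        dups = profile.index[profile.index.duplicated()].unique().tolist()
        raise ValueError(f"{name} has duplicate gene ids: {dups[:5]}")
    values = np.asarray(profile.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return profile.astype(float)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with processing state.

    Parameters
    ----------
    data : DataFrame
        Rows are genes, columns are samples.
    dialect : str
        ``"one_channel"`` (absolute intensities) or ``"two_channel"``
        (log-ratios, already relative to a reference).
    is_relative : bool
        True once values are per-gene relative expression levels, the
        precondition for scoring.
    """

    data: pd.DataFrame
    dialect: str = ONE_CHANNEL
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in (ONE_CHANNEL, TWO_CHANNEL):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.all(np.isfinite(self.data.values)):
            # drop genes with any missing value: simplest well-defined contract
            bad = ~np.isfinite(self.data.values).all(axis=1)
            n_bad = int(bad.sum())
            warnings.warn(
                f"dropping {n_bad} genes with missing/non-finite values",
                RipscoreWarning,
                stacklevel=2,
            )
            self.data = self.data.loc[~bad]

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def with_data(self, data: pd.DataFrame, **changes) -> "ExpressionMatrix":
        return replace(self, data=data, **changes)


@dataclass
class KnockdownWeights:
    """Paired per-gene weight vectors derived from a knockdown comparison.

    ``w_plus`` weights genes upregulated by the knockdown, ``w_minus``
    genes downregulated; both live in [0, 1] and are mutually exclusive
    per gene (a gene has nonzero weight in at most one of the two).
    """

    gene_ids: pd.Index
    w_plus: np.ndarray
    w_minus: np.ndarray
    trim_cap: float = 10.0

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        n = len(self.gene_ids)
        if self.w_plus.shape != (n,) or self.w_minus.shape != (n,):
            raise ValueError("weight vectors must match gene_ids length")
        for name, w in (("w_plus", self.w_plus), ("w_minus", self.w_minus)):
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any((self.w_plus > 0) & (self.w_minus > 0)):
            raise ValueError("a gene has nonzero weight in both directions")
        if self.trim_cap <= 0:
            raise ValueError("trim_cap must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"w_plus": self.w_plus, "w_minus": self.w_minus},
            index=self.gene_ids.rename("gene"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, trim_cap: float = 10.0) -> "KnockdownWeights":
        return cls(
            gene_ids=frame.index,
            w_plus=frame["w_plus"].to_numpy(),
            w_minus=frame["w_minus"].to_numpy(),
            trim_cap=trim_cap,
        )

    def reindex(self, genes: pd.Index) -> "KnockdownWeights":
        frame = self.to_frame().loc[genes]
        return KnockdownWeights.from_frame(frame, trim_cap=self.trim_cap)


@dataclass
class SampleScore:
    """Per-sample scoring result.

    ``similarity = score_plus - score_minus`` measures how closely the
    sample's relative expression resembles the knockdown profile; the
    proliferation score is its negation (high score = high inferred
    proliferation, i.e. dissimilar to the growth-arrested knockdown state).
    """

    sample_id: str
    score_plus: float
    score_minus: float

    @property
    def similarity(self) -> float:
        return self.score_plus - self.score_minus

    @property
    def rips(self) -> float:
        return -self.similarity


def scores_to_frame(scores: list[SampleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score_plus": [s.score_plus for s in scores],
            "score_minus": [s.score_minus for s in scores],
            "similarity": [s.similarity for s in scores],
            "rips": [s.rips for s in scores],
        }
    ).set_index("sample_id")
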
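"""Downstream cohort analyses over proliferation scores.

Stratification, ROC/AUC classification, Kaplan-Meier/log-rank and Cox
survival association, chemoresponse (pCR) rates, contingency folds, and
genome-instability metrics (per-sample mutated-gene counts and the
copy-number deviation score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RipscoreWarning

#: GRCh37 total assembled length; "the size of the human genome".
GENOME_SIZE_GRCH37 = 3_095_677_412

#: MAF variant classes counted as non-synonymous or indel mutations.
QUALIFYING_VARIANT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Translation_Start_Site", "Splice_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
})

#: Classes recognized but excluded (synonymous / non-coding).
NONQUALIFYING_VARIANT_CLASSES = frozenset({
    "Silent", "3'UTR", "5'UTR", "Intron", "IGR", "RNA", "3'Flank", "5'Flank",
    "lincRNA", "De_novo_Start_InFrame", "De_novo_Start_OutOfFrame",
})


# ---------------------------------------------------------------- stratify

def stratify_sign(scores: pd.Series) -> dict[str, pd.Index]:
    """Partition samples into score-negative (low) and score-positive (high).

    Scores exactly 0 go to the low group with a warning.
    """
    scores = scores.astype(float)
    if not np.all(np.isfinite(scores.values)):
        raise ValueError("scores must be finite")
    if (scores == 0).any():
        warnings.warn("scores equal to 0 assigned to the low group",
                      RipscoreWarning, stacklevel=2)
    groups = {"low": scores.index[scores <= 0], "high": scores.index[scores > 0]}
    for name in ("low", "high"):
        if len(groups[name]) == 0:
            warnings.warn(f"{name} group is empty", RipscoreWarning, stacklevel=2)
    return groups


def stratify_tertiles(scores: pd.Series) -> dict[str, pd.Index]:
    """Split the cohort into low/intermediate/high thirds by score.

    Cut points are the empirical 1/3 and 2/3 quantiles; ties at a cut
    point go to the lower group.
    """
    scores = scores.astype(float)
    if len(scores) < 3:
        raise ValueError("need at least 3 samples for tertiles")
    q1, q2 = np.quantile(scores.values, [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate score distribution; tertiles collapse",
                      RipscoreWarning, stacklevel=2)
    low = scores.index[scores <= q1]
    mid = scores.index[(scores > q1) & (scores <= q2)]
    high = scores.index[scores > q2]
    return {"low": low, "intermediate": mid, "high": high}


# ---------------------------------------------------------------- ROC / AUC

def roc_auc(labels: np.ndarray | pd.Series, scores: np.ndarray | pd.Series) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals the probability that a random positive outranks a random
    negative; tied scores contribute 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    pos = labels.astype(bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------- survival

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    curves: dict[str, pd.DataFrame]


def km_logrank(
    groups: dict[str, pd.Index],
    time: pd.Series,
    event: pd.Series,
) -> LogrankResult:
    """Kaplan-Meier curves per group plus the log-rank test across groups."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels, times, events = [], [], []
    curves = {}
    for name, idx in groups.items():
        if len(idx) == 0:
            continue
        t, ev = time.loc[idx], event.loc[idx]
        labels.extend([name] * len(idx))
        times.append(t)
        events.append(ev)
        kmf = KaplanMeierFitter()
        kmf.fit(t, ev, label=name)
        curves[name] = kmf.survival_function_
    times = pd.concat(times)
    events = pd.concat(events)
    if events.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value), curves=curves)


def cox_multivariate(
    covariates: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (partial likelihood).

    Returns one row per covariate with columns ``coefficient``, ``p``
    (Wald), ``hr`` and the 95% CI bounds, mirroring the usual
    prognostic-table layout.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    nunique = covariates.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    if int(event.sum()) < covariates.shape[1]:
        raise ValueError("fewer events than covariates")
    df = covariates.copy()
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summary = cph.summary
    return pd.DataFrame({
        "coefficient": summary["coef"],
        "p": summary["p"],
        "hr": summary["exp(coef)"],
        "ci_lower": summary["exp(coef) lower 95%"],
        "ci_upper": summary["exp(coef) upper 95%"],
    })


# ---------------------------------------------------------------- chemoresponse

@dataclass
class PcrResult:
    rates: dict[str, float]
    counts: dict[str, tuple[int, int]]
    fold: float | None   # high-rate over low-rate; None when undefined


def pcr_rates(groups: dict[str, pd.Index], pcr_labels: pd.Series) -> PcrResult:
    """Per-group pathologic-complete-response rate and high/low fold."""
    rates, counts = {}, {}
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {name!r} is empty")
        labels = pcr_labels.loc[idx].astype(int)
        counts[name] = (int(labels.sum()), len(labels))
        rates[name] = float(labels.mean())
    fold = rate_fold(rates.get("high", np.nan), rates.get("low", np.nan))
    return PcrResult(rates=rates, counts=counts, fold=fold)


def rate_fold(rate_high: float, rate_low: float) -> float | None:
    """Ratio of two rates; None when the denominator rate is zero."""
    if not np.isfinite(rate_high) or not np.isfinite(rate_low):
        return None
    if rate_low == 0:
        warnings.warn("low-group rate is 0; fold undefined",
                      RipscoreWarning, stacklevel=2)
        return None
    return float(rate_high / rate_low)


@dataclass
class ContingencyFold:
    fold: float | None
    chi2: float
    p_value: float


def contingency_fold(
    a_num: int, a_den: int, b_num: int, b_den: int,
    yates: bool = False,
) -> ContingencyFold:
    """Fold ratio of frequencies b/a with a 2x2 chi-square test.

    ``a_num/a_den`` and ``b_num/b_den`` are event frequencies in the two
    groups; the chi-square is computed without continuity correction by
    default.
    """
    if a_den <= 0 or b_den <= 0:
        raise ValueError("denominators must be positive")
    freq_a, freq_b = a_num / a_den, b_num / b_den
    if freq_a == 0:
        warnings.warn("reference frequency is 0; fold undefined",
                      RipscoreWarning, stacklevel=2)
        fold = None
    else:
        fold = float(freq_b / freq_a)
    table = np.array([[a_num, a_den - a_num], [b_num, b_den - b_num]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return ContingencyFold(fold=fold, chi2=float(chi2), p_value=float(p))


# ---------------------------------------------------------------- instability

def cnd(
    segments: pd.DataFrame,
    genome_size: int = GENOME_SIZE_GRCH37,
    dialect: str = "copy-number",
) -> pd.Series:
    """Copy-number deviation per sample.

    CND = sum_i |log2(c_i / 2) * f_i| / N over a sample's abnormal
    segments, where c_i is the segment's copy number, f_i its size
    (end - start + 1, 1-based inclusive) and N the genome size. Zero
    means a copy-number-normal genome. ``dialect="log2ratio"`` treats
    the value column as log2(c/2) directly.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if dialect not in ("copy-number", "log2ratio"):
        raise ValueError("dialect must be 'copy-number' or 'log2ratio'")
    required = {"sample_id", "start", "end", "value"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if len(segments) == 0:
        return pd.Series(dtype=float, name="cnd")
    sizes = segments["end"].to_numpy() - segments["start"].to_numpy() + 1
    if np.any(sizes <= 0):
        raise ValueError("segments with nonpositive size")
    values = segments["value"].to_numpy(dtype=float)
    if dialect == "copy-number":
        if np.any(values <= 0):
            raise ValueError("copy numbers must be positive")
        log2_dev = np.log2(values / 2.0)
    else:
        log2_dev = values
    contrib = np.abs(log2_dev * sizes) / genome_size
    return (pd.Series(contrib, index=segments["sample_id"].values)
            .groupby(level=0).sum().rename("cnd"))


def mutation_counts(muts: pd.DataFrame) -> pd.Series:
    """Distinct genes with >=1 non-synonymous or indel mutation per sample."""
    required = {"sample_id", "gene", "variant_class"}
    missing = required - set(muts.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    known = QUALIFYING_VARIANT_CLASSES | NONQUALIFYING_VARIANT_CLASSES
    unknown = set(muts["variant_class"]) - known
    if unknown:
        warnings.warn(f"unknown variant classes excluded: {sorted(unknown)}",
                      RipscoreWarning, stacklevel=2)
    hits = muts[muts["variant_class"].isin(QUALIFYING_VARIANT_CLASSES)]
    counts = hits.groupby("sample_id")["gene"].nunique()
    # samples present in the table but with no qualifying hit count as 0
    all_samples = pd.Index(pd.unique(muts["sample_id"]))
    return counts.reindex(all_samples, fill_value=0).rename("mutated_genes")


# ---------------------------------------------------------------- classifiers

def rf_pcr_comparison(
    features: pd.DataFrame,
    pcr_labels: pd.Series,
    include_rips: bool = True,
    rips_column: str = "rips",
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean AUC of a random-forest pCR classifier over repeated CV.

    Ten-fold cross-validation repeated ``n_repeats`` times; features are
    the clinical covariates, optionally augmented with the proliferation
    score column. Returns (mean AUC, sd of per-repeat AUCs).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    if len(features) < 50:
        raise ValueError("need at least 50 samples")
    y = pcr_labels.loc[features.index].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cols = list(features.columns)
    if not include_rips:
        cols = [c for c in cols if c != rips_column]
    X = features[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    repeat_aucs = []
    for _ in range(n_repeats):
        cv_seed = int(rng.integers(0, 2**31 - 1))
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
        y_prob = np.empty(len(y))
        for train, test in cv.split(X, y):
            if len(np.unique(y[train])) < 2:
                raise ValueError("a fold lost one class; labels too imbalanced")
            clf = RandomForestClassifier(n_estimators=200, random_state=cv_seed)
            clf.fit(X[train], y[train])
            y_prob[test] = clf.predict_proba(X[test])[:, 1]
        repeat_aucs.append(roc_auc(y, y_prob))
    return float(np.mean(repeat_aucs)), float(np.std(repeat_aucs))
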
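"""Synthetic knockdown experiments and tumor cohorts with known truth.

The generator emulates the statistical structure the scoring pipeline
assumes: a knockdown experiment whose downregulated genes form a
proliferation program; a tumor cohort whose latent per-sample
proliferation activity a_s drives expression of that program (genes down
in the knockdown rise with proliferation); survival, chemoresponse,
mutation burden and copy-number aberrations all coupled to a_s. Null
switches (kappa=0, gamma=0, pcr_slope=0, mut_c1=0) decouple each layer
so downstream associations can be driven to their null behavior.

Everything is deterministic under the master seed: sub-streams are
spawned from one SeedSequence in a fixed order, never shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import TWO_CHANNEL, ExpressionMatrix

#: toy genome used for simulated copy-number segments
TOY_CHROM_SIZES = {f"chr{i}": 40_000_000 for i in range(1, 6)}
TOY_GENOME_SIZE = sum(TOY_CHROM_SIZES.values())


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a mid-sized expression cohort: 5000 genes of which
    300 form the down-in-knockdown proliferation module and 150 the
    up-module, log2 effect sizes of mean magnitude 1.5 (sd 0.5),
    per-replicate noise sd 0.7, and 500 tumor samples whose latent
    activity is standard normal with hereditary cases shifted up by 1.
    """

    n_genes: int = 5000
    n_down: int = 300           # proliferation-program genes (down in knockdown)
    n_up: int = 150
    effect_mean: float = 1.5    # mean |log2 fold change| of module genes
    effect_sd: float = 0.5
    noise_sd: float = 0.7       # per-replicate expression noise, log2 scale
    n_replicates: int = 3
    n_samples: int = 500
    hereditary_frac: float = 0.15
    hereditary_shift: float = 1.0   # activity shift of hereditary samples
    kappa: float = 1.0          # tumor loading scale: beta_g = -kappa * delta_g
    baseline_hazard: float = 0.02   # events per month at activity 0
    gamma: float = 0.8          # log-hazard per unit activity
    censoring_rate: float = 0.4
    pcr_intercept: float = -2.5
    pcr_slope: float = 1.2
    mut_c0: float = float(np.log(20.0))  # Poisson log-link intercept
    mut_c1: float = 0.5                  # log-count slope in activity
    cnv_slope: float = 0.5               # log segment-count slope in activity
    n_mut_genes: int = 2000              # mutation gene universe
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hereditary_frac", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_down + self.n_up >= self.n_genes:
            raise ValueError("module sizes must be smaller than n_genes")
        for name in ("n_genes", "n_down", "n_up", "n_samples", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticCohort:
    """All generated artifacts plus the generating truth."""

    control_replicates: list[pd.Series]
    knockdown_replicates: list[pd.Series]
    tumors: ExpressionMatrix
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    segments: pd.DataFrame
    truth: pd.DataFrame          # per-sample: activity, hereditary
    module: pd.DataFrame         # per-gene: delta, membership
    genome_size: int = TOY_GENOME_SIZE


def _gene_universe(cfg: SimulationConfig) -> tuple[pd.Index, pd.DataFrame]:
    """Gene names and module assignment; MKI67 marks the down-module."""
    names = ["MKI67"] + [f"G{i:05d}" for i in range(1, cfg.n_genes)]
    genes = pd.Index(names, name="gene")
    membership = np.array(["none"] * cfg.n_genes, dtype=object)
    membership[: cfg.n_down] = "down"
    membership[cfg.n_down: cfg.n_down + cfg.n_up] = "up"
    module = pd.DataFrame({"membership": membership}, index=genes)
    return genes, module


def simulate_knockdown(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[pd.Series], list[pd.Series], pd.DataFrame]:
    """Control and knockdown replicate profiles plus the per-gene truth.

    Control replicates are baseline + noise; knockdown replicates add
    the effect delta_g: negative for the down-module (the proliferation
    program), positive for the up-module, zero elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes, module = _gene_universe(cfg)
    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)
    magnitudes = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd, size=cfg.n_genes))
    delta = np.zeros(cfg.n_genes)
    down = module["membership"].to_numpy() == "down"
    up = module["membership"].to_numpy() == "up"
    delta[down] = -magnitudes[down]
    delta[up] = magnitudes[up]
    module["delta"] = delta
    controls, knockdowns = [], []
    for r in range(cfg.n_replicates):
        controls.append(pd.Series(
            baseline + rng.normal(0, cfg.noise_sd, cfg.n_genes),
            index=genes, name=f"control_{r+1}"))
    for r in range(cfg.n_replicates):
        knockdowns.append(pd.Series(
            baseline + delta + rng.normal(0, cfg.noise_sd, cfg.n_genes),
            index=genes, name=f"knockdown_{r+1}"))
    return controls, knockdowns, module


def simulate_tumors(
    cfg: SimulationConfig,
    module: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Tumor log-ratio expression driven by latent proliferation activity.

    a_s ~ Normal(0, 1), with hereditary samples shifted by
    ``hereditary_shift``; gene loadings are beta_g = -kappa * delta_g,
    so genes suppressed by the knockdown rise with proliferation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(cfg.n_samples)], name="sample_id")
    hereditary = rng.random(cfg.n_samples) < cfg.hereditary_frac
    activity = rng.normal(0.0, 1.0, cfg.n_samples)
    activity[hereditary] += cfg.hereditary_shift
    beta = -cfg.kappa * module["delta"].to_numpy()
    values = beta[:, None] * activity[None, :] + rng.normal(
        0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    tumors = ExpressionMatrix(
        data=pd.DataFrame(values, index=module.index, columns=sample_ids),
        dialect=TWO_CHANNEL,
        is_relative=False,
    )
    truth = pd.DataFrame({"activity": activity, "hereditary": hereditary},
                         index=sample_ids)
    return tumors, truth


def _censoring_horizon(hazards: np.ndarray, target_rate: float) -> float:
    """Uniform(0, C) horizon giving the target expected censored fraction.

    With exponential event times at rate lambda_s and independent
    Uniform(0, C) censoring, P(censored | lambda) = (1 - exp(-lambda C))
    / (lambda C); C is solved so the cohort mean matches the target.
    """
    if target_rate <= 0:
        return np.inf

    def mean_censor_prob(c: float) -> float:
        x = hazards * c
        return float(np.mean(np.where(x > 0, -np.expm1(-x) / np.maximum(x, 1e-300), 1.0)))

    lo, hi = 1e-9, 1e9
    return float(brentq(lambda c: mean_censor_prob(c) - target_rate, lo, hi))


def simulate_clinical(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Survival, chemoresponse and clinical covariates from activity.

    Event times are exponential with hazard h0*exp(gamma*a_s); censoring
    is independent Uniform(0, C) with C calibrated to the configured
    censoring rate. pCR is Bernoulli(logistic(intercept + slope*a_s)).
    Covariates carry mild correlation with activity.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    a = truth["activity"].to_numpy()
    n = len(a)
    hazards = cfg.baseline_hazard * np.exp(cfg.gamma * a)
    event_times = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        horizon = _censoring_horizon(hazards, cfg.censoring_rate)
        censor_times = rng.uniform(0, horizon, n)
    else:
        censor_times = np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    pcr_prob = 1.0 / (1.0 + np.exp(-(cfg.pcr_intercept + cfg.pcr_slope * a)))
    pcr = (rng.random(n) < pcr_prob).astype(int)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    clinical = pd.DataFrame({
        "time": time,
        "event": event,
        "pcr": pcr,
        "hereditary": truth["hereditary"].astype(int),
        "age": np.clip(rng.normal(55 - 2 * a, 8), 25, 90),
        "er_status": (rng.random(n) < expit(0.8 - 0.6 * a)).astype(int),
        "pr_status": (rng.random(n) < expit(0.5 - 0.5 * a)).astype(int),
        "her2_status": (rng.random(n) < 0.2).astype(int),
        "size": np.exp(rng.normal(0.7 + 0.15 * a, 0.3)),
        "stage": np.clip(np.round(rng.normal(1.8 + 0.3 * a, 0.6)), 1, 4).astype(int),
        "grade": np.clip(np.round(rng.normal(2.0 + 0.4 * a, 0.5)), 1, 3).astype(int),
        "nodes": rng.poisson(np.exp(0.5 + 0.2 * a)),
    }, index=truth.index)
    return clinical


def simulate_instability(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic mutation table and copy-number segments from activity.

    Mutated-gene counts are Poisson with log-mean c0 + c1*a_s over a
    fixed gene universe; a TP53-like gene is mutated with probability
    logistic(-1.5 + a_s). Segment counts grow log-linearly in activity
    on a toy five-chromosome genome; high-activity samples also draw
    higher-magnitude aberrations.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    a = truth["activity"].to_numpy()
    universe = np.array([f"MG{i:04d}" for i in range(cfg.n_mut_genes)])
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    mut_rows = []
    for sample_id, act in zip(truth.index, a):
        n_mut = rng.poisson(np.exp(cfg.mut_c0 + cfg.mut_c1 * act))
        n_mut = min(n_mut, len(universe))
        genes = rng.choice(universe, size=n_mut, replace=False)
        classes = rng.choice(
            ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
             "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del"],
            p=[0.6, 0.12, 0.1, 0.08, 0.06, 0.04], size=n_mut)
        for g, c in zip(genes, classes):
            mut_rows.append((sample_id, g, c))
        # silent passengers: present in the table, never counted
        for g in rng.choice(universe, size=rng.poisson(3), replace=False):
            mut_rows.append((sample_id, g, "Silent"))
        if rng.random() < expit(-1.5 + act):
            mut_rows.append((sample_id, "TP53", "Missense_Mutation"))
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_class"])

    chroms = list(TOY_CHROM_SIZES)
    seg_rows = []
    for sample_id, act in zip(truth.index, a):
        n_seg = rng.poisson(np.exp(1.0 + cfg.cnv_slope * act))
        for _ in range(n_seg):
            chrom = chroms[rng.integers(len(chroms))]
            size = int(rng.integers(100_000, 5_000_000))
            start = int(rng.integers(1, TOY_CHROM_SIZES[chrom] - size))
            if rng.random() < expit(-1.5 + 0.5 * act):
                copy = 4  # high-level amplification, more likely when proliferative
            else:
                copy = 1 if rng.random() < 0.5 else 3
            seg_rows.append((sample_id, chrom, start, start + size - 1, copy))
    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "value"])
    return mutations, segments


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study from one master seed."""
    root = np.random.SeedSequence(cfg.seed)
    kd_ss, tumor_ss, clin_ss, inst_ss = root.spawn(4)
    controls, knockdowns, module = simulate_knockdown(
        cfg, np.random.default_rng(kd_ss))
    tumors, truth = simulate_tumors(cfg, module, np.random.default_rng(tumor_ss))
    clinical = simulate_clinical(cfg, truth, np.random.default_rng(clin_ss))
    mutations, segments = simulate_instability(
        cfg, truth, np.random.default_rng(inst_ss))
    return SyntheticCohort(
        control_replicates=controls,
        knockdown_replicates=knockdowns,
        tumors=tumors,
        clinical=clinical,
        mutations=mutations,
        segments=segments,
        truth=truth,
        module=module,
    )
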
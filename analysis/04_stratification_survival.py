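"""Stratify by proliferation score; hereditary discrimination and survival.

Reproduces the study structure: (i) hereditary-vs-sporadic separation by
score (ROC/AUC), (ii) Kaplan-Meier / log-rank comparison of the
score-negative vs score-positive groups, (iii) a multivariate Cox model
of the score against the clinical covariates. Writes results/cox_table.tsv.
"""

from pathlib import Path

import pandas as pd

from ripscore import io
from ripscore.downstream import cox_multivariate, km_logrank, roc_auc, stratify_sign

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", index_col="sample_id")["rips"]
    clin = io.read_clinical(ROOT / "cohort" / "clinical.tsv")

    auc = roc_auc(clin["hereditary"], scores)
    print(f"hereditary-vs-sporadic AUC by proliferation score: {auc:.3f} "
          f"({clin['hereditary'].sum()} hereditary of {len(clin)})")

    groups = stratify_sign(scores)
    res = km_logrank(groups, clin["time"], clin["event"])
    print(f"sign-stratified log-rank: chi2 = {res.statistic:.2f}, "
          f"p = {res.p_value:.3g} "
          f"(low n={len(groups['low'])}, high n={len(groups['high'])})")

    covariates = clin[["age", "size", "er_status", "her2_status",
                       "nodes", "stage", "grade"]].astype(float)
    covariates.insert(0, "rips", scores)
    table = cox_multivariate(covariates, clin["time"], clin["event"])
    table.to_csv(ROOT / "cox_table.tsv", sep="\t", index_label="covariate")
    row = table.loc["rips"]
    print(f"Cox (multivariate): score HR = {row['hr']:.3f} "
          f"[{row['ci_lower']:.3f}, {row['ci_upper']:.3f}], p = {row['p']:.3g}")
    print(f"full table -> {ROOT / 'cox_table.tsv'}")


if __name__ == "__main__":
    main()
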
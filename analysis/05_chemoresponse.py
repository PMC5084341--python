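"""Chemoresponse: pCR rates across score tertiles and RF classification.

Stratifies the cohort into score tertiles, compares pathologic
complete-response rates (and the high/low fold), and contrasts
random-forest pCR classifiers with and without the proliferation score
as a feature (10-fold CV repeated 10 times).
"""

import sys
from pathlib import Path

import pandas as pd

from ripscore import io
from ripscore.downstream import pcr_rates, rf_pcr_comparison, stratify_tertiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", index_col="sample_id")["rips"]
    clin = io.read_clinical(ROOT / "cohort" / "clinical.tsv")

    groups = stratify_tertiles(scores)
    res = pcr_rates(groups, clin["pcr"])
    for name in ("low", "intermediate", "high"):
        num, den = res.counts[name]
        print(f"pCR rate, {name} tertile: {res.rates[name]:.1%} ({num}/{den})")
    print(f"high/low pCR fold: {res.fold:.2f}" if res.fold is not None
          else "high/low pCR fold undefined (low rate 0)")

    features = clin[["age", "er_status", "pr_status", "her2_status",
                     "stage", "grade", "nodes"]].astype(float).copy()
    features["rips"] = scores
    for label, include in (("clinical + score", True), ("clinical only", False)):
        mean_auc, sd = rf_pcr_comparison(features, clin["pcr"],
                                         include_rips=include, seed=seed)
        print(f"RF pCR AUC ({label}): {mean_auc:.3f} (sd {sd:.3f})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 17)
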
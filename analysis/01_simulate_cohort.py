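"""Generate the synthetic study: knockdown experiment + tumor cohort.

Writes the control/knockdown replicate profiles, the tumor expression
matrix, clinical table, mutation and segment tables, and the generating
truth (latent proliferation activity per sample) under results/cohort/.
"""

import sys
from pathlib import Path

import pandas as pd

from ripscore import io
from ripscore.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 17) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    cohort = simulate_cohort(cfg)
    pd.concat(cohort.control_replicates, axis=1).to_csv(
        OUT / "control.tsv", sep="\t", index_label="gene")
    pd.concat(cohort.knockdown_replicates, axis=1).to_csv(
        OUT / "knockdown.tsv", sep="\t", index_label="gene")
    io.write_expression_matrix(cohort.tumors, OUT / "tumors.tsv")
    cohort.clinical.to_csv(OUT / "clinical.tsv", sep="\t")
    cohort.mutations.to_csv(OUT / "mutations.tsv", sep="\t", index=False)
    cohort.segments.to_csv(OUT / "segments.tsv", sep="\t", index=False)
    cohort.truth.to_csv(OUT / "truth.tsv", sep="\t")
    n_mod = (cohort.module["membership"] != "none").sum()
    print(f"simulated {cfg.n_samples} tumors x {cfg.n_genes} genes "
          f"({n_mod} module genes, {cohort.truth['hereditary'].sum()} hereditary); "
          f"wrote 7 tables to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 17)
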
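"""Turn the knockdown-vs-control comparison into weight vectors.

Averages replicates, forms per-gene log-ratios, z-scores them and maps
the standard-normal tail probabilities to [0, 1] weights (trim cap 10).
Writes results/weights.tsv and the top-300 up/down gene lists.
"""

from pathlib import Path

import pandas as pd

from ripscore import average_replicates, derive_weights, io, log_ratios, top_k_genes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    controls = io.read_profile(ROOT / "cohort" / "control.tsv")
    knockdowns = io.read_profile(ROOT / "cohort" / "knockdown.tsv")
    w = derive_weights(controls, knockdowns)
    io.write_weights(w, ROOT / "weights.tsv")
    n_up, n_down = (w.w_plus > 0).sum(), (w.w_minus > 0).sum()
    sat = ((w.w_plus == 1) | (w.w_minus == 1)).sum()
    print(f"weights for {len(w.gene_ids)} genes: {n_up} up, {n_down} down, "
          f"{sat} at the trim cap")
    f = log_ratios(average_replicates(knockdowns), average_replicates(controls))
    up, down = top_k_genes(f, k=300)
    pd.DataFrame({"up": up, "down": down}).to_csv(
        ROOT / "top300_genes.tsv", sep="\t", index=False)
    print(f"top-300 up/down gene lists -> {ROOT / 'top300_genes.tsv'}")


if __name__ == "__main__":
    main()
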
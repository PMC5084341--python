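"""Readers and writers for the tab-delimited formats the pipeline uses."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, KnockdownWeights, harmonize_gene_index


def read_expression_matrix(
    path: str | Path,
    dialect: str = "one_channel",
    is_relative: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample TSV (header row, gene ids in column 1)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    data = harmonize_gene_index(data)
    return ExpressionMatrix(data=data, dialect=dialect, is_relative=is_relative)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


def read_profile(path: str | Path) -> list[pd.Series]:
    """Read single-condition profiles (one column per replicate)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    data = harmonize_gene_index(data)
    return [data[c] for c in data.columns]


def read_weights(path: str | Path, trim_cap: float = 10.0) -> KnockdownWeights:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = harmonize_gene_index(frame)
    return KnockdownWeights.from_frame(frame, trim_cap=trim_cap)


def write_weights(w: KnockdownWeights, path: str | Path) -> None:
    w.to_frame().to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "time" in table.columns and (table["time"] < 0).any():
        raise ValueError("negative survival times")
    if "event" in table.columns and not table["event"].isin([0, 1]).all():
        raise ValueError("event column must be 0/1")
    return table


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-style mutation TSV; standard MAF headers are mapped."""
    table = pd.read_csv(path, sep="\t")
    renames = {"Hugo_Symbol": "gene", "Tumor_Sample_Barcode": "sample_id",
               "Variant_Classification": "variant_class"}
    table = table.rename(columns=renames)
    return table[["sample_id", "gene", "variant_class"]]


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style segment TSV; standard SEG headers are mapped."""
    table = pd.read_csv(path, sep="\t")
    renames = {"Sample": "sample_id", "Chromosome": "chrom",
               "Start": "start", "End": "end",
               "Segment_Mean": "value", "Copy_Number": "value"}
    table = table.rename(columns={k: v for k, v in renames.items()
                                  if k in table.columns})
    return table
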
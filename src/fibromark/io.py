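"""Readers and writers for the pipeline's plain-text interchange formats.

Expression: gene x sample TSV with a header row of sample ids, plus a
two-column sample sheet (sample_id, group[, subgroup]).  Methylation:
CSV with probe, genes, beta_case_mean, beta_control_mean, p_value[, q].
Cells: 10x-style triplet (features.tsv, barcodes.tsv, matrix.mtx in
MatrixMarket coordinate format) plus a barcode -> cell_type label TSV.
Gene lists are newline-delimited; the truth manifest is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .celltype import CellMatrix
from .dge import ExpressionMatrix
from .methylome import MethylationTable, compute_delta_beta

__all__ = [
    "write_expression",
    "read_expression",
    "write_methylation",
    "read_methylation",
    "write_10x_triplet",
    "read_10x_triplet",
    "write_gene_list",
    "read_gene_list",
    "write_json",
    "read_json",
]


def write_expression(
    matrix: ExpressionMatrix, counts_path: str | Path, samples_path: str | Path
) -> None:
    matrix.values.to_csv(counts_path, sep="\t", index_label="gene")
    sheet = pd.DataFrame({"sample_id": matrix.samples, "group": matrix.groups.values})
    if matrix.subgroups is not None:
        sheet["subgroup"] = matrix.subgroups.values
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_expression(
    counts_path: str | Path, samples_path: str | Path, unit: str = "raw_counts"
) -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    values.index.name = None
    values.columns.name = None
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"], name="group")
    subgroups = None
    if "subgroup" in sheet.columns:
        subgroups = pd.Series(
            sheet["subgroup"].values, index=sheet["sample_id"], name="subgroup"
        )
    return ExpressionMatrix(values=values, groups=groups, unit=unit, subgroups=subgroups)


def write_methylation(table: MethylationTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False)


def read_methylation(path: str | Path) -> MethylationTable:
    t = pd.read_csv(path)
    if "p" in t.columns and "p_value" not in t.columns:
        t = t.rename(columns={"p": "p_value"})
    return compute_delta_beta(t)


def write_10x_triplet(
    matrix: CellMatrix, outdir: str | Path, labels_name: str = "labels.tsv"
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(matrix.genes).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(matrix.spots).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), matrix.counts.astype(int))
    matrix.labels.rename_axis("barcode").rename("cell_type").to_csv(
        outdir / labels_name, sep="\t"
    )


def read_10x_triplet(
    indir: str | Path,
    labels_path: str | Path | None = None,
    mito_prefix: str = "MT-",
) -> CellMatrix:
    indir = Path(indir)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    counts = sparse.csr_matrix(scipy_io.mmread(str(indir / "matrix.mtx")))
    if labels_path is None:
        labels_path = indir / "labels.tsv"
    lab = pd.read_csv(labels_path, sep="\t")
    labels = pd.Series(lab["cell_type"].values, index=lab["barcode"], name="cell_type")
    return CellMatrix(
        counts=counts,
        genes=pd.Index(genes),
        spots=pd.Index(barcodes),
        labels=labels,
        mito_prefix=mito_prefix,
    )


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
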
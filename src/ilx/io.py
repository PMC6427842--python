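"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* expression matrix — TSV, first column ``gene_id``, remaining columns sample ids
* sample sheet — CSV: sample_id, genotype, aS (0/1), batch, chronological_time_h
* gene map — BED (chrom, start, end, gene_id), 0-based half-open bp;
  converted internally to 1-based Mb midpoints
* GO annotation — TSV (gene_id, go_id) plus a term table TSV
  (go_id, description, type)
* phenotype — long CSV; survival — CSV with per-worm event records
* age calibration — TSV (gene_id, slope, intercept)

All writers emit headers and round-trip numeric values at full ``repr``
precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CHROMOSOMES,
    ExpressionDataset,
    GeneMap,
    GOCatalog,
    GOTerm,
    PhenotypeTable,
    SurvivalTable,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "read_sample_sheet",
    "read_gene_map_bed",
    "read_go_annotation",
    "read_phenotype_table",
    "read_survival_table",
    "read_age_calibration",
    "load_dataset",
    "write_results",
    "write_gene_map_bed",
]

_FLOAT_FORMAT = "%.17g"  # full double-precision round trip


def read_expression_matrix(path: str | os.PathLike) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    return mat


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "genotype": str, "batch": str})
    required = ["sample_id", "genotype", "aS", "batch"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if "chronological_time_h" not in sheet.columns:
        sheet["chronological_time_h"] = 48.0
    sheet["aS"] = sheet["aS"].astype(int).astype(bool)
    return sheet.set_index("sample_id")


def read_gene_map_bed(path: str | os.PathLike) -> GeneMap:
    """Read a BED gene map (0-based half-open, bp) into 1-based Mb midpoints."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chromosome", "start", "end", "gene_id"],
                      dtype={"chromosome": str, "gene_id": str})
    bad = set(bed["chromosome"]) - set(CHROMOSOMES)
    if bad:
        raise ValidationError(f"unknown chromosome label(s) in gene map: {sorted(bad)}")
    # midpoint of the 1-based inclusive interval [start+1, end], in Mb
    mid_bp = (bed["start"] + 1 + bed["end"]) / 2.0
    table = pd.DataFrame(
        {"chromosome": bed["chromosome"].to_numpy(),
         "position_mb": (mid_bp / 1e6).to_numpy()},
        index=pd.Index(bed["gene_id"], name="gene_id"),
    )
    return GeneMap(table=table)


def write_gene_map_bed(gene_map: GeneMap, path: str | os.PathLike) -> None:
    """Write a gene map back to BED (a 1 bp feature at the Mb position)."""
    pos_bp = np.rint(gene_map.table["position_mb"].to_numpy() * 1e6).astype(int)
    out = pd.DataFrame({
        "chromosome": gene_map.table["chromosome"].to_numpy(),
        "start": np.maximum(pos_bp - 1, 0),
        "end": pos_bp,
        "gene_id": gene_map.table.index,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_go_annotation(gene2go_path: str | os.PathLike,
                       term_path: str | os.PathLike) -> GOCatalog:
    g2g = pd.read_csv(gene2go_path, sep="\t", dtype=str)
    if list(g2g.columns[:2]) != ["gene_id", "go_id"]:
        raise ValidationError("gene-to-GO file must have columns gene_id, go_id")
    terms = pd.read_csv(term_path, sep="\t", dtype=str)
    for col in ("go_id", "description", "type"):
        if col not in terms.columns:
            raise ValidationError(f"GO term table missing column {col!r}")
    genes_by_term = g2g.groupby("go_id")["gene_id"].agg(frozenset)
    catalog = GOCatalog()
    for _, row in terms.iterrows():
        genes = genes_by_term.get(row["go_id"], frozenset())
        if not genes:
            continue  # term with no annotated genes carries no information
        catalog.terms[row["go_id"]] = GOTerm(
            go_id=row["go_id"], description=row["description"],
            type=row["type"], genes=genes)
    return catalog


def read_phenotype_table(path: str | os.PathLike) -> PhenotypeTable:
    table = pd.read_csv(path, dtype={"line": str, "genotype": str, "replicate": str,
                                     "phenotype_name": str},
                        float_precision="round_trip")
    table["aS"] = table["aS"].astype(int).astype(bool)
    return PhenotypeTable(table=table)


def read_survival_table(path: str | os.PathLike) -> SurvivalTable:
    table = pd.read_csv(path, dtype={"line": str, "genotype": str, "worm_id": str,
                                     "event": str}, float_precision="round_trip")
    table["aS"] = table["aS"].astype(int).astype(bool)
    return SurvivalTable(table=table)


def read_age_calibration(path: str | os.PathLike) -> pd.DataFrame:
    cal = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                      float_precision="round_trip")
    for col in ("gene_id", "slope", "intercept"):
        if col not in cal.columns:
            raise ValidationError(f"age calibration missing column {col!r}")
    return cal.set_index("gene_id")


def load_dataset(expression_path: str | os.PathLike,
                 sample_sheet_path: str | os.PathLike,
                 gene_map_path: str | os.PathLike | None = None,
                 go_gene2go_path: str | os.PathLike | None = None,
                 go_term_path: str | os.PathLike | None = None,
                 scale: str = "intensity",
                 ) -> tuple[ExpressionDataset, GeneMap | None, GOCatalog | None]:
    """Load and cross-validate the expression matrix, sample sheet and annexes.

    Column order of the returned matrix follows sample-sheet row order.
    Mismatched sample ids, missing values and unknown chromosome labels are
    hard errors naming the offenders.
    """
    matrix = read_expression_matrix(expression_path)
    samples = read_sample_sheet(sample_sheet_path)
    dataset = ExpressionDataset(matrix=matrix, samples=samples, scale=scale)
    gene_map = read_gene_map_bed(gene_map_path) if gene_map_path is not None else None
    catalog = None
    if go_gene2go_path is not None and go_term_path is not None:
        catalog = read_go_annotation(go_gene2go_path, go_term_path)
    return dataset, gene_map, catalog


def dataset_report(dataset: ExpressionDataset) -> dict:
    """Small summary of the loaded design: sizes and cell occupancy."""
    cells = dataset.design_cells()
    return {
        "n_genes": dataset.n_genes,
        "n_samples": dataset.n_samples,
        "n_genotypes": len(dataset.genotypes),
        "design_cells": {f"{g}:aS={int(a)}": int(n) for (g, a), n in cells.items()},
        "scale": dataset.scale,
    }


def write_results(table: pd.DataFrame, path: str | os.PathLike,
                  format: str = "tsv") -> None:
    """Write a results table as TSV (or CSV) with a header, full precision."""
    if table is None or len(table) == 0:
        raise ValidationError(f"refusing to write empty table to {path}")
    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        raise ValidationError(f"unknown output format {format!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    index = table.index.name is not None
    table.to_csv(path, sep=sep, index=index, float_format=_FLOAT_FORMAT)


def write_expression_dataset(dataset: ExpressionDataset, expression_path, sheet_path) -> None:
    mat = dataset.matrix.copy()
    mat.index.name = "gene_id"
    mat.to_csv(expression_path, sep="\t", float_format=_FLOAT_FORMAT)
    sheet = dataset.samples.copy()
    sheet = sheet.assign(aS=sheet["aS"].astype(int))
    sheet.index.name = "sample_id"
    sheet.to_csv(sheet_path, float_format=_FLOAT_FORMAT)
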
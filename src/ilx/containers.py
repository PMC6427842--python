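"""Shared data containers for the introgression-line expression pipeline.

The central object is :class:`ExpressionDataset`: a genes x samples matrix of
log2-scale expression values together with per-sample metadata (genotype,
transgene status, batch, chronological time).  All downstream stages — the
gene-wise factorial model, permutation FDR, age estimation, introgression
mapping — consume this container.  Auxiliary containers carry the gene map
(chromosome + Mb position), GO annotation, phenotype observations and
per-worm survival records.

Validation is performed at construction: matrices must be free of missing
values, identifiers unique, and metadata complete.  Errors name the offending
gene/sample so that malformed input files fail loudly and early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")

#: Expression value scale markers.  "intensity" = log2 intensities as
#: deposited; "ratio" = per-gene mean-centred log2 ratios (the scale the
#: factorial analysis and PCA operate on).
SCALE_INTENSITY = "intensity"
SCALE_RATIO = "ratio"

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "aS", "batch", "chronological_time_h")

SURVIVAL_EVENTS = ("death", "bagging", "crawloff")


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for a single array/sample."""

    sample_id: str
    genotype: str
    aS: bool
    batch: str
    chronological_time_h: float = 48.0


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: dict[str, int] = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    dups = sorted(k for k, c in seen.items() if c > 1)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionDataset:
    """Genes x samples log2 expression matrix with aligned sample metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by gene_id with one column per sample, log2 scale,
        no missing values.
    samples
        DataFrame indexed by sample_id with columns ``genotype``, ``aS``
        (bool), ``batch`` and ``chronological_time_h``; row order defines the
        column order of ``matrix``.
    scale
        Either ``"intensity"`` or ``"ratio"``; the mean-ratio transform is
        only legal on intensity-scale data (double-centring guard).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_INTENSITY

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_INTENSITY, SCALE_RATIO):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.matrix.index, "gene ids")
        _check_unique(self.samples.index, "sample ids")
        missing_cols = [c for c in ("genotype", "aS", "batch") if c not in self.samples.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet missing columns: {missing_cols}")
        if "chronological_time_h" not in self.samples.columns:
            self.samples = self.samples.assign(chronological_time_h=48.0)
        sheet_ids = list(self.samples.index)
        matrix_ids = list(self.matrix.columns)
        only_sheet = [s for s in sheet_ids if s not in set(matrix_ids)]
        only_matrix = [s for s in matrix_ids if s not in set(sheet_ids)]
        if only_sheet or only_matrix:
            raise ValidationError(
                "sample sheet / matrix id mismatch: "
                f"missing from matrix: {only_sheet or 'none'}; "
                f"missing from sample sheet: {only_matrix or 'none'}"
            )
        # column order always follows the sample sheet
        self.matrix = self.matrix.loc[:, sheet_ids]
        vals = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            gi, si = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.matrix.index[gi]!r}, "
                f"sample {self.matrix.columns[si]!r}"
            )
        self.samples = self.samples.copy()
        self.samples["aS"] = self.samples["aS"].astype(bool)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.samples["genotype"]))

    def values(self) -> np.ndarray:
        """Matrix as a float ndarray (genes x samples)."""
        return self.matrix.to_numpy(dtype=float)

    def design_cells(self) -> pd.Series:
        """Sample counts per (genotype, aS) cell."""
        return self.samples.groupby(["genotype", "aS"], observed=True).size()

    def with_matrix(self, matrix: pd.DataFrame, scale: str | None = None) -> "ExpressionDataset":
        return ExpressionDataset(matrix=matrix, samples=self.samples.copy(),
                                 scale=self.scale if scale is None else scale)

    def sample_meta(self) -> list[SampleMeta]:
        return [
            SampleMeta(sample_id=str(sid), genotype=str(r["genotype"]), aS=bool(r["aS"]),
                       batch=str(r["batch"]),
                       chronological_time_h=float(r["chronological_time_h"]))
            for sid, r in self.samples.iterrows()
        ]


@dataclass
class GeneMap:
    """Genomic positions of genes: chromosome (I-V, X) and 1-based Mb midpoint."""

    table: pd.DataFrame  # index gene_id, columns chromosome, position_mb

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene ids in gene map")
        bad = set(self.table["chromosome"]) - set(CHROMOSOMES)
        if bad:
            raise ValidationError(f"unknown chromosome label(s): {sorted(bad)}")
        if (self.table["position_mb"].to_numpy() < 0).any():
            raise ValidationError("negative position in gene map")

    def positions(self, gene_ids: Iterable[str]) -> pd.DataFrame:
        return self.table.loc[list(gene_ids)]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index


@dataclass(frozen=True)
class GOTerm:
    """One GO term: id, human-readable description, ontology type, gene set."""

    go_id: str
    description: str
    type: str  # BP | MF | CC
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.type not in ("BP", "MF", "CC"):
            raise ValidationError(f"GO type must be BP/MF/CC, got {self.type!r}")
        if not self.genes:
            raise ValidationError(f"GO term {self.go_id} has an empty gene set")


@dataclass
class GOCatalog:
    """Collection of GO terms with gene-to-term lookup."""

    terms: dict[str, GOTerm] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out


@dataclass
class PhenotypeTable:
    """Long-format phenotype observations.

    Columns: line, genotype, aS, replicate, phenotype_name, value, duration_s
    (duration required for count phenotypes such as pumping and thrashing).
    """

    table: pd.DataFrame

    COUNT_PHENOTYPES = ("pumping", "thrashing")

    def __post_init__(self) -> None:
        required = ["line", "genotype", "aS", "replicate", "phenotype_name", "value"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if "duration_s" not in self.table.columns:
            self.table = self.table.assign(duration_s=np.nan)
        if not np.isfinite(self.table["value"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite phenotype value")
        is_count = self.table["phenotype_name"].str.startswith(self.COUNT_PHENOTYPES)
        if is_count.any() and self.table.loc[is_count, "duration_s"].isna().any():
            raise ValidationError("count phenotypes require duration_s")
        self.table = self.table.copy()
        self.table["aS"] = self.table["aS"].astype(bool)

    def phenotype(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["phenotype_name"] == name]
        if sub.empty:
            raise KeyError(f"no observations for phenotype {name!r}")
        return sub

    def phenotype_names(self) -> list[str]:
        return list(pd.unique(self.table["phenotype_name"]))


@dataclass
class SurvivalTable:
    """Per-worm lifespan records with event type.

    ``event`` is one of death / bagging / crawloff.  Bagging (matricidal
    hatching) and crawl-off are right-censoring events for lifespan, but
    bagging additionally counts as an event in the bagging-rate analysis.
    """

    table: pd.DataFrame  # columns line, genotype, aS, worm_id, time_days, event

    def __post_init__(self) -> None:
        required = ["line", "genotype", "aS", "worm_id", "time_days", "event"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"survival table missing columns: {missing}")
        t = self.table["time_days"].to_numpy(dtype=float)
        if not (np.isfinite(t).all() and (t > 0).all()):
            raise ValidationError("survival times must be finite and positive")
        bad = set(self.table["event"]) - set(SURVIVAL_EVENTS)
        if bad:
            raise ValidationError(f"unknown survival event(s): {sorted(bad)}")
        self.table = self.table.copy()
        self.table["aS"] = self.table["aS"].astype(bool)

    def group(self, line: str | None = None, genotype: str | None = None,
              aS: bool | None = None) -> pd.DataFrame:
        sub = self.table
        if line is not None:
            sub = sub[sub["line"] == line]
        if genotype is not None:
            sub = sub[sub["genotype"] == genotype]
        if aS is not None:
            sub = sub[sub["aS"] == aS]
        return sub
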
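"""Hypergeometric GO-term enrichment on significance-defined gene groups.

Gene groups are selected from the factorial model output with a -log10(p)
threshold (default 2.0, i.e. p < 0.01).  Each GO term is tested with the
upper-tail hypergeometric probability: with a universe of N genes of which K
carry the term, a group of n genes containing k carriers has

    p = P(X >= k),  X ~ Hypergeom(N, K, n).

The tail is evaluated exactly with integer arithmetic (binomial
coefficients), so small configurations agree rationally with brute-force
enumeration; multiple testing is controlled with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GOCatalog, ValidationError
from .model import GeneExpressionLMResults

UNIVERSE_ALL = "all_genes_on_array"
UNIVERSE_ANNOTATED = "all_annotated_genes"


@dataclass
class EnrichmentConfig:
    """Group definition and reporting options for the enrichment stage."""

    neglog10p_threshold: float = 2.0
    universe: str = UNIVERSE_ANNOTATED
    min_overlap: int = 5
    adjustment: str = "fdr_bh"

    def __post_init__(self) -> None:
        if self.neglog10p_threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        if self.universe not in (UNIVERSE_ALL, UNIVERSE_ANNOTATED):
            raise ValidationError(f"unknown universe {self.universe!r}")


def select_significant_genes(results: GeneExpressionLMResults, term: str,
                             config: EnrichmentConfig | None = None) -> set[str]:
    """Genes with -log10(p) above the enrichment threshold for one model term."""
    config = config or EnrichmentConfig()
    hits = results.neg_log10_p(term) > config.neglog10p_threshold
    group = set(results.gene_ids[hits.to_numpy()])
    if not group:
        warnings.warn(f"no gene passes the enrichment threshold for term {term!r}",
                      stacklevel=2)
    return group


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), as a Fraction."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("invalid hypergeometric parameters")
    if k <= max(0, n + K - N):
        return Fraction(1)
    total = comb(N, n)
    upper = min(K, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, upper + 1))
    return Fraction(num, total)


def hypergeometric_enrichment(group: set[str], catalog: GOCatalog,
                              universe: set[str],
                              config: EnrichmentConfig | None = None,
                              ) -> pd.DataFrame:
    """Test every GO term for over-representation in ``group``.

    Annotation genes outside the universe are dropped (count logged as a
    warning); the group must be a subset of the universe.  Returns a
    DataFrame sorted by p with columns go_id, description, type, all_genes
    (K), group_genes (k), group_size (n), universe_size (N), p_value,
    adjusted_p and ``reported`` (False where the overlap is below the
    reporting minimum — kept in the full output, excluded from the ranked
    report).
    """
    config = config or EnrichmentConfig()
    if not group <= universe:
        raise ValidationError("gene group is not a subset of the universe")
    N = len(universe)
    n = len(group)
    rows = []
    n_dropped = 0
    for term in catalog:
        genes = term.genes & universe
        n_dropped += len(term.genes) - len(genes)
        if not genes:
            continue
        K = len(genes)
        k = len(genes & group)
        p = float(hypergeom_sf_exact(k, N, K, n))
        rows.append({"go_id": term.go_id, "description": term.description,
                     "type": term.type, "all_genes": K, "group_genes": k,
                     "group_size": n, "universe_size": N, "p_value": p})
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} annotation gene instance(s) outside "
                      "the universe", stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["go_id", "description", "type", "all_genes",
                                     "group_genes", "group_size", "universe_size",
                                     "p_value", "adjusted_p", "reported"])
    out = pd.DataFrame(rows)
    out["adjusted_p"] = adjust_pvalues(out["p_value"].to_numpy(), method=config.adjustment)
    out["reported"] = out["group_genes"] >= config.min_overlap
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out.index.name = "rank"
    return out


def adjust_pvalues(p: np.ndarray | list[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, >= raw p, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def build_universe(results: GeneExpressionLMResults, catalog: GOCatalog,
                   config: EnrichmentConfig | None = None) -> set[str]:
    """The enrichment universe: all array genes, or those with >= 1 annotation."""
    config = config or EnrichmentConfig()
    all_genes = set(results.gene_ids)
    if config.universe == UNIVERSE_ALL:
        return all_genes
    return all_genes & catalog.annotated_genes()
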
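"""Permutation-based significance thresholds via the FP/TP-ratio curve.

The significance cutoff for the gene-wise factorial model is chosen
empirically: sample labels (and with them the whole metadata row, including
the age covariate) are permuted, the full model is refit per permutation,
and for every candidate threshold tau on the -log10(p) scale the ratio

    ratio(tau) = FP(tau) / TP(tau)

is formed, where TP(tau) is the observed number of genes with
-log10(p) >= tau and FP(tau) the mean such count across permutations — a
plug-in estimate of the false discovery rate.  The selected threshold is the
smallest tau whose ratio drops to the target (default 0.05); the realized
per-term ratios at that tau are the empirical FDRs reported alongside.

Genes are then classified into the per-term significance sets (Age,
Genotype, aS, aS x Genotype) and the transgene-specific set: significant for
aS but for neither age nor genetic background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, ValidationError
from .model import (
    TERMS,
    DesignMatrix,
    GeneExpressionLMResults,
    fit_term_tests,
)


@dataclass
class PermutationPlan:
    """Reproducible set of sample-label permutations.

    ``scheme`` is ``"unrestricted"`` (any bijection of samples) or
    ``"within_batch"`` (labels only move inside their hybridization batch).
    """

    n_permutations: int = 100
    scheme: str = "unrestricted"
    seed: int = 0
    permutations: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("need at least one permutation")
        if self.scheme not in ("unrestricted", "within_batch"):
            raise ValidationError(f"unknown permutation scheme {self.scheme!r}")
        if self.n_permutations < 10:
            warnings.warn("fewer than 10 permutations: FP/TP ratio estimates "
                          "will be unstable", stacklevel=2)

    def realize(self, samples: pd.DataFrame) -> list[np.ndarray]:
        """Draw (or return the already-drawn) permutations for these samples."""
        if self.permutations:
            return self.permutations
        rng = np.random.default_rng(self.seed)
        n = len(samples)
        if self.scheme == "unrestricted":
            self.permutations = [rng.permutation(n) for _ in range(self.n_permutations)]
        else:
            batches = samples["batch"].to_numpy()
            groups = [np.flatnonzero(batches == b) for b in pd.unique(batches)]
            if all(len(g) == 1 for g in groups):
                warnings.warn("all batches are singletons: within-batch "
                              "permutations are all the identity", stacklevel=2)
            perms = []
            for _ in range(self.n_permutations):
                perm = np.arange(n)
                for g in groups:
                    perm[g] = g[rng.permutation(len(g))]
                perms.append(perm)
            self.permutations = perms
        return self.permutations


def permute_sample_labels(plan: PermutationPlan,
                          dataset: ExpressionDataset) -> Iterator[ExpressionDataset]:
    """Yield datasets whose matrix columns are permuted as one block.

    A single shared column permutation per iteration preserves gene-gene
    correlation; sample metadata stays attached to its position, so the
    permutation breaks the sample-to-metadata link wholesale.
    """
    for perm in plan.realize(dataset.samples):
        mat = pd.DataFrame(dataset.values()[:, perm], index=dataset.gene_ids,
                           columns=dataset.sample_ids)
        yield dataset.with_matrix(mat)


# ---------------------------------------------------------------------------

@dataclass
class ThresholdCurve:
    """FP/TP-ratio curves per model term.

    ``tables[term]`` has columns tau (ascending), TP, FP, ratio (NaN where
    TP = 0).  The sorted observed and pooled permuted -log10(p) arrays are
    retained so the curve can be evaluated at arbitrary tau.
    """

    tables: dict[str, pd.DataFrame]
    observed_sorted: dict[str, np.ndarray]
    permuted_sorted: dict[str, np.ndarray]
    n_permutations: int

    def tp(self, term: str, tau: float) -> int:
        obs = self.observed_sorted[term]
        return int(len(obs) - np.searchsorted(obs, tau, side="left"))

    def fp(self, term: str, tau: float) -> float:
        perm = self.permuted_sorted[term]
        count = len(perm) - np.searchsorted(perm, tau, side="left")
        return float(count) / self.n_permutations

    def ratio(self, term: str, tau: float) -> float:
        tp = self.tp(term, tau)
        return self.fp(term, tau) / tp if tp > 0 else np.nan


def fdr_threshold_curve(observed: GeneExpressionLMResults,
                        plan: PermutationPlan,
                        dataset: ExpressionDataset,
                        design: DesignMatrix) -> ThresholdCurve:
    """Refit the model under every permutation and build the ratio curves.

    The candidate tau grid per term is the sorted set of unique observed
    -log10(p) values; FP(tau) is averaged over permutations.
    """
    if list(design.sample_ids) != list(dataset.sample_ids):
        raise ValidationError("design does not match dataset sample order")
    Y = dataset.values()
    perms = plan.realize(dataset.samples)
    perm_values: dict[str, list[np.ndarray]] = {t: [] for t in TERMS}
    for perm in perms:
        tests = fit_term_tests(Y[:, perm], design, warn_constant=False)
        for t in TERMS:
            perm_values[t].append(tests[f"neglog10p_{t}"].to_numpy())

    tables: dict[str, pd.DataFrame] = {}
    observed_sorted: dict[str, np.ndarray] = {}
    permuted_sorted: dict[str, np.ndarray] = {}
    for t in TERMS:
        obs = np.sort(observed.neg_log10_p(t).to_numpy())
        pooled = np.sort(np.concatenate(perm_values[t]))
        taus = np.unique(obs)
        tp = len(obs) - np.searchsorted(obs, taus, side="left")
        fp = (len(pooled) - np.searchsorted(pooled, taus, side="left")) / len(perms)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(tp > 0, fp / np.maximum(tp, 1), np.nan)
        tables[t] = pd.DataFrame({"tau": taus, "TP": tp, "FP": fp, "ratio": ratio})
        observed_sorted[t] = obs
        permuted_sorted[t] = pooled
    return ThresholdCurve(tables=tables, observed_sorted=observed_sorted,
                          permuted_sorted=permuted_sorted,
                          n_permutations=len(perms))


@dataclass
class TermThreshold:
    term: str
    tau: float | None        # None: no tau reaches the target ratio
    ratio: float | None      # realized FP/TP ratio (empirical FDR) at tau
    n_genes: int


@dataclass
class ThresholdSelection:
    """Selected -log10(p) thresholds and their realized empirical FDRs."""

    mode: str                       # per_term | global
    target_ratio: float
    per_term: dict[str, TermThreshold]
    global_tau: float | None = None

    def tau_for(self, term: str) -> float | None:
        if self.mode == "global":
            return self.global_tau
        return self.per_term[term].tau

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for t, sel in self.per_term.items():
            rows.append({"term": t, "tau": sel.tau, "realized_fdr": sel.ratio,
                         "n_genes": sel.n_genes})
        out = pd.DataFrame(rows)
        out.index.name = "row"
        return out


def select_threshold(curve: ThresholdCurve, target_ratio: float = 0.05,
                     mode: str = "per_term",
                     terms: tuple[str, ...] = ("aS", "genotype", "aS:genotype"),
                     ) -> ThresholdSelection:
    """Pick the smallest qualifying tau.

    per_term: independently per term, the smallest grid tau with
    ratio <= target (TP = 0 points are skipped).  global: the smallest tau
    achieving ratio <= target simultaneously for all designated ``terms``;
    realized per-term ratios at that tau are reported for every term.
    """
    if mode not in ("per_term", "global"):
        raise ValidationError(f"unknown selection mode {mode!r}")
    per_term: dict[str, TermThreshold] = {}
    if mode == "per_term":
        for t, tab in curve.tables.items():
            ok = tab[(tab["TP"] > 0) & (tab["ratio"] <= target_ratio)]
            if ok.empty:
                per_term[t] = TermThreshold(term=t, tau=None, ratio=None, n_genes=0)
            else:
                row = ok.iloc[0]
                per_term[t] = TermThreshold(term=t, tau=float(row["tau"]),
                                            ratio=float(row["ratio"]),
                                            n_genes=int(row["TP"]))
        return ThresholdSelection(mode=mode, target_ratio=target_ratio,
                                  per_term=per_term)

    grid = np.unique(np.concatenate([curve.tables[t]["tau"].to_numpy() for t in terms]))
    global_tau = None
    for tau in grid:
        ratios = [curve.ratio(t, tau) for t in terms]
        if all(np.isfinite(r) and r <= target_ratio for r in ratios):
            global_tau = float(tau)
            break
    for t in curve.tables:
        if global_tau is None:
            per_term[t] = TermThreshold(term=t, tau=None, ratio=None, n_genes=0)
        else:
            r = curve.ratio(t, global_tau)
            per_term[t] = TermThreshold(term=t, tau=global_tau,
                                        ratio=None if np.isnan(r) else float(r),
                                        n_genes=curve.tp(t, global_tau))
    return ThresholdSelection(mode=mode, target_ratio=target_ratio,
                              per_term=per_term, global_tau=global_tau)


# ---------------------------------------------------------------------------

@dataclass
class GeneClassification:
    """Per-term significance sets plus the transgene-specific set and the
    Venn partition over {age, genotype, aS, aS:genotype}."""

    sets: dict[str, set[str]]
    aS_specific: set[str]
    venn_counts: dict[str, int]   # e.g. "aS&genotype" -> count; keys sorted by term order

    def set_sizes(self) -> dict[str, int]:
        out = {t: len(s) for t, s in self.sets.items()}
        out["aS_specific"] = len(self.aS_specific)
        return out


def classify_genes(results: GeneExpressionLMResults,
                   selection: ThresholdSelection,
                   exclude_interaction_from_specific: bool = False,
                   ) -> GeneClassification:
    """Assign genes to term sets at the selected thresholds.

    A gene joins a term's set iff its -log10(p) for that term is >= the
    term's tau (ties move together).  The transgene-specific set is the aS
    set minus the Age and Genotype sets; with
    ``exclude_interaction_from_specific`` the interaction set is subtracted
    as well.
    """
    sets: dict[str, set[str]] = {}
    for term in TERMS:
        tau = selection.tau_for(term)
        if tau is None:
            sets[term] = set()
            continue
        hits = results.neg_log10_p(term) >= tau
        sets[term] = set(results.gene_ids[hits.to_numpy()])
    specific = sets["aS"] - sets["age"] - sets["genotype"]
    if exclude_interaction_from_specific:
        specific = specific - sets["aS:genotype"]

    union = set().union(*sets.values())
    venn: dict[str, int] = {}
    for gene in union:
        key = "&".join(t for t in TERMS if gene in sets[t])
        venn[key] = venn.get(key, 0) + 1
    return GeneClassification(sets=sets, aS_specific=specific, venn_counts=venn)
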
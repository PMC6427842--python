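"""Gene-wise factorial linear model for expression matrices.

Each gene is fitted by ordinary least squares with the model

    expression ~ age + aS * genotype

where ``age`` is a continuous, mean-centred covariate (by default the
transcriptome-estimated developmental age), ``aS`` is the transgene flag and
``genotype`` the genetic background, treatment-coded against a reference
level (N2, aS = 0).  Per-term F statistics use Type II sums of squares: each
main effect is tested by comparing nested models that exclude any
higher-order term containing it, the interaction against the full model; the
denominator is the full-model residual mean square.  On the balanced design
of the study Type I/II/III coincide.

The engine is vectorised across genes: each nested model is orthogonalised
once (QR) and residual sums of squares for all genes follow from two matrix
products, which makes refitting under hundreds of sample-label permutations
cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionDataset, ValidationError, SCALE_INTENSITY, SCALE_RATIO

TERMS = ("age", "aS", "genotype", "aS:genotype")

_P_FLOOR = 1e-300  # keeps neg_log10_p finite for zero-residual fits


class RankDeficientDesignError(ValidationError):
    """Raised when the factorial design cannot identify all model terms."""


@dataclass
class DesignMatrix:
    """Samples x coefficients design with a term -> columns mapping."""

    X: np.ndarray
    columns: list[str]
    term_columns: dict[str, list[int]]
    genotype_levels: list[str]
    reference: str
    age_mean: float
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.X.shape[1]

    def term_df(self, term: str) -> int:
        return len(self.term_columns[term])

    def residual_df(self) -> int:
        return self.n_samples - self.n_coefficients


def build_design_matrix(samples: pd.DataFrame, age: np.ndarray | pd.Series,
                        reference: str = "N2") -> DesignMatrix:
    """Build the treatment-coded design for ``age + aS * genotype``.

    Columns: intercept, centred age, aS, genotype offsets (G-1) and
    aS x genotype interaction offsets (G-1).  Raises
    :class:`RankDeficientDesignError` naming the missing cell when a
    (genotype, aS) combination is unobserved, or the degenerate factor when a
    factor has a single level.
    """
    age = np.asarray(age, dtype=float)
    if age.shape[0] != len(samples):
        raise ValidationError("age vector length does not match sample count")
    if not np.isfinite(age).all():
        raise ValidationError("non-finite age value")

    genotypes = list(pd.unique(samples["genotype"]))
    if len(genotypes) < 2:
        raise RankDeficientDesignError("need >= 2 genotype levels, got "
                                       f"{genotypes}")
    as_levels = set(samples["aS"].astype(bool))
    if len(as_levels) < 2:
        raise RankDeficientDesignError(
            "factor aS has a single level "
            f"(all samples aS={int(next(iter(as_levels)))})")
    observed = set(map(tuple, samples[["genotype", "aS"]].itertuples(index=False)))
    missing = [(g, a) for g in genotypes for a in (False, True)
               if (g, a) not in observed]
    if missing:
        raise RankDeficientDesignError(
            "empty design cell(s): "
            + ", ".join(f"({g}, aS={int(a)})" for g, a in missing))

    if reference in genotypes:
        levels = [reference] + [g for g in genotypes if g != reference]
    else:
        levels = genotypes
    ref = levels[0]

    n = len(samples)
    as_col = samples["aS"].to_numpy(dtype=float)
    age_mean = float(age.mean())
    age_c = age - age_mean

    cols: list[np.ndarray] = [np.ones(n), age_c, as_col]
    names = ["Intercept", "age", "aS"]
    term_columns: dict[str, list[int]] = {"age": [1], "aS": [2]}
    geno = samples["genotype"].to_numpy()
    term_columns["genotype"] = []
    for g in levels[1:]:
        cols.append((geno == g).astype(float))
        term_columns["genotype"].append(len(names))
        names.append(f"genotype[T.{g}]")
    term_columns["aS:genotype"] = []
    for g in levels[1:]:
        cols.append(((geno == g) & (as_col > 0)).astype(float))
        term_columns["aS:genotype"].append(len(names))
        names.append(f"aS:genotype[T.{g}]")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError("design matrix is rank deficient")
    return DesignMatrix(X=X, columns=names, term_columns=term_columns,
                        genotype_levels=levels, reference=ref, age_mean=age_mean,
                        sample_ids=list(samples.index))


# ---------------------------------------------------------------------------
# Type II machinery

def _rss(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual sum of squares per gene for the column space spanned by Q."""
    total = np.einsum("gs,gs->g", Y, Y)
    proj = Y @ Q
    fitted = np.einsum("gk,gk->g", proj, proj)
    return np.maximum(total - fitted, 0.0)


def _submodel_q(X: np.ndarray, keep: list[int]) -> np.ndarray:
    Q, _ = np.linalg.qr(X[:, keep])
    return Q


def type2_nested_models(design: DesignMatrix) -> dict[str, tuple[list[int], list[int]]]:
    """Column index sets (with term, without term) for each Type II comparison."""
    tc = design.term_columns
    all_cols = list(range(design.n_coefficients))
    no_int = [c for c in all_cols if c not in tc["aS:genotype"]]
    models: dict[str, tuple[list[int], list[int]]] = {}
    # age: no higher-order term contains age -> adjust for everything else
    models["age"] = (all_cols, [c for c in all_cols if c not in tc["age"]])
    # aS and genotype: the interaction contains them, so it is excluded
    models["aS"] = (no_int, [c for c in no_int if c not in tc["aS"]])
    models["genotype"] = (no_int, [c for c in no_int if c not in tc["genotype"]])
    models["aS:genotype"] = (all_cols, no_int)
    return models


@dataclass
class GeneExpressionLMResults:
    """Per-gene results of the factorial fit.

    ``term_tests`` holds, for every gene and term, the Type II F statistic,
    p-value and -log10(p); ``params`` the full-model coefficient estimates
    (log2 units).
    """

    design: DesignMatrix
    term_tests: pd.DataFrame  # columns F_<term>, p_<term>, neglog10p_<term>
    params: pd.DataFrame      # genes x coefficients
    residual_df: int
    gene_ids: pd.Index = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_ids is None:
            self.gene_ids = self.term_tests.index

    def neg_log10_p(self, term: str) -> pd.Series:
        return self.term_tests[f"neglog10p_{term}"]

    def p_values(self, term: str) -> pd.Series:
        return self.term_tests[f"p_{term}"]

    def to_table(self) -> pd.DataFrame:
        """Flat output table: per-term statistics followed by coefficients."""
        return self.term_tests.join(self.params)

    def summary(self, alpha_neglog10: float = 2.0) -> str:
        lines = ["Gene-wise factorial model: expression ~ age + aS * genotype",
                 f"genes: {len(self.term_tests)}   samples: {self.design.n_samples}"
                 f"   residual df: {self.residual_df}",
                 f"reference level: {self.design.reference}, aS=0",
                 "",
                 f"{'term':>14} {'df':>4} {'median F':>10} "
                 f"{'genes -log10(p) > ' + str(alpha_neglog10):>24}"]
        for term in TERMS:
            f_med = float(np.median(self.term_tests[f"F_{term}"]))
            n_hit = int((self.term_tests[f"neglog10p_{term}"] > alpha_neglog10).sum())
            lines.append(f"{term:>14} {self.design.term_df(term):>4} "
                         f"{f_med:>10.3f} {n_hit:>24}")
        return "\n".join(lines)

    # convenience hook into the permutation-FDR stage
    def permutation_fdr(self, dataset: ExpressionDataset, **kwargs):
        from .fdr import fdr_threshold_curve, PermutationPlan
        plan = kwargs.pop("plan", None)
        if plan is None:
            plan = PermutationPlan(
                n_permutations=kwargs.pop("n_permutations", 100),
                scheme=kwargs.pop("scheme", "unrestricted"),
                seed=kwargs.pop("seed", 0))
        return fdr_threshold_curve(self, plan, dataset, self.design, **kwargs)


class GeneExpressionLM:
    """OLS model of ``expression ~ age + aS * genotype`` fitted per gene.

    Parameters
    ----------
    dataset
        Expression dataset; every sample needs genotype, aS and batch.
    age
        Per-sample continuous age covariate (hours).  Defaults to the
        sample sheet's ``chronological_time_h``; in the study pipeline the
        transcriptome-estimated age is passed instead.
    reference
        Reference genotype level (default N2).
    """

    def __init__(self, dataset: ExpressionDataset,
                 age: np.ndarray | pd.Series | None = None,
                 reference: str = "N2"):
        self.dataset = dataset
        if age is None:
            age = dataset.samples["chronological_time_h"]
        if isinstance(age, pd.Series):
            age = age.reindex(dataset.sample_ids).to_numpy(dtype=float)
        self.age = np.asarray(age, dtype=float)
        self.design = build_design_matrix(dataset.samples, self.age, reference=reference)
        if self.design.residual_df() <= 0:
            raise ValidationError(
                f"residual df {self.design.residual_df()} <= 0: "
                "more coefficients than samples")

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset, **kwargs) -> "GeneExpressionLM":
        return cls(dataset, **kwargs)

    def fit(self) -> GeneExpressionLMResults:
        Y = self.dataset.values()
        tests = fit_term_tests(Y, self.design)
        tests.index = self.dataset.gene_ids
        params = _fit_params(Y, self.design)
        params.index = self.dataset.gene_ids
        return GeneExpressionLMResults(design=self.design, term_tests=tests,
                                       params=params,
                                       residual_df=self.design.residual_df())


def fit_term_tests(Y: np.ndarray, design: DesignMatrix,
                   warn_constant: bool = True) -> pd.DataFrame:
    """Type II F and p per term for a genes x samples value matrix.

    Constant (zero-variance) genes get p = 1 for every term with a warning.
    """
    n_genes = Y.shape[0]
    if Y.shape[1] != design.n_samples:
        raise ValidationError("matrix sample dimension does not match design")
    df_resid = design.residual_df()
    if df_resid <= 0:
        raise ValidationError("residual df <= 0")
    models = type2_nested_models(design)
    q_cache: dict[tuple[int, ...], np.ndarray] = {}

    def q_for(cols: list[int]) -> np.ndarray:
        key = tuple(cols)
        if key not in q_cache:
            q_cache[key] = _submodel_q(design.X, cols)
        return q_cache[key]

    rss_full = _rss(Y, q_for(list(range(design.n_coefficients))))
    constant = Y.std(axis=1) == 0.0
    if constant.any() and warn_constant:
        warnings.warn(f"{int(constant.sum())} constant gene(s): p set to 1",
                      stacklevel=2)

    out: dict[str, np.ndarray] = {}
    mse = rss_full / df_resid
    for term in TERMS:
        with_cols, without_cols = models[term]
        ss = _rss(Y, q_for(without_cols)) - _rss(Y, q_for(with_cols))
        ss = np.maximum(ss, 0.0)
        df_term = design.term_df(term)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_term) / mse
        F = np.where(np.isnan(F), 0.0, F)  # 0/0: no signal, no residual
        p = stats.f.sf(F, df_term, df_resid)
        p = np.where(constant, 1.0, p)
        F = np.where(constant, 0.0, F)
        out[f"F_{term}"] = F
        out[f"p_{term}"] = p
        out[f"neglog10p_{term}"] = -np.log10(np.maximum(p, _P_FLOOR))
    return pd.DataFrame(out)


def _fit_params(Y: np.ndarray, design: DesignMatrix) -> pd.DataFrame:
    beta, *_ = np.linalg.lstsq(design.X, Y.T, rcond=None)
    return pd.DataFrame(beta.T, columns=design.columns)


# ---------------------------------------------------------------------------

def mean_ratio_transform(dataset: ExpressionDataset) -> ExpressionDataset:
    """Subtract each gene's across-sample mean: log2 ratios with the mean.

    Only legal on intensity-scale data; re-centring an already-ratio dataset
    is blocked (double-centring guard), although the operation would be a
    value-level no-op.
    """
    if dataset.scale == SCALE_RATIO:
        raise ValidationError("dataset is already on the mean-ratio scale")
    assert dataset.scale == SCALE_INTENSITY
    mat = dataset.matrix.sub(dataset.matrix.mean(axis=1), axis=0)
    return dataset.with_matrix(mat, scale=SCALE_RATIO)
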
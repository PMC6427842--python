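"""Phenotype and survival statistics.

The life-history phenotypes (development time, pharyngeal pumping,
thrashing, lifespan) are analysed with the factorial model
``phenotype ~ aS * genotype``: a two-way ANOVA (Type II sums of squares,
robust to the unbalanced group sizes censoring produces) for overall
effects, followed by Tukey HSD over all (genotype x transgene) groups with
the within-genotype wild-type vs transgenic contrasts extracted.  Survival
uses the Kaplan-Meier product-limit estimator with bagging (matricidal
hatching) and crawl-off treated as right-censoring, pairwise log-rank tests
(optionally restricted to the first d days by administrative censoring), and
a Fisher exact comparison of bagging rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import PhenotypeTable, SurvivalTable, ValidationError


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA of a phenotype."""

    phenotype_name: str
    table: pd.DataFrame       # index term: sum_sq, df, F, p
    cell_means: pd.DataFrame  # genotype x aS means
    residual_ss: float
    residual_df: int

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def summary(self) -> str:
        lines = [f"ANOVA: {self.phenotype_name} ~ aS * genotype (Type II SS)"]
        for term in ("aS", "genotype", "aS:genotype"):
            row = self.table.loc[term]
            lines.append(f"  {term:>12}: F({int(row['df'])}, {self.residual_df}) "
                         f"= {row['F']:.4g}, p = {row['p']:.4g}")
        return "\n".join(lines)


def _require_full_design(df: pd.DataFrame, what: str) -> None:
    counts = df.groupby(["genotype", "aS"], observed=True).size()
    genotypes = pd.unique(df["genotype"])
    missing = [(g, a) for g in genotypes for a in (False, True)
               if (g, a) not in counts.index]
    if missing:
        raise ValidationError(
            f"{what}: empty design cell(s) "
            + ", ".join(f"({g}, aS={int(a)})" for g, a in missing))


def two_way_anova(table: PhenotypeTable, phenotype_name: str) -> AnovaResult:
    """Fit ``value ~ aS * genotype`` and return Type II per-term F tests."""
    df = table.phenotype(phenotype_name).copy()
    if df["genotype"].nunique() < 2:
        raise ValidationError("need >= 2 genotype levels")
    if df["aS"].nunique() < 2:
        raise ValidationError("need both aS levels")
    _require_full_design(df, phenotype_name)
    df["aS"] = df["aS"].astype(int)
    n_cells = df.groupby(["genotype", "aS"], observed=True).ngroups
    if len(df) - n_cells <= 0:
        raise ValidationError("zero residual degrees of freedom")
    fit = smf.ols("value ~ C(aS) * C(genotype)", data=df).fit()
    if np.allclose(df["value"].var(ddof=0), 0.0):
        # degenerate: identical values everywhere -> no evidence for any term
        terms = ["aS", "genotype", "aS:genotype"]
        aov = pd.DataFrame({"sum_sq": 0.0, "df": [1, df["genotype"].nunique() - 1,
                                                  df["genotype"].nunique() - 1],
                            "F": 0.0, "p": 1.0}, index=terms)
        resid_ss, resid_df = 0.0, int(fit.df_resid)
    else:
        aov = sm.stats.anova_lm(fit, typ=2)
        aov = aov.rename(index={"C(aS)": "aS", "C(genotype)": "genotype",
                                "C(aS):C(genotype)": "aS:genotype"},
                         columns={"PR(>F)": "p"})
        resid_ss = float(aov.loc["Residual", "sum_sq"])
        resid_df = int(aov.loc["Residual", "df"])
        aov = aov.drop(index="Residual")
    means = df.groupby(["genotype", "aS"], observed=True)["value"].mean().unstack()
    return AnovaResult(phenotype_name=phenotype_name, table=aov, cell_means=means,
                       residual_ss=resid_ss, residual_df=resid_df)


@dataclass
class TukeyContrast:
    genotype: str
    wt_mean: float
    as_mean: float
    difference: float   # aS - WT
    adjusted_p: float


def tukey_within_genotype(table: PhenotypeTable, phenotype_name: str,
                          ) -> tuple[list[TukeyContrast], pd.DataFrame]:
    """Tukey HSD over all (genotype, aS) groups; extract WT-vs-aS per genotype.

    The studentized-range adjustment runs over the full family of pairwise
    group comparisons; the contrasts of interest — wild type against the
    transgenic line within each background — are pulled out with their
    family-adjusted p-values.  The full pairwise table is returned alongside.
    """
    df = table.phenotype(phenotype_name).copy()
    df["group"] = df["genotype"].astype(str) + "|" + df["aS"].map({True: "aS", False: "WT"})
    sizes = df.groupby("group").size()
    if (sizes < 2).any():
        bad = list(sizes.index[sizes < 2])
        raise ValidationError(f"group(s) with a single observation: {bad}")
    res = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    full = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    full["p-adj"] = np.asarray(res.pvalues, dtype=float)  # unrounded
    contrasts = []
    means = df.groupby("group")["value"].mean()
    for genotype in pd.unique(df["genotype"]):
        g_wt, g_as = f"{genotype}|WT", f"{genotype}|aS"
        if g_wt not in means.index or g_as not in means.index:
            continue
        row = full[((full["group1"] == g_wt) & (full["group2"] == g_as))
                   | ((full["group1"] == g_as) & (full["group2"] == g_wt))]
        adj_p = float(row["p-adj"].iloc[0])
        contrasts.append(TukeyContrast(
            genotype=str(genotype), wt_mean=float(means[g_wt]),
            as_mean=float(means[g_as]),
            difference=float(means[g_as] - means[g_wt]), adjusted_p=adj_p))
    return contrasts, full


# ---------------------------------------------------------------------------
# survival

@dataclass
class KMCurve:
    """Kaplan-Meier curve for one group of worms."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    n_worms: int
    n_deaths: int
    mean_lifespan_days: float | None  # over death events only; None if no deaths

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def _duration_event(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = df["time_days"].to_numpy(dtype=float)
    observed = (df["event"] == "death").to_numpy()
    return t, observed


def kaplan_meier(table: SurvivalTable, line: str | None = None,
                 genotype: str | None = None, aS: bool | None = None,
                 group_label: str | None = None) -> KMCurve:
    """Product-limit survival estimate for one group.

    Bagging and crawl-off records censor at their time.  The mean lifespan is
    computed over death events only and is None when every worm is censored.
    """
    df = table.group(line=line, genotype=genotype, aS=aS)
    if df.empty:
        raise ValidationError("no worms in the requested group")
    t, observed = _duration_event(df)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    deaths = t[observed]
    label = group_label or (line or f"{genotype}:aS={aS}")
    return KMCurve(group=label, times=times, survival=surv, at_risk=at_risk,
                   censor_times=np.sort(t[~observed]), n_worms=len(df),
                   n_deaths=int(observed.sum()),
                   mean_lifespan_days=float(deaths.mean()) if observed.any() else None)


@dataclass
class LogrankResult:
    group_a: str
    group_b: str
    statistic: float
    p: float
    df: int = 1
    restrict_days: float | None = None


def logrank(table: SurvivalTable, group_a: dict, group_b: dict,
            restrict_days: float | None = None) -> LogrankResult:
    """Log-rank test between two groups selected by line/genotype/aS filters.

    ``restrict_days`` administratively censors every observation at the bound
    before testing (the "first d days" analysis), preserving risk sets.
    """
    df_a = table.group(**group_a)
    df_b = table.group(**group_b)
    if df_a.empty or df_b.empty:
        raise ValidationError("empty survival group")
    ta, ea = _duration_event(df_a)
    tb, eb = _duration_event(df_b)
    if restrict_days is not None:
        ea = ea & (ta <= restrict_days)
        eb = eb & (tb <= restrict_days)
        ta = np.minimum(ta, restrict_days)
        tb = np.minimum(tb, restrict_days)
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("no death events within the restriction")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(group_a=str(group_a), group_b=str(group_b),
                         statistic=float(res.test_statistic), p=float(res.p_value),
                         restrict_days=restrict_days)


@dataclass
class BaggingComparison:
    genotype: str
    wt_rate: float
    as_rate: float
    difference_pct_points: float  # aS - WT, percentage points
    p: float
    wt_counts: tuple[int, int]    # (bagged, total)
    as_counts: tuple[int, int]


def bagging_rate_test(table: SurvivalTable, genotype: str) -> BaggingComparison:
    """Fisher exact comparison of bagging rates between WT and aS lines."""
    wt = table.group(genotype=genotype, aS=False)
    tg = table.group(genotype=genotype, aS=True)
    if wt.empty or tg.empty:
        raise ValidationError(f"both WT and aS worms needed for {genotype}")
    wt_bag = int((wt["event"] == "bagging").sum())
    tg_bag = int((tg["event"] == "bagging").sum())
    n_wt, n_tg = len(wt), len(tg)
    _, p = stats.fisher_exact([[tg_bag, n_tg - tg_bag], [wt_bag, n_wt - wt_bag]],
                              alternative="two-sided")
    wt_rate = wt_bag / n_wt
    as_rate = tg_bag / n_tg
    return BaggingComparison(genotype=genotype, wt_rate=wt_rate, as_rate=as_rate,
                             difference_pct_points=100.0 * (as_rate - wt_rate),
                             p=float(p), wt_counts=(wt_bag, n_wt),
                             as_counts=(tg_bag, n_tg))


def mean_lifespan_test(table: SurvivalTable, genotype: str,
                       method: str = "welch") -> tuple[float, float]:
    """Compare mean lifespan (death events only) between WT and aS lines.

    ``method="welch"`` runs a Welch two-sample t-test; ``method="tukey"``
    embeds the contrast in the all-groups Tukey family over every
    (genotype, aS) group in the table.  Returns (difference aS - WT, p).
    """
    wt = table.group(genotype=genotype, aS=False)
    tg = table.group(genotype=genotype, aS=True)
    wt_d = wt.loc[wt["event"] == "death", "time_days"].to_numpy()
    tg_d = tg.loc[tg["event"] == "death", "time_days"].to_numpy()
    if len(wt_d) < 2 or len(tg_d) < 2:
        raise ValidationError("need >= 2 deaths per line for the mean comparison")
    diff = float(tg_d.mean() - wt_d.mean())
    if method == "welch":
        _, p = stats.ttest_ind(tg_d, wt_d, equal_var=False)
        return diff, float(p)
    if method == "tukey":
        deaths = table.table[table.table["event"] == "death"]
        pheno = PhenotypeTable(table=pd.DataFrame({
            "line": deaths["line"], "genotype": deaths["genotype"],
            "aS": deaths["aS"], "replicate": "rep1",
            "phenotype_name": "lifespan_days",
            "value": deaths["time_days"], "duration_s": np.nan}))
        contrasts, _ = tukey_within_genotype(pheno, "lifespan_days")
        for c in contrasts:
            if c.genotype == genotype:
                return diff, c.adjusted_p
        raise ValidationError(f"genotype {genotype} not in Tukey family")
    raise ValidationError(f"unknown method {method!r}")
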
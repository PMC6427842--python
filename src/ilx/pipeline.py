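"""End-to-end orchestration of the introgression-line analysis.

Stages, in dependency order: obtain data (synthetic generator or files) →
mean-ratio transform + PCA → developmental age estimation → gene-wise
factorial model (with estimated age as the covariate) → permutation FDR,
threshold selection and Venn classification → GO enrichment of the
transgene-responsive group → introgression mapping from wild-isolate
markers → phenotype ANOVA/Tukey and survival statistics.  Every stage's
table is written as TSV; when the input is synthetic, a truth-comparison
appendix (false-discovery proportion, age-recovery error, interval-recovery
error) is added.

The whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .age import AgeCalibration, age_contrast_summary, estimate_sample_ages
from .containers import ExpressionDataset, GeneMap, GOCatalog, ValidationError
from .enrichment import (
    EnrichmentConfig,
    build_universe,
    hypergeometric_enrichment,
    select_significant_genes,
)
from .fdr import (
    PermutationPlan,
    ThresholdSelection,
    classify_genes,
    fdr_threshold_curve,
    select_threshold,
)
from .introgression import (
    call_marker_presence,
    detect_introgression_intervals,
    intervals_to_table,
)
from .io import write_results
from .model import GeneExpressionLM, mean_ratio_transform
from .phenostats import (
    bagging_rate_test,
    kaplan_meier,
    logrank,
    tukey_within_genotype,
    two_way_anova,
)
from .simulate import (
    SimulationConfig,
    age_calibration_from_truth,
    marker_gene_list,
    simulate_expression_experiment,
    simulate_go_catalog,
    simulate_phenotypes,
    simulate_survival,
)

logger = logging.getLogger("ilx")


@dataclass
class PcaScores:
    """First two principal-component scores of the sample profiles."""

    scores: pd.DataFrame            # index sample_id: PC1, PC2
    variance_fractions: np.ndarray  # all components, non-increasing
    loadings: pd.DataFrame          # genes x (PC1, PC2)


def pca_scores(dataset: ExpressionDataset) -> PcaScores:
    """PCA of the mean-ratio expression profiles (samples as observations).

    Requires ratio-scale data (the transform guard enforces single
    centring) and at least 3 samples.  Component signs are fixed by making
    each component's largest-magnitude gene loading positive, so scores are
    fully deterministic.
    """
    if dataset.scale != "ratio":
        raise ValidationError("PCA expects mean-ratio transformed data; "
                              "apply mean_ratio_transform first")
    if dataset.n_samples < 3:
        raise ValidationError("PCA needs at least 3 samples")
    M = dataset.values().T  # samples x genes, gene means already zero
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    var = S ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    # sign convention: largest-|loading| gene positive per component
    for j in range(min(2, Vt.shape[0])):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    n_comp = min(2, U.shape[1])
    scores = pd.DataFrame(U[:, :n_comp] * S[:n_comp],
                          index=dataset.sample_ids,
                          columns=[f"PC{j + 1}" for j in range(n_comp)])
    loadings = pd.DataFrame(Vt[:n_comp].T, index=dataset.gene_ids,
                            columns=[f"PC{j + 1}" for j in range(n_comp)])
    return PcaScores(scores=scores, variance_fractions=frac, loadings=loadings)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one input route: a :class:`SimulationConfig` (synthetic run with
    truth appendix) or a mapping of input file paths (expression, sample
    sheet, gene map, GO files, calibration, marker list, phenotype and
    survival tables).
    """

    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None
    output_dir: str = "ilx_out"
    seed: int = 0
    n_permutations: int = 100
    target_ratio: float = 0.05
    selection_mode: str = "per_term"
    permutation_scheme: str = "unrestricted"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    use_estimated_age: bool = True
    min_run: int = 3

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ValidationError(
                "exactly one of simulation config or input paths must be given")
        if self.simulation is not None:
            self.simulation.seed = self.seed


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage TSVs and a JSON report.

    Returns the report as a dict.  A stage failure aborts with the stage
    name in the exception message; outputs of completed stages remain on
    disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("data")
        data = _obtain_data(config)
    except Exception as e:
        raise RuntimeError(f"stage 'data' failed: {e}") from e
    dataset: ExpressionDataset = data["dataset"]
    report["n_genes"] = dataset.n_genes
    report["n_samples"] = dataset.n_samples

    def run_stage(name, fn):
        stage(name)
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    # transform + PCA ------------------------------------------------------
    ratios = run_stage("mean_ratio_transform", lambda: mean_ratio_transform(dataset))
    pca = run_stage("pca", lambda: pca_scores(ratios))
    write_results(pca.scores.rename_axis("sample_id"), out / "pca_scores.tsv")
    report["pca_variance_fractions"] = [float(v) for v in pca.variance_fractions[:2]]

    # age ------------------------------------------------------------------
    calibration: AgeCalibration | None = data.get("calibration")
    ages = None
    if calibration is not None:
        ages = run_stage("age_estimation",
                         lambda: estimate_sample_ages(dataset, calibration))
        write_results(ages.table.rename_axis("sample_id"), out / "estimated_ages.tsv")
        aov = age_contrast_summary(ages, dataset.samples)
        write_results(aov.table.rename_axis("term"), out / "age_anova.tsv")
        report["age_anova_p"] = {t: aov.p(t) for t in ("aS", "genotype", "aS:genotype")}

    # factorial model ------------------------------------------------------
    age_vec = ages.ages() if (ages is not None and config.use_estimated_age) else None
    model = run_stage("fit", lambda: GeneExpressionLM(dataset, age=age_vec))
    results = model.fit()
    write_results(results.to_table().rename_axis("gene_id"), out / "gene_term_tests.tsv")

    # permutation FDR ------------------------------------------------------
    plan = PermutationPlan(n_permutations=config.n_permutations,
                           scheme=config.permutation_scheme, seed=config.seed)
    curve = run_stage("permutation_fdr",
                      lambda: fdr_threshold_curve(results, plan, dataset, model.design))
    for term, tab in curve.tables.items():
        write_results(tab.rename_axis("row"),
                      out / f"threshold_curve_{term.replace(':', 'x')}.tsv")
    selection: ThresholdSelection = run_stage(
        "select_threshold",
        lambda: select_threshold(curve, target_ratio=config.target_ratio,
                                 mode=config.selection_mode))
    write_results(selection.summary_table(), out / "threshold_selection.tsv")
    classification = run_stage("classify",
                               lambda: classify_genes(results, selection))
    report["threshold"] = {
        t: {"tau": s.tau, "realized_fdr": s.ratio, "n_genes": s.n_genes}
        for t, s in selection.per_term.items()}
    report["venn_set_sizes"] = classification.set_sizes()
    report["venn_partition"] = classification.venn_counts
    sets_rows = [{"term": t, "gene_id": g}
                 for t, genes in classification.sets.items() for g in sorted(genes)]
    sets_rows += [{"term": "aS_specific", "gene_id": g}
                  for g in sorted(classification.aS_specific)]
    if sets_rows:
        tbl = pd.DataFrame(sets_rows)
        tbl.index.name = "row"
        write_results(tbl, out / "gene_sets.tsv")

    # enrichment -----------------------------------------------------------
    catalog: GOCatalog | None = data.get("catalog")
    if catalog is not None and len(catalog) > 0:
        def _enrich():
            group = select_significant_genes(results, "aS", config.enrichment)
            universe = build_universe(results, catalog, config.enrichment)
            return hypergeometric_enrichment(group & universe, catalog, universe,
                                             config.enrichment)
        enr = run_stage("enrichment", _enrich)
        if len(enr):
            write_results(enr, out / "enrichment_aS.tsv")
            report["enrichment_top_terms"] = enr[enr["reported"]].head(5)[
                ["go_id", "p_value", "adjusted_p"]].to_dict("records")

    # introgression --------------------------------------------------------
    gene_map: GeneMap | None = data.get("gene_map")
    markers: list[str] | None = data.get("marker_genes")
    intervals = []
    if gene_map is not None and markers:
        def _introgress():
            ivs = []
            for genotype in dataset.genotypes:
                if genotype == "N2":
                    continue
                calls = call_marker_presence(dataset, markers, genotype, genotype)
                ivs.extend(detect_introgression_intervals(
                    calls, gene_map, line=genotype, min_run=config.min_run))
            return ivs
        intervals = run_stage("introgression", _introgress)
        if intervals:
            write_results(intervals_to_table(intervals), out / "introgression_intervals.tsv")
        report["introgression_intervals"] = [
            {"line": iv.line, "chromosome": iv.chromosome,
             "start_mb": iv.start_mb, "end_mb": iv.end_mb} for iv in intervals]

    # phenotypes -----------------------------------------------------------
    phenotypes = data.get("phenotypes")
    if phenotypes is not None:
        def _pheno():
            rep = {}
            for name in phenotypes.phenotype_names():
                aov = two_way_anova(phenotypes, name)
                write_results(aov.table.rename_axis("term"), out / f"anova_{name}.tsv")
                contrasts, _ = tukey_within_genotype(phenotypes, name)
                ctab = pd.DataFrame([c.__dict__ for c in contrasts])
                ctab.index.name = "row"
                write_results(ctab, out / f"tukey_{name}.tsv")
                rep[name] = {
                    "anova_p": {t: aov.p(t) for t in ("aS", "genotype", "aS:genotype")},
                    "tukey_p": {c.genotype: c.adjusted_p for c in contrasts}}
            return rep
        report["phenotypes"] = run_stage("phenotypes", _pheno)

    survival = data.get("survival")
    if survival is not None:
        def _surv():
            rep = {}
            km_rows = []
            for genotype in pd.unique(survival.table["genotype"]):
                lr = logrank(survival, {"genotype": genotype, "aS": False},
                             {"genotype": genotype, "aS": True})
                bag = bagging_rate_test(survival, genotype)
                for aS in (False, True):
                    km = kaplan_meier(survival, genotype=genotype, aS=aS)
                    for t, sv in zip(km.times, km.survival):
                        km_rows.append({"group": km.group, "time_days": t,
                                        "survival": sv})
                rep[genotype] = {"logrank_p": lr.p,
                                 "bagging_difference_pct": bag.difference_pct_points,
                                 "bagging_p": bag.p}
            km_tab = pd.DataFrame(km_rows)
            km_tab.index.name = "row"
            write_results(km_tab, out / "km_curves.tsv")
            return rep
        report["survival"] = run_stage("survival", _surv)

    # truth appendix -------------------------------------------------------
    if data.get("truth") is not None:
        report["truth_comparison"] = run_stage(
            "truth_comparison",
            lambda: _truth_appendix(data, results, selection, classification,
                                    ages, intervals))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _obtain_data(config: PipelineConfig) -> dict:
    if config.simulation is not None:
        sim = config.simulation
        dataset, gene_map, truth = simulate_expression_experiment(sim)
        calibration = AgeCalibration(table=age_calibration_from_truth(truth, sim))
        phenotypes, pheno_truth = simulate_phenotypes(sim)
        survival, surv_truth = simulate_survival(sim)
        catalog = simulate_go_catalog(truth, sim)
        return {"dataset": dataset, "gene_map": gene_map, "truth": truth,
                "calibration": calibration, "marker_genes": marker_gene_list(truth),
                "phenotypes": phenotypes, "survival": survival,
                "catalog": catalog, "pheno_truth": pheno_truth,
                "surv_truth": surv_truth, "sim_config": sim}
    from . import io as _io
    paths = config.input_paths
    dataset, gene_map, catalog = _io.load_dataset(
        paths["expression"], paths["sample_sheet"],
        paths.get("gene_map"), paths.get("go_gene2go"), paths.get("go_terms"))
    data: dict = {"dataset": dataset, "gene_map": gene_map, "catalog": catalog,
                  "truth": None}
    if paths.get("age_calibration"):
        data["calibration"] = AgeCalibration(
            table=_io.read_age_calibration(paths["age_calibration"]))
    if paths.get("marker_genes"):
        data["marker_genes"] = list(
            pd.read_csv(paths["marker_genes"], sep="\t", dtype=str)["gene_id"])
    if paths.get("phenotypes"):
        data["phenotypes"] = _io.read_phenotype_table(paths["phenotypes"])
    if paths.get("survival"):
        data["survival"] = _io.read_survival_table(paths["survival"])
    return data


def _truth_appendix(data: dict, results, selection, classification, ages,
                    intervals) -> dict:
    truth: pd.DataFrame = data["truth"]
    sim: SimulationConfig = data["sim_config"]
    out: dict = {}

    int_cols = [c for c in truth.columns if c.startswith("beta_int_")]
    any_transgene = truth["is_aS"] | (truth[int_cols].abs().sum(axis=1) > 0)
    true_for_term = {
        "age": truth["is_age"],
        # markers carry background-specific offsets, hence genotype signal;
        # inside introgression blocks their transgene response is
        # genotype-dependent, hence interaction signal; interaction genes
        # differ between genotypes among transgenic samples, hence also
        # carry genotype main-effect signal
        "genotype": truth["is_genotype"] | truth["is_marker"] | truth["is_interaction"],
        "aS": any_transgene,
        "aS:genotype": truth["is_interaction"] | truth["is_marker"],
    }
    fdp = {}
    for term, mask in true_for_term.items():
        called = classification.sets[term]
        if not called:
            fdp[term] = None
            continue
        true_ids = set(truth.index[mask])
        fdp[term] = len(called - true_ids) / len(called)
    out["false_discovery_proportion"] = fdp

    if ages is not None and "true_age_h" in data["dataset"].samples:
        err = (ages.ages().to_numpy()
               - data["dataset"].samples["true_age_h"].to_numpy())
        out["age_mean_abs_error_h"] = float(np.abs(err).mean())

    if intervals:
        errors = []
        for iv in intervals:
            for blk in sim.marker_blocks.get(iv.line, ()):
                if blk.chromosome == iv.chromosome:
                    errors.append(max(abs(iv.start_mb - blk.start_mb),
                                      abs(iv.end_mb - blk.end_mb)))
        if errors:
            out["interval_max_boundary_error_mb"] = float(np.max(errors))
    return out
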
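"""Permutation machinery, FP/TP-ratio curves, threshold selection, Venn sets."""

import numpy as np
import pandas as pd
import pytest

from ilx import (
    GeneExpressionLM,
    PermutationPlan,
    SimulationConfig,
    classify_genes,
    fdr_threshold_curve,
    permute_sample_labels,
    select_threshold,
    simulate_expression_experiment,
)
from ilx.fdr import TermThreshold, ThresholdCurve, ThresholdSelection

from conftest import make_dataset, make_sample_sheet


def _small_null_fit(seed=0, n_genes=300):
    rng = np.random.default_rng(seed)
    sheet = make_sample_sheet()
    age = rng.uniform(47, 53, size=len(sheet))
    ds = make_dataset(rng.normal(0, 1, size=(n_genes, len(sheet))), sheet)
    model = GeneExpressionLM(ds, age=age)
    return ds, model, model.fit()


class TestPermutationPlan:
    def test_permutations_preserve_value_multiset(self):
        ds, _, _ = _small_null_fit()
        plan = PermutationPlan(n_permutations=10, seed=1)
        for permuted in permute_sample_labels(plan, ds):
            np.testing.assert_array_equal(np.sort(permuted.values(), axis=1),
                                          np.sort(ds.values(), axis=1))

    def test_fixed_seed_reproduces_permutation_sequence(self):
        ds, _, _ = _small_null_fit()
        a = PermutationPlan(n_permutations=5, seed=3).realize(ds.samples)
        b = PermutationPlan(n_permutations=5, seed=3).realize(ds.samples)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_within_batch_never_crosses_batches(self):
        sheet = make_sample_sheet(genotypes=("N2", "JU1511", "JU1926", "JU1931",
                                             "JU1941"))
        assert len(sheet) == 30  # batches rep1/rep2/rep3, 10 samples each
        plan = PermutationPlan(n_permutations=20, scheme="within_batch", seed=2)
        batches = sheet["batch"].to_numpy()
        for perm in plan.realize(sheet):
            assert (batches[perm] == batches).all()

    def test_each_permutation_is_a_bijection(self):
        ds, _, _ = _small_null_fit()
        for perm in PermutationPlan(n_permutations=10, seed=4).realize(ds.samples):
            assert sorted(perm) == list(range(ds.n_samples))

    def test_too_few_permutations_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            PermutationPlan(n_permutations=5)


class TestThresholdCurve:
    def test_fp_at_zero_threshold_counts_every_gene(self):
        ds, model, res = _small_null_fit()
        plan = PermutationPlan(n_permutations=10, seed=0)
        curve = fdr_threshold_curve(res, plan, ds, model.design)
        for term in curve.tables:
            assert curve.fp(term, 0.0) == ds.n_genes
            assert curve.tp(term, 0.0) == ds.n_genes

    def test_tp_and_fp_monotone_non_increasing(self):
        ds, model, res = _small_null_fit()
        plan = PermutationPlan(n_permutations=10, seed=0)
        curve = fdr_threshold_curve(res, plan, ds, model.design)
        for term, tab in curve.tables.items():
            assert (np.diff(tab["TP"]) <= 0).all()
            assert (np.diff(tab["FP"]) <= 1e-12).all()

    def test_null_data_gives_ratio_near_one(self):
        # no simulated signal: permuted and observed exceedance match
        ds, model, res = _small_null_fit(seed=5, n_genes=2000)
        plan = PermutationPlan(n_permutations=100, seed=5)
        curve = fdr_threshold_curve(res, plan, ds, model.design)
        for term, tab in curve.tables.items():
            mid = tab[(tab["TP"] >= 20)]  # where the ratio is stable
            assert np.abs(mid["ratio"] - 1.0).mean() < 0.3, term

    def test_injected_signal_separates_cleanly(self):
        # strong aS effects far beyond the null distribution: ratio -> 0 there
        cfg = SimulationConfig(seed=8, n_genes=500, n_as_genes=50,
                               as_effect_log2=3.0, n_age_genes=0, n_age_markers=0,
                               n_genotype_genes=0, n_interaction_genes=0)
        ds, _, truth = simulate_expression_experiment(cfg)
        model = GeneExpressionLM(ds, age=ds.samples["true_age_h"])
        res = model.fit()
        plan = PermutationPlan(n_permutations=50, seed=8)
        curve = fdr_threshold_curve(res, plan, ds, model.design)
        tab = curve.tables["aS"]
        strong = tab[tab["tau"] >= 8.0]
        assert len(strong) and (strong["ratio"] < 0.05).all()
        assert strong["TP"].iloc[0] >= 40

    def test_determinism(self):
        ds, model, res = _small_null_fit()
        curves = [fdr_threshold_curve(res, PermutationPlan(n_permutations=10, seed=7),
                                      ds, model.design) for _ in range(2)]
        for term in curves[0].tables:
            pd.testing.assert_frame_equal(curves[0].tables[term],
                                          curves[1].tables[term])


def _toy_curve(taus, ratios, tps):
    # per_term selection consults only the table rows
    tab = pd.DataFrame({"tau": taus, "TP": tps,
                        "FP": np.array(ratios) * np.array(tps), "ratio": ratios})
    obs = np.sort(np.asarray(taus, dtype=float))
    return ThresholdCurve(tables={"aS": tab}, observed_sorted={"aS": obs},
                          permuted_sorted={"aS": obs}, n_permutations=1)


class TestSelectThreshold:
    def test_smallest_qualifying_tau_selected(self):
        curve = _toy_curve([2.0, 3.0, 4.0], [0.5, 0.04, 0.01], [100, 50, 10])
        sel = select_threshold(curve, target_ratio=0.05, mode="per_term")
        assert sel.per_term["aS"].tau == 3.0
        assert sel.per_term["aS"].ratio == 0.04
        assert sel.per_term["aS"].n_genes == 50

    def test_no_threshold_is_sentinel_not_exception(self):
        curve = _toy_curve([2.0, 3.0], [0.5, 0.2], [100, 50])
        sel = select_threshold(curve, target_ratio=0.05)
        assert sel.per_term["aS"].tau is None
        assert sel.per_term["aS"].n_genes == 0

    def test_zero_tp_taus_are_skipped(self):
        tab = pd.DataFrame({"tau": [2.0, 3.0], "TP": [10, 0], "FP": [0.2, 0.0],
                            "ratio": [0.02, np.nan]})
        curve = ThresholdCurve(tables={"aS": tab},
                               observed_sorted={"aS": np.full(10, 2.0)},
                               permuted_sorted={"aS": np.array([1.0])},
                               n_permutations=1)
        sel = select_threshold(curve)
        assert sel.per_term["aS"].tau == 2.0

    def test_selection_invariant_to_genotype_relabelling(self):
        cfg = SimulationConfig(seed=13, n_genes=400, n_age_genes=50,
                               n_age_markers=20, n_genotype_genes=50,
                               n_as_genes=20, n_interaction_genes=20)
        ds, _, _ = simulate_expression_experiment(cfg)

        def run(dataset):
            model = GeneExpressionLM(dataset, age=dataset.samples["true_age_h"])
            res = model.fit()
            plan = PermutationPlan(n_permutations=20, seed=13)
            return select_threshold(fdr_threshold_curve(res, plan, dataset,
                                                        model.design))

        sel_a = run(ds)
        relabelled = ds.samples.copy()
        relabelled["genotype"] = relabelled["genotype"].replace(
            {"JU1511": "WILD_X", "JU1941": "WILD_Y"})
        ds_b = ds.with_matrix(ds.matrix)
        ds_b.samples = relabelled
        sel_b = run(ds_b)
        for term in sel_a.per_term:
            assert sel_a.per_term[term].tau == sel_b.per_term[term].tau
            assert sel_a.per_term[term].n_genes == sel_b.per_term[term].n_genes

    def test_global_mode_single_tau_for_all_terms(self):
        ds, model, res = _small_null_fit(seed=2, n_genes=500)
        plan = PermutationPlan(n_permutations=20, seed=2)
        curve = fdr_threshold_curve(res, plan, ds, model.design)
        sel = select_threshold(curve, target_ratio=0.5, mode="global")
        taus = {s.tau for s in sel.per_term.values()}
        assert len(taus) == 1


class TestClassifyGenes:
    def _selection(self, tau):
        per_term = {t: TermThreshold(term=t, tau=tau, ratio=0.05, n_genes=0)
                    for t in ("age", "aS", "genotype", "aS:genotype")}
        return ThresholdSelection(mode="per_term", target_ratio=0.05,
                                  per_term=per_term)

    def _results_with(self, values):
        """Fabricate results with given per-term neglog10p rows."""
        from ilx.model import GeneExpressionLMResults
        ds, model, res = _small_null_fit(n_genes=len(values))
        tests = res.term_tests.copy()
        for i, row in enumerate(values):
            for term, v in row.items():
                tests.iloc[i, tests.columns.get_loc(f"neglog10p_{term}")] = v
        return GeneExpressionLMResults(design=model.design, term_tests=tests,
                                       params=res.params,
                                       residual_df=res.residual_df)

    def test_as_only_gene_lands_in_specific_set(self):
        res = self._results_with([
            {"aS": 5.0, "age": 0.1, "genotype": 0.1, "aS:genotype": 0.1},
            {"aS": 5.0, "age": 5.0, "genotype": 0.1, "aS:genotype": 0.1},
        ])
        cls = classify_genes(res, self._selection(4.0))
        g0, g1 = res.gene_ids[0], res.gene_ids[1]
        assert g0 in cls.sets["aS"] and g0 in cls.aS_specific
        assert g1 in cls.sets["aS"] and g1 not in cls.aS_specific

    def test_interaction_exclusion_flag(self):
        res = self._results_with([
            {"aS": 5.0, "age": 0.1, "genotype": 0.1, "aS:genotype": 5.0}])
        g = res.gene_ids[0]
        keep = classify_genes(res, self._selection(4.0))
        drop = classify_genes(res, self._selection(4.0),
                              exclude_interaction_from_specific=True)
        assert g in keep.aS_specific and g not in drop.aS_specific

    def test_venn_partition_sums_to_union(self):
        ds, model, res = _small_null_fit(seed=9, n_genes=400)
        cls = classify_genes(res, self._selection(0.5))
        union = set().union(*cls.sets.values())
        assert sum(cls.venn_counts.values()) == len(union)

    def test_threshold_comparison_uses_greater_equal(self):
        res = self._results_with([
            {"aS": 4.0, "age": 0.0, "genotype": 0.0, "aS:genotype": 0.0}])
        cls = classify_genes(res, self._selection(4.0))
        assert res.gene_ids[0] in cls.sets["aS"]  # tied gene moves with the set
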
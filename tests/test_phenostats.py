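"""Phenotype ANOVA/Tukey and survival statistics against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from ilx import (
    PhenotypeTable,
    SimulationConfig,
    SurvivalTable,
    ValidationError,
    bagging_rate_test,
    kaplan_meier,
    logrank,
    mean_lifespan_test,
    simulate_phenotypes,
    tukey_within_genotype,
    two_way_anova,
)
from ilx.simulate import PhenotypeSpec, SurvivalSpec, simulate_survival

from conftest import BALANCED_ORACLE


def _pheno(values_by_cell, name="toy"):
    rows = []
    for (g, aS), vals in values_by_cell.items():
        for i, v in enumerate(vals):
            rows.append({"line": f"{g}_{int(aS)}", "genotype": g, "aS": aS,
                         "replicate": f"r{i}", "phenotype_name": name,
                         "value": float(v), "duration_s": np.nan})
    return PhenotypeTable(table=pd.DataFrame(rows))


def _survival(records):
    rows = []
    for i, (line, g, aS, t, ev) in enumerate(records):
        rows.append({"line": line, "genotype": g, "aS": aS, "worm_id": f"w{i}",
                     "time_days": float(t), "event": ev})
    return SurvivalTable(table=pd.DataFrame(rows))


class TestTwoWayAnova:
    def test_matches_hand_computed_balanced_oracle(self, balanced_phenotype_table):
        aov = two_way_anova(balanced_phenotype_table, "toy")
        for term in ("aS", "genotype", "aS:genotype"):
            ss, f, p = BALANCED_ORACLE[term]
            assert aov.table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-9)
            assert aov.table.loc[term, "F"] == pytest.approx(f, abs=1e-9)
            assert aov.table.loc[term, "p"] == pytest.approx(p, abs=1e-9)
        assert aov.residual_ss == pytest.approx(BALANCED_ORACLE["residual_ss"],
                                                abs=1e-9)
        assert aov.residual_df == BALANCED_ORACLE["residual_df"]

    def test_balanced_ss_decomposition_sums_to_total(self, balanced_phenotype_table):
        aov = two_way_anova(balanced_phenotype_table, "toy")
        vals = balanced_phenotype_table.table["value"].to_numpy()
        total = ((vals - vals.mean()) ** 2).sum()
        parts = aov.table["sum_sq"].sum() + aov.residual_ss
        assert parts == pytest.approx(total, rel=1e-9)

    def test_purely_additive_data_has_zero_interaction(self):
        cells = {}
        for g, gm in [("N2", 0.0), ("JU1511", 3.0)]:
            for aS, am in [(False, 0.0), (True, 2.0)]:
                cells[(g, aS)] = [10.0 + gm + am + r for r in (-0.5, 0.0, 0.5)]
        aov = two_way_anova(_pheno(cells), "toy")
        assert aov.table.loc["aS:genotype", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_values_yield_p_one(self):
        cells = {(g, a): [5.0, 5.0, 5.0] for g in ("N2", "JU1511")
                 for a in (False, True)}
        aov = two_way_anova(_pheno(cells), "toy")
        assert (aov.table["p"] == 1.0).all()

    def test_empty_cell_named_in_error(self):
        cells = {("N2", False): [1.0, 2.0], ("N2", True): [1.0, 2.0],
                 ("JU1511", False): [1.0, 2.0]}
        with pytest.raises(ValidationError, match=r"JU1511, aS=1"):
            two_way_anova(_pheno(cells), "toy")

    def test_null_as_shift_gives_uniform_p(self):
        # aS shift zero everywhere: the aS p-value is uniform across seeds
        ps = []
        for seed in range(80):
            spec = PhenotypeSpec("flat", {"N2": 50.0, "JU1511": 55.0},
                                 {"N2": 0.0, "JU1511": 0.0}, sd=2.0,
                                 n_per_group=10)
            cfg = SimulationConfig(seed=seed, genotypes=("N2", "JU1511"),
                                   phenotypes=[spec])
            table, _ = simulate_phenotypes(cfg)
            ps.append(two_way_anova(table, "flat").p("aS"))
        ps = np.asarray(ps)
        # empirical CDF close to the diagonal
        for q in (0.1, 0.25, 0.5, 0.75):
            assert abs((ps <= q).mean() - q) < 0.17


class TestTukey:
    def test_identical_groups_adjusted_p_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=8)
        cells = {(g, a): base for g in ("N2", "JU1511") for a in (False, True)}
        contrasts, _ = tukey_within_genotype(_pheno(cells), "toy")
        for c in contrasts:
            assert c.adjusted_p > 0.99

    def test_adjusted_p_dominates_pooled_pairwise_p(self):
        # family-wise property: the studentized-range adjusted p is never
        # smaller than the unadjusted pairwise p computed with the same
        # pooled error variance and residual df
        from scipy import stats as sps
        rng = np.random.default_rng(1)
        cells = {(g, a): rng.normal(10 + 2 * a, 1, size=10)
                 for g in ("N2", "JU1511") for a in (False, True)}
        table = _pheno(cells)
        contrasts, _ = tukey_within_genotype(table, "toy")
        groups = [np.asarray(v) for v in cells.values()]
        df_resid = sum(len(g) - 1 for g in groups)
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_resid
        n = 10
        for c in contrasts:
            se = np.sqrt(mse * 2 / n)
            t = abs(c.difference) / se
            p_pooled = 2 * sps.t.sf(t, df_resid)
            assert c.adjusted_p >= p_pooled - 1e-12

    def test_single_observation_group_is_error(self):
        cells = {("N2", False): [1.0], ("N2", True): [1.0, 2.0],
                 ("JU1511", False): [1.0, 2.0], ("JU1511", True): [1.0, 2.0]}
        with pytest.raises(ValidationError, match="single observation"):
            tukey_within_genotype(_pheno(cells), "toy")

    def test_shifted_genotype_detected_specifically(self):
        # a strong transgene shift only in one background: only that
        # within-genotype contrast is significant, in most seeds
        hits = {"JU1941": 0, "N2": 0, "JU1511": 0}
        n_seeds = 25
        for seed in range(n_seeds):
            specs = [PhenotypeSpec("t", {g: 50.0 for g in hits},
                                   {"N2": 0.0, "JU1511": 0.0, "JU1941": 5.0},
                                   sd=1.0, n_per_group=20)]
            cfg = SimulationConfig(seed=seed, genotypes=tuple(hits),
                                   phenotypes=specs,
                                   as_delay_h={g: 0.5 for g in hits})
            table, _ = simulate_phenotypes(cfg)
            contrasts, _ = tukey_within_genotype(table, "t")
            for c in contrasts:
                hits[c.genotype] += c.adjusted_p < 0.01
        assert hits["JU1941"] == n_seeds          # 5-sd effect always found
        assert hits["N2"] + hits["JU1511"] <= 2   # null contrasts stay quiet


class TestKaplanMeier:
    def test_two_deaths_no_censoring(self):
        table = _survival([("A", "N2", False, 5, "death"),
                           ("A", "N2", False, 10, "death")])
        km = kaplan_meier(table, line="A")
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5) == pytest.approx(0.5)
        assert km.survival_at(10) == pytest.approx(0.0)
        assert km.mean_lifespan_days == pytest.approx(7.5)

    def test_censoring_between_deaths_hand_product_limit(self):
        table = _survival([("A", "N2", False, 5, "death"),
                           ("A", "N2", False, 7, "bagging"),
                           ("A", "N2", False, 10, "death")])
        km = kaplan_meier(table, line="A")
        assert km.survival_at(5) == pytest.approx(2 / 3)
        assert km.survival_at(9.9) == pytest.approx(2 / 3)
        assert km.survival_at(10) == pytest.approx(0.0)
        assert km.n_deaths == 2
        assert km.mean_lifespan_days == pytest.approx(7.5)  # deaths only

    def test_all_censored_curve_flat_mean_unavailable(self):
        table = _survival([("A", "N2", False, 5, "bagging"),
                           ("A", "N2", False, 8, "crawloff")])
        km = kaplan_meier(table, line="A")
        assert km.mean_lifespan_days is None
        assert (km.survival >= 1.0 - 1e-12).all()

    def test_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 20, size=50).astype(float)
        table = _survival([("A", "N2", False, t, "death") for t in times])
        km = kaplan_meier(table, line="A")
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_survival_monotone_non_increasing_from_one(self):
        table, _ = simulate_survival(SimulationConfig(seed=5))
        km = kaplan_meier(table, genotype="JU1926", aS=True)
        assert km.survival[0] <= 1.0 + 1e-12
        assert (np.diff(km.survival) <= 1e-12).all()


# two groups of 5 with one censored worm in B; chi-square and p computed
# independently with R survival::survdiff on the printed times
LOGRANK_FIXTURE = [("A", 2, 1), ("A", 4, 1), ("A", 6, 1), ("A", 8, 1),
                   ("A", 10, 1),
                   ("B", 3, 1), ("B", 5, 1), ("B", 7, 1), ("B", 9, 0),
                   ("B", 12, 1)]
LOGRANK_ORACLE = {"chisq": 0.75965348768912555, "p": 0.38343698453885644}


class TestLogrank:
    def _fixture_table(self):
        return _survival([(g, "N2", g == "B", t, "death" if e else "crawloff")
                          for g, t, e in LOGRANK_FIXTURE])

    def test_fixture_matches_r_survdiff_oracle(self):
        table = self._fixture_table()
        res = logrank(table, {"line": "A"}, {"line": "B"})
        assert res.statistic == pytest.approx(LOGRANK_ORACLE["chisq"], abs=1e-9)
        assert res.p == pytest.approx(LOGRANK_ORACLE["p"], abs=1e-9)

    def test_symmetric_under_group_swap(self):
        table = self._fixture_table()
        a = logrank(table, {"line": "A"}, {"line": "B"})
        b = logrank(table, {"line": "B"}, {"line": "A"})
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_identical_groups_statistic_zero(self):
        rows = [("A", "N2", False, t, "death") for t in (3, 5, 8, 11)] + \
               [("B", "N2", True, t, "death") for t in (3, 5, 8, 11)]
        res = logrank(_survival(rows), {"line": "A"}, {"line": "B"})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_time_restriction_censors_late_divergence(self):
        # identical for 20 days, then group B dies out fast: the restricted
        # test must ignore the divergence, the full test must see it
        rows = [("A", "N2", False, t, "death") for t in range(5, 45, 2)] + \
               [("B", "N2", True, t, "death") for t in list(range(5, 25, 2)) +
                [25, 25, 26, 26, 26, 27, 27, 27, 27, 28]]
        table = _survival(rows)
        full = logrank(table, {"line": "A"}, {"line": "B"})
        restricted = logrank(table, {"line": "A"}, {"line": "B"},
                             restrict_days=20.0)
        assert restricted.p > 0.5
        assert full.p < restricted.p

    def test_no_events_in_restriction_is_error(self):
        table = self._fixture_table()
        with pytest.raises(ValidationError, match="no death events"):
            logrank(table, {"line": "A"}, {"line": "B"}, restrict_days=1.0)


class TestBaggingRate:
    def _table(self, n_bag_wt, n_bag_as, n=100):
        rows = []
        for i in range(n):
            rows.append(("WT", "JU1926", False, 10,
                         "bagging" if i < n_bag_wt else "death"))
        for i in range(n):
            rows.append(("AS", "JU1926", True, 10,
                         "bagging" if i < n_bag_as else "death"))
        return _survival(rows)

    def test_no_bagging_anywhere(self):
        res = bagging_rate_test(self._table(0, 0), "JU1926")
        assert res.difference_pct_points == 0.0
        assert res.p == pytest.approx(1.0)

    def test_difference_and_exact_p(self):
        from scipy import stats as sps
        res = bagging_rate_test(self._table(10, 30), "JU1926")
        assert res.difference_pct_points == pytest.approx(20.0)
        _, expected = sps.fisher_exact([[30, 70], [10, 90]])
        assert res.p == pytest.approx(expected, rel=1e-12)
        assert res.p < 0.001

    def test_swap_negates_difference_keeps_p(self):
        a = bagging_rate_test(self._table(10, 30), "JU1926")
        b = bagging_rate_test(self._table(30, 10), "JU1926")
        assert a.difference_pct_points == -b.difference_pct_points
        assert a.p == pytest.approx(b.p, rel=1e-12)


class TestMeanLifespan:
    def test_welch_and_tukey_agree_on_direction(self):
        spec = SurvivalSpec(as_scale_factor={"N2": 0.7, "JU1511": 1.0},
                            p_bag=0.1, p_crawl=0.05)
        cfg = SimulationConfig(seed=4, genotypes=("N2", "JU1511"), survival=spec,
                               as_delay_h={"N2": 0.5, "JU1511": 0.5})
        table, _ = simulate_survival(cfg)
        for method in ("welch", "tukey"):
            diff, p = mean_lifespan_test(table, "N2", method=method)
            assert diff < 0  # transgene shortens life in this background
            assert p < 0.01
        diff_null, p_null = mean_lifespan_test(table, "JU1511", method="welch")
        assert p_null > 0.01
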
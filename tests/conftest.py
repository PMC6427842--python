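import numpy as np
import pandas as pd
import pytest

from ilx import ExpressionDataset, SimulationConfig, simulate_expression_experiment


def make_sample_sheet(genotypes=("N2", "JU1511"), n_reps=3) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for aS in (False, True):
            for r in range(n_reps):
                tag = "aS" if aS else "WT"
                rows.append({"sample_id": f"{g}_{tag}_r{r + 1}", "genotype": g,
                             "aS": aS, "batch": f"rep{r + 1}",
                             "chronological_time_h": 48.0})
    return pd.DataFrame(rows).set_index("sample_id")


def make_dataset(values: np.ndarray, samples: pd.DataFrame,
                 scale: str = "intensity") -> ExpressionDataset:
    matrix = pd.DataFrame(
        np.atleast_2d(values),
        index=pd.Index([f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
                       name="gene_id"),
        columns=samples.index)
    return ExpressionDataset(matrix=matrix, samples=samples, scale=scale)


@pytest.fixture
def two_genotype_sheet():
    return make_sample_sheet()


@pytest.fixture
def five_genotype_sheet():
    return make_sample_sheet(genotypes=("N2", "JU1511", "JU1926", "JU1931", "JU1941"))


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    dataset, gene_map, truth = simulate_expression_experiment(cfg)
    return cfg, dataset, gene_map, truth


# Balanced 2 genotypes x 2 aS x 3 reps phenotype fixture with its
# independently computed factorial ANOVA oracle (Type II; balanced, so all
# SS types coincide).
BALANCED_VALUES = {
    ("N2", False): [10.0, 11.0, 12.0],
    ("N2", True): [13.0, 12.0, 14.0],
    ("JU1511", False): [9.0, 8.0, 10.0],
    ("JU1511", True): [16.0, 15.0, 17.0],
}
BALANCED_ORACLE = {
    # term: (sum_sq, F, p)
    "aS": (60.75, 60.750000000000178, 5.2652087865995611e-05),
    "genotype": (0.75, 0.74999999999999523, 0.41169443182590781),
    "aS:genotype": (18.75, 18.750000000000089, 0.0025115519065117605),
    "residual_ss": 8.0,
    "residual_df": 8,
}


@pytest.fixture
def balanced_phenotype_table():
    from ilx import PhenotypeTable
    rows = []
    for (g, aS), vals in BALANCED_VALUES.items():
        for i, v in enumerate(vals):
            rows.append({"line": f"{g}_{int(aS)}", "genotype": g, "aS": aS,
                         "replicate": f"rep{i + 1}", "phenotype_name": "toy",
                         "value": v, "duration_s": np.nan})
    return PhenotypeTable(table=pd.DataFrame(rows))
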
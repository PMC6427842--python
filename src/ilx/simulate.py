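"""Synthetic experiment generator with recorded ground truth.

Emulates the design of the alpha-synuclein introgression-line study:
five genetic backgrounds (N2 plus four wild isolates), each with and without
the transgene, three biological replicates — 30 arrays — sampled inside the
46-54 h developmental window where class-I age-responsive genes increase
linearly in expression.  The expression generator realises exactly the
structural model the analysis fits,

    x_gs = baseline_g + beta_age_g * (age_s - 46)
           + beta_genotype_g[G(s)] + beta_aS_g * aS(s)
           + beta_int_g[G(s)] * aS(s) + N(0, noise_sd),

plus wild-isolate marker genes whose background-specific offsets are zeroed
(set to the N2 level) inside the introgressed N2 block of each transgenic
line — the signal the introgression mapper detects.

Every simulated effect is recorded in a :class:`TruthTable` so that false
discovery proportions, age-recovery error and interval-recovery error can be
measured exactly.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionDataset,
    GeneMap,
    PhenotypeTable,
    SurvivalTable,
    ValidationError,
)

DEFAULT_GENOTYPES = ("N2", "JU1511", "JU1926", "JU1931", "JU1941")

#: Developmental delay of the transgenic line relative to its wild-type
#: background, in hours (the transgene slows development; maximum 2.5 h).
DEFAULT_AS_DELAY_H: dict[str, float] = {
    "N2": 0.5, "JU1511": 1.0, "JU1926": 1.5, "JU1931": 0.5, "JU1941": 2.5,
}


@dataclass(frozen=True)
class MarkerBlock:
    """An introgressed N2 segment in one line: chromosome + Mb span."""

    chromosome: str
    start_mb: float
    end_mb: float

    def __post_init__(self) -> None:
        if self.end_mb < self.start_mb:
            raise ValidationError("marker block end before start")

    def contains(self, position_mb: float) -> bool:
        return self.start_mb <= position_mb <= self.end_mb


def _default_marker_blocks() -> dict[str, tuple[MarkerBlock, ...]]:
    # every transgenic line carries the N2 block around the transgene on IV;
    # one line carries an additional block on V
    block_iv = MarkerBlock("IV", 4.2, 13.2)
    return {
        "JU1511": (block_iv,),
        "JU1926": (block_iv,),
        "JU1931": (block_iv, MarkerBlock("V", 6.0, 9.0)),
        "JU1941": (block_iv,),
    }


@dataclass
class PhenotypeSpec:
    """Structural definition of one simulated phenotype.

    ``genotype_means`` give the wild-type mean per background; ``as_shift``
    the transgene effect per background (its variation across backgrounds is
    the genotype x transgene interaction).  Gaussian phenotypes add noise of
    ``sd``; count phenotypes (family "poisson") draw Poisson around the
    structural mean and therefore need a recording ``duration_s``.
    """

    name: str
    genotype_means: dict[str, float]
    as_shift: dict[str, float]
    sd: float = 1.0
    family: str = "gaussian"  # gaussian | poisson
    duration_s: float | None = None
    n_per_group: int = 30

    def structural_mean(self, genotype: str, aS: bool) -> float:
        return self.genotype_means[genotype] + (self.as_shift[genotype] if aS else 0.0)


def default_phenotype_specs(genotypes: Sequence[str] = DEFAULT_GENOTYPES) -> list[PhenotypeSpec]:
    """Phenotype battery mirroring the study: development time, pharyngeal
    pumping at two ages (30 s and 60 s counting windows), thrashing activity
    over 30 min.  Transgene shifts are genotype-specific: strong in some wild
    backgrounds, absent in N2."""
    g = list(genotypes)
    base_dev = {"N2": 60.0, "JU1511": 61.5, "JU1926": 59.0, "JU1931": 60.5, "JU1941": 62.0}
    dev_shift = {"N2": 0.1, "JU1511": 0.3, "JU1926": 1.2, "JU1931": 0.1, "JU1941": 2.5}
    pump48 = {k: 130.0 for k in g}
    pump72 = {"N2": 240.0, "JU1511": 235.0, "JU1926": 245.0, "JU1931": 238.0, "JU1941": 230.0}
    pump72_shift = {"N2": -2.0, "JU1511": -25.0, "JU1926": -30.0, "JU1931": -5.0, "JU1941": -45.0}
    thrash = {"N2": 600.0, "JU1511": 640.0, "JU1926": 580.0, "JU1931": 610.0, "JU1941": 560.0}
    thrash_shift = {"N2": 0.0, "JU1511": -80.0, "JU1926": -60.0, "JU1931": -55.0, "JU1941": -10.0}

    def _sub(d: Mapping[str, float]) -> dict[str, float]:
        return {k: d[k] for k in g if k in d}

    return [
        PhenotypeSpec("development_h", _sub(base_dev), _sub(dev_shift), sd=1.5,
                      family="gaussian", n_per_group=30),
        PhenotypeSpec("pumping_48h", _sub(pump48), {k: 0.0 for k in g},
                      family="poisson", duration_s=30.0, n_per_group=19),
        PhenotypeSpec("pumping_72h", _sub(pump72), _sub(pump72_shift),
                      family="poisson", duration_s=60.0, n_per_group=30),
        PhenotypeSpec("thrashing", _sub(thrash), _sub(thrash_shift),
                      family="poisson", duration_s=1800.0, n_per_group=12),
    ]


@dataclass
class SurvivalSpec:
    """Weibull lifespans with competing censoring events.

    Each worm is independently assigned bagging (matricidal hatching, time
    drawn uniformly from the reproductive window) with probability
    ``p_bag``, crawl-off with probability ``p_crawl``, otherwise dies at a
    Weibull-distributed age.  Bagging and crawl-off right-censor lifespan.
    """

    weibull_shape: float = 4.0
    weibull_scale_days: float = 20.0
    #: transgene multiplier on the Weibull scale, per background (<1 shortens life)
    as_scale_factor: dict[str, float] = field(default_factory=lambda: {
        "N2": 1.0, "JU1511": 0.85, "JU1926": 0.8, "JU1931": 0.97, "JU1941": 0.82})
    p_bag: dict[tuple[str, bool], float] | float = field(default_factory=lambda: {
        ("N2", False): 0.05, ("N2", True): 0.06,
        ("JU1511", False): 0.05, ("JU1511", True): 0.25,
        ("JU1926", False): 0.05, ("JU1926", True): 0.3,
        ("JU1931", False): 0.05, ("JU1931", True): 0.2,
        ("JU1941", False): 0.05, ("JU1941", True): 0.25})
    p_crawl: float = 0.05
    n_worms: int = 100
    bagging_window_days: tuple[float, float] = (4.0, 10.0)
    crawl_window_days: tuple[float, float] = (2.0, 15.0)

    def bag_prob(self, genotype: str, aS: bool) -> float:
        if isinstance(self.p_bag, Mapping):
            return float(self.p_bag.get((genotype, aS), 0.05))
        return float(self.p_bag)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment (expression + phenotypes + survival)."""

    n_genes: int = 2000
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_replicates: int = 3
    seed: int = 0
    # developmental ages
    age_window_h: tuple[float, float] = (46.0, 54.0)
    wildtype_age_h: float = 51.0
    as_delay_h: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AS_DELAY_H))
    #: biological-replicate scatter around the cell's developmental age; makes
    #: the age covariate identifiable within design cells (set 0 to disable)
    replicate_age_sd_h: float = 0.3
    # effect-set sizes
    n_age_genes: int = 300
    n_genotype_genes: int = 200
    n_as_genes: int = 100
    n_interaction_genes: int = 100
    n_age_markers: int = 50
    # effect sizes (log2 units)
    age_slope_range: tuple[float, float] = (0.2, 1.0)  # per hour
    genotype_effect_log2: float = 1.0
    as_effect_log2: float = 1.0
    interaction_effect_log2: float = 1.0
    # wild-isolate marker genes for introgression mapping
    marker_spacing_mb: float = 0.5
    marker_chromosome_lengths_mb: dict[str, float] = field(default_factory=lambda: {
        "IV": 17.5, "V": 21.0})
    marker_separation_log2: float = 2.0
    marker_blocks: dict[str, tuple[MarkerBlock, ...]] = field(
        default_factory=_default_marker_blocks)
    # noise
    noise_sd: float = 0.25
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    # phenotype / survival layers
    phenotypes: list[PhenotypeSpec] | None = None
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for n in (self.n_age_genes, self.n_genotype_genes, self.n_as_genes,
                  self.n_interaction_genes, self.n_age_markers):
            if n > self.n_genes:
                raise ValidationError("effect-set count exceeds n_genes")
        if self.n_age_markers > max(self.n_age_genes, 0) and self.n_age_markers > 0:
            raise ValidationError("age markers are drawn from age-responsive genes; "
                                  "n_age_markers must be <= n_age_genes")
        lo, hi = self.age_window_h
        for g in self.genotypes:
            delay = self.as_delay_h.get(g, 0.0)
            if not (lo <= self.wildtype_age_h <= hi and lo <= self.wildtype_age_h - delay <= hi):
                raise ValidationError(f"age offsets leave the calibration window for {g}")

    def cell_ages(self) -> dict[tuple[str, bool], float]:
        """True developmental age per (genotype, aS) cell at sampling."""
        out: dict[tuple[str, bool], float] = {}
        for g in self.genotypes:
            out[(g, False)] = self.wildtype_age_h
            out[(g, True)] = self.wildtype_age_h - self.as_delay_h.get(g, 0.0)
        return out

    def rng(self, stream: int) -> np.random.Generator:
        # decoupled streams so that e.g. adding phenotype noise never
        # perturbs the expression draw for the same seed
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


# ---------------------------------------------------------------------------
# expression

def _marker_layout(config: SimulationConfig) -> pd.DataFrame:
    """Positions of wild-isolate marker genes: a regular grid along each
    chromosome that carries an introgression block."""
    rows = []
    i = 0
    for chrom, length in sorted(config.marker_chromosome_lengths_mb.items()):
        pos = np.arange(config.marker_spacing_mb, length, config.marker_spacing_mb)
        for p in pos:
            rows.append({"marker_index": i, "chromosome": chrom, "position_mb": float(p)})
            i += 1
    return pd.DataFrame(rows, columns=["marker_index", "chromosome", "position_mb"])


def simulate_expression_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GeneMap, pd.DataFrame]:
    """Generate an expression experiment with known ground truth.

    Returns the dataset (log2 intensities), the gene map, and the truth
    table: one row per gene with effect flags (is_age, is_genotype, is_aS,
    is_interaction, is_marker, is_age_marker) and the true effect sizes.
    """
    rng = config.rng(1)
    genotypes = list(config.genotypes)
    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    # -- sample sheet ---------------------------------------------------------
    rows = []
    for g in genotypes:
        for aS in (False, True):
            for r in range(config.n_replicates):
                tag = "aS" if aS else "WT"
                rows.append({"sample_id": f"{g}_{tag}_r{r + 1}", "genotype": g,
                             "aS": aS, "batch": f"rep{r + 1}",
                             "chronological_time_h": 48.0})
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(samples)
    cell_ages = config.cell_ages()
    true_age = np.array([cell_ages[(r["genotype"], r["aS"])] for _, r in samples.iterrows()])
    if config.replicate_age_sd_h > 0:
        jitter = rng.normal(0.0, config.replicate_age_sd_h, size=n_samples)
        true_age = np.clip(true_age + jitter, *config.age_window_h)

    # -- effect assignment ----------------------------------------------------
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for col in ("is_age", "is_genotype", "is_aS", "is_interaction",
                "is_marker", "is_age_marker"):
        truth[col] = False
    truth["beta_age"] = 0.0
    truth["beta_aS"] = 0.0
    for g in genotypes:
        truth[f"beta_genotype_{g}"] = 0.0
        truth[f"beta_int_{g}"] = 0.0

    markers = _marker_layout(config)
    n_markers = len(markers)
    if n_markers + config.n_age_genes + config.n_genotype_genes > n_genes:
        raise ValidationError("n_genes too small for the requested marker grid")

    # marker genes occupy the head of the index so their grid positions are fixed
    marker_idx = np.arange(n_markers)
    remaining = np.arange(n_markers, n_genes)
    age_idx = rng.choice(remaining, size=config.n_age_genes, replace=False)
    # other effect sets may overlap each other (flags record everything)
    geno_idx = rng.choice(remaining, size=config.n_genotype_genes, replace=False)
    as_idx = rng.choice(remaining, size=config.n_as_genes, replace=False)
    int_idx = rng.choice(remaining, size=config.n_interaction_genes, replace=False)
    age_marker_idx = rng.choice(age_idx, size=config.n_age_markers, replace=False) \
        if config.n_age_markers else np.array([], dtype=int)

    truth.iloc[age_idx, truth.columns.get_loc("is_age")] = True
    truth.iloc[geno_idx, truth.columns.get_loc("is_genotype")] = True
    truth.iloc[as_idx, truth.columns.get_loc("is_aS")] = True
    truth.iloc[int_idx, truth.columns.get_loc("is_interaction")] = True
    truth.iloc[marker_idx, truth.columns.get_loc("is_marker")] = True
    truth.iloc[marker_idx, truth.columns.get_loc("is_genotype")] = True
    truth.iloc[age_marker_idx, truth.columns.get_loc("is_age_marker")] = True

    # -- effect sizes ---------------------------------------------------------
    lo_s, hi_s = config.age_slope_range
    beta_age = np.zeros(n_genes)
    beta_age[age_idx] = rng.uniform(lo_s, hi_s, size=len(age_idx))  # strictly positive
    truth["beta_age"] = beta_age

    beta_aS = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=len(as_idx))
    beta_aS[as_idx] = signs * config.as_effect_log2
    truth["beta_aS"] = beta_aS

    beta_geno = np.zeros((n_genes, len(genotypes)))  # offset relative to N2
    for j, g in enumerate(genotypes):
        if g == "N2" or j == 0:
            continue
        beta_geno[geno_idx, j] = rng.normal(0.0, config.genotype_effect_log2,
                                            size=len(geno_idx))
    # wild-isolate marker genes: background-specific offset of fixed separation
    for j, g in enumerate(genotypes):
        if j == 0:
            continue
        beta_geno[marker_idx, j] = config.marker_separation_log2

    beta_int = np.zeros((n_genes, len(genotypes)))
    for j, g in enumerate(genotypes):
        if j == 0:
            continue
        beta_int[int_idx, j] = rng.normal(0.0, config.interaction_effect_log2,
                                          size=len(int_idx))
    # introgression: inside the block of line (g, aS=1) the marker reverts to N2
    blocks = config.marker_blocks
    for j, g in enumerate(genotypes):
        for blk in blocks.get(g, ()):  # blocks only exist for transgenic lines
            on_chrom = markers["chromosome"] == blk.chromosome
            inside = on_chrom & markers["position_mb"].apply(blk.contains)
            idx = markers.loc[inside, "marker_index"].to_numpy()
            # aS samples of genotype g lose the background offset: model this
            # as an interaction term that cancels the genotype offset
            beta_int[idx, j] = -config.marker_separation_log2

    for j, g in enumerate(genotypes):
        truth[f"beta_genotype_{g}"] = beta_geno[:, j]
        truth[f"beta_int_{g}"] = beta_int[:, j]

    # -- assemble matrix ------------------------------------------------------
    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n_genes)
    geno_j = np.array([genotypes.index(g) for g in samples["genotype"]])
    as_flag = samples["aS"].to_numpy(dtype=float)
    lo_age = config.age_window_h[0]

    mean = (baseline[:, None]
            + beta_age[:, None] * (true_age[None, :] - lo_age)
            + beta_geno[:, geno_j]
            + beta_aS[:, None] * as_flag[None, :]
            + beta_int[:, geno_j] * as_flag[None, :])
    noise = rng.normal(0.0, config.noise_sd, size=mean.shape) if config.noise_sd > 0 \
        else np.zeros_like(mean)
    matrix = pd.DataFrame(mean + noise, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples.index)

    # -- gene map -------------------------------------------------------------
    chrom = np.empty(n_genes, dtype=object)
    pos = np.empty(n_genes)
    chrom[marker_idx] = markers["chromosome"].to_numpy()
    pos[marker_idx] = markers["position_mb"].to_numpy()
    all_chroms = ("I", "II", "III", "IV", "V", "X")
    chrom[remaining] = rng.choice(all_chroms, size=len(remaining))
    pos[remaining] = rng.uniform(0.1, 17.0, size=len(remaining))
    gene_map = GeneMap(table=pd.DataFrame(
        {"chromosome": chrom, "position_mb": pos},
        index=pd.Index(gene_ids, name="gene_id")))

    truth["baseline"] = baseline
    dataset = ExpressionDataset(matrix=matrix, samples=samples, scale="intensity")
    # record per-sample true age on the sample sheet for truth comparisons
    dataset.samples["true_age_h"] = true_age
    return dataset, gene_map, truth


def age_calibration_from_truth(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Calibration table (gene_id, slope, intercept at 46 h) for the simulated
    class-I age markers — the synthetic stand-in for the literature marker list."""
    m = truth[truth["is_age_marker"]]
    return pd.DataFrame({"slope": m["beta_age"].to_numpy(),
                         "intercept": m["baseline"].to_numpy()},
                        index=pd.Index(m.index, name="gene_id"))


def marker_gene_list(truth: pd.DataFrame) -> list[str]:
    """Gene ids of the wild-isolate marker panel."""
    return list(truth.index[truth["is_marker"]])


def simulate_go_catalog(truth: pd.DataFrame, config: SimulationConfig,
                        n_random_terms: int = 40,
                        n_enriched_terms: int = 5) -> "GOCatalog":
    """Synthetic GO catalog: random terms plus terms enriched for true
    transgene-responsive genes, so the enrichment stage has signal to find."""
    from .containers import GOCatalog, GOTerm

    rng = config.rng(4)
    genes = np.asarray(truth.index)
    as_genes = np.asarray(truth.index[truth["is_aS"]])
    catalog = GOCatalog()
    types = ("BP", "MF", "CC")
    for i in range(n_random_terms):
        size = int(rng.integers(10, 100))
        members = rng.choice(genes, size=size, replace=False)
        catalog.terms[f"GO:{7000000 + i}"] = GOTerm(
            go_id=f"GO:{7000000 + i}", description=f"random process {i}",
            type=types[i % 3], genes=frozenset(members))
    for i in range(n_enriched_terms):
        if len(as_genes) == 0:
            break
        n_sig = min(len(as_genes), int(rng.integers(5, 15)))
        picked = set(rng.choice(as_genes, size=n_sig, replace=False))
        picked |= set(rng.choice(genes, size=20, replace=False))
        catalog.terms[f"GO:{8000000 + i}"] = GOTerm(
            go_id=f"GO:{8000000 + i}", description=f"transgene-response process {i}",
            type=types[i % 3], genes=frozenset(picked))
    return catalog


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(config: SimulationConfig) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Generate the phenotype battery.

    Returns the long-format table and a truth table of structural means per
    (phenotype, genotype, aS) cell.
    """
    rng = config.rng(2)
    specs = config.phenotypes if config.phenotypes is not None \
        else default_phenotype_specs(config.genotypes)
    rows = []
    truth_rows = []
    for spec in specs:
        for g in config.genotypes:
            if g not in spec.genotype_means:
                continue
            for aS in (False, True):
                mu = spec.structural_mean(g, aS)
                if spec.family == "poisson" and mu < 0:
                    raise ValidationError(
                        f"negative structural mean for count phenotype {spec.name} "
                        f"in cell ({g}, aS={aS})")
                line = _line_name(g, aS)
                truth_rows.append({"phenotype_name": spec.name, "genotype": g,
                                   "aS": aS, "structural_mean": mu})
                if spec.family == "poisson":
                    vals = rng.poisson(mu, size=spec.n_per_group).astype(float)
                else:
                    vals = rng.normal(mu, spec.sd, size=spec.n_per_group)
                reps = np.repeat(np.arange(spec.n_per_group) % 3 + 1, 1)
                for i, v in enumerate(vals):
                    rows.append({"line": line, "genotype": g, "aS": aS,
                                 "replicate": f"rep{reps[i]}",
                                 "phenotype_name": spec.name, "value": float(v),
                                 "duration_s": spec.duration_s})
    table = PhenotypeTable(table=pd.DataFrame(rows))
    return table, pd.DataFrame(truth_rows)


def _line_name(genotype: str, aS: bool) -> str:
    if not aS:
        return genotype
    if genotype == "N2":
        return "NL5901"
    return genotype.replace("JU", "SCH").replace("CB", "SCH")


# ---------------------------------------------------------------------------
# survival

def simulate_survival(config: SimulationConfig) -> tuple[SurvivalTable, pd.DataFrame]:
    """Generate per-worm lifespan records with bagging / crawl-off censoring."""
    rng = config.rng(3)
    spec = config.survival
    for g in config.genotypes:
        for aS in (False, True):
            p = spec.bag_prob(g, aS)
            if not (0.0 <= p <= 1.0) or not (0.0 <= spec.p_crawl <= 1.0):
                raise ValidationError("event probabilities must lie in [0, 1]")
            if p + spec.p_crawl > 1.0:
                raise ValidationError("p_bag + p_crawl exceeds 1")
    rows = []
    truth_rows = []
    for g in config.genotypes:
        for aS in (False, True):
            scale = spec.weibull_scale_days * (spec.as_scale_factor.get(g, 1.0) if aS else 1.0)
            p_bag = spec.bag_prob(g, aS)
            truth_rows.append({"genotype": g, "aS": aS, "weibull_shape": spec.weibull_shape,
                               "weibull_scale_days": scale, "p_bag": p_bag,
                               "p_crawl": spec.p_crawl})
            u = rng.uniform(size=spec.n_worms)
            deaths = scale * rng.weibull(spec.weibull_shape, size=spec.n_worms)
            bag_t = rng.uniform(*spec.bagging_window_days, size=spec.n_worms)
            crawl_t = rng.uniform(*spec.crawl_window_days, size=spec.n_worms)
            line = _line_name(g, aS)
            for w in range(spec.n_worms):
                if u[w] < p_bag:
                    event, t = "bagging", bag_t[w]
                elif u[w] < p_bag + spec.p_crawl:
                    event, t = "crawloff", crawl_t[w]
                else:
                    event, t = "death", deaths[w]
                rows.append({"line": line, "genotype": g, "aS": aS,
                             "worm_id": f"{line}_w{w:03d}",
                             "time_days": max(float(t), 1e-6), "event": event})
    return SurvivalTable(table=pd.DataFrame(rows)), pd.DataFrame(truth_rows)
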
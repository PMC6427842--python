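# Methods

This note documents the models the package implements, the assumptions they
make, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## The factorial expression model

Each gene is fitted independently by ordinary least squares:

x_gs = β₀ + β_age (a_s − ā) + β_aS t_s + β_G[g(s)] + β_int[g(s)] t_s + ε_gs

where a_s is the sample's developmental age in hours, t_s ∈ {0, 1} the
transgene indicator and g(s) the genetic background, treatment-coded with
N2 / non-transgenic as the reference cell. The age covariate is the
*estimated* developmental age from the marker-gene calibration by default
(chronological time via a flag): samples are harvested at the same clock
time, but the transgene delays development by up to ~2.5 h, so a large
share of apparent transgene signal is really age signal. Putting estimated
age in the model is what separates the two.

Per-term F statistics use Type II sums of squares: each main effect is
tested against the model containing every term that does not include it
(so aS and genotype are adjusted for age and each other, with the
interaction excluded), and the interaction against the full model; the
denominator is always the full-model residual mean square. On a balanced
design all three classical SS types coincide — the suite asserts this — so
the choice only matters once censoring or dropout unbalances the data. The
engine is a vectorised QR implementation (one orthogonalisation per nested
model, residual sums for all genes from two matrix products), which is what
makes permutation refitting cheap; it is cross-checked gene-by-gene against
statsmodels' `anova_lm(typ=2)` in the tests.

Plain OLS is used, with no empirical-Bayes variance moderation. With three
replicates per cell and 19 residual df the moderation a limma-style fit
would add is modest; the difference is documented rather than modelled.
Constant genes receive p = 1 with a warning; a zero-residual (noiseless)
fit yields p = 0 and exact coefficients, with −log10(p) capped at 300.

## Permutation FDR and threshold selection

The null is built by permuting whole sample columns of the matrix while the
design (metadata and age covariate) stays fixed — equivalent to randomly
redistributing hybridisation intensities over genotypes and batches. One
shared permutation per iteration preserves gene–gene correlation. A
within-batch scheme is available for designs where batch must be held.

For each term, the candidate grid is the sorted set of observed −log10(p)
values. TP(τ) counts observed exceedances, FP(τ) the mean permuted
exceedance (mean, not median, is the standard plug-in FDR estimate; the
median is available), and the selected threshold is the smallest grid τ
with FP/TP ≤ the target (0.05 default). Ties move together (≥ comparison);
τ values with TP = 0 are skipped; if no τ qualifies the result is an
explicit no-threshold sentinel, not an exception. Selection can be per term
(default) or global — one τ that satisfies all designated terms at once —
since a single convenience threshold shared across terms with different
realized FDRs is a legitimate reading of the procedure. Both the selected τ
and the realized per-term ratios (the empirical FDRs) are reported.

The default 100 permutations bound the resolution of FP(τ) at roughly
1/(100·TP); the count is configurable. Gene classification: a gene joins a
term's set iff its −log10(p) ≥ τ for that term; the transgene-specific set
is aS minus Age minus Genotype. Interaction-significant genes stay in the
specific set by default (a flag subtracts them): specificity is defined
against age and background main effects, and a background-dependent
transgene response is still a transgene response.

## Developmental age estimation

Class-I age-responsive genes rise linearly in log2 expression inside the
46–54 h window. The calibration (slope in log2/h, intercept at 46 h, per
marker) is treated as external input — in practice it comes from prior
time-course literature; the generator ships a synthetic stand-in. Given
marker values x_m for one sample, the age estimate is the least-squares
inversion

â = 46 + Σ_m s_m (x_m − b_m) / Σ_m s_m²,

i.e. inverse regression pooled over markers, with a standard error from the
residual spread across markers. This is one faithful reading of the
procedure; the regression direction and weighting are not uniquely
determined by its description, so the estimator is unweighted by default
with slope-squared weighting as an option. Estimates are exact on noiseless
in-window samples and unbiased to first order under additive marker noise
(mean absolute error ≈ 0.04 h with 50 markers at noise sd 0.25 —
measured by the acceptance script). Estimates outside the window are
reported but flagged, since linearity is only asserted inside it.

## Introgression mapping

"A marker gene missing for the wild-type background" is operationalised as
nearest-centroid assignment: for marker m in line L, compare L's mean
expression to the N2 centroid and the wild-background centroid; the nearest
wins, with calls inside a margin (0.5 × centroid separation by default)
labelled ambiguous. Per chromosome, maximal runs containing at least
`min_run = 3` N2-like calls become intervals; ambiguous calls bridge runs
but do not count toward the minimum — isolated miscalls therefore neither
create nor break intervals. Interval bounds are the outermost N2-like
marker positions (1-based inclusive Mb), so the boundary error is bounded
by one marker spacing when calls are correct. The PCR-panel route reports
the N2-call span plus an uncertainty zone extending to the nearest flanking
background calls, representing explicitly that sparse panels cannot resolve
precise breakpoints.

## Enrichment

Gene groups are defined by −log10(p) > 2 (p < 0.01) per term. Each GO term
is tested with the upper-tail hypergeometric probability P(X ≥ k),
enrichment only. The tail is evaluated with exact integer arithmetic
(binomial coefficients), so small configurations agree *rationally* with
brute-force enumeration; scipy's floating-point tail serves as an
independent cross-check in the tests. The universe defaults to array genes
carrying at least one annotation (the all-genes option is exposed; which
one the original analysis used is unknowable from its description, and the
choice shifts K and N together, mostly mildly). Adjustment is
Benjamini–Hochberg step-up; terms overlapping the group in fewer than 5
genes are kept in the full output but dropped from the ranked report. GO
graph propagation (ancestor closure) is deliberately out of scope: the
annotation is taken as given, flat.

## Phenotype and survival statistics

Phenotypes are analysed with `value ~ aS * genotype`: Type II two-way ANOVA
(statsmodels OLS underneath) and Tukey HSD over the full family of
(genotype × transgene) groups, from which the within-background wild-type
vs transgenic contrasts are extracted with their family-adjusted p-values.
Unbalanced tables — the norm once worms are censored — are why Type II is
the default here too.

Lifespan uses the Kaplan–Meier product-limit estimator (lifelines).
Bagging (matricidal hatching) and crawl-off right-censor lifespan at their
time; bagging additionally counts as the event in the bagging-rate
analysis, which compares per-line proportions with a two-sided Fisher exact
test. Mean lifespan is computed over death events only. The log-rank test
is lifelines' chi-square; a time-restricted variant administratively
censors every observation at the bound first, preserving risk sets rather
than subsetting deaths — this reproduces "first d days" comparisons for
crossing survival curves. The mean-lifespan comparison is exposed both as a
Welch t-test and through the Tukey family, since either is defensible.

## The synthetic-data generator

The generator realises exactly the structural model the analysis fits, plus
i.i.d. Gaussian noise on the log2 scale (sd 0.25 by default — a typical
residual sd for log-intensity microarray data). Defaults mirror the study
design: 5 backgrounds × {wild type, transgenic} × 3 replicates = 30 arrays,
batches assigned replicate-wise; wild-type cells at 51 h developmental age
with transgenic lines delayed 0.5–2.5 h depending on background (the
transgenic lines are always the younger ones); 300 age-responsive genes
with strictly positive slopes in 0.2–1.0 log2/h, 50 of them designated
calibration markers; 200 genotype-responsive, 100 transgene-responsive
(±1 log2) and 100 interaction genes; and a wild-isolate marker grid every
0.5 Mb on chromosomes IV and V with a 2.0 log2 background offset, zeroed
inside the introgressed blocks (IV: 4.2–13.2 Mb in every transgenic line,
plus V: 6–9 Mb in one). Replicate-level age jitter (sd 0.3 h) represents
biological scatter in developmental timing; it is also what makes the age
slope identifiable within design cells.

Phenotype and survival layers: development time Gaussian (sd 1.5 h),
pumping and thrashing Poisson around structural means (≈130 counts/30 s at
the L4 stage with no transgene effect, ≈240 counts/60 s at day 3 with
background-specific deficits, ≈600 activity counts/30 min), lifespans
Weibull (shape 4, scale 20 d) with background-specific transgene scale
factors, bagging probabilities elevated in transgenic wild-isolate lines,
and 100 worms per line. The phenotype variances are package defaults chosen
to be realistic for these assays, not estimates from data — no variance
components are published for them — and should be treated as placeholders
when calibrating against real measurements.

What the generator does *not* emulate: probe-level structure (one row per
gene throughout), dye/channel effects and spatial artefacts, correlated
gene modules (noise is independent across genes, so permutation-null
behaviour on real arrays — where correlation inflates the variance of
FP(τ) — will be somewhat noisier than the tests show), non-linear age
trajectories outside the calibration window, and day-quantised survival
observation (times are continuous; daily rounding is a thin wrapper away).
Passing tests therefore demonstrate correctness of the procedures and their
calibration under the stated model, not robustness to every failure mode of
real microarray data.

## Numerical choices and scales

Problem sizes in the test suite and acceptance script: FDR calibration runs
50 simulated experiments of 2000 genes × 30 arrays with 100 permutations
each; effect-size recovery 100 experiments of 200 genes; age recovery 100
experiments with 50 markers; introgression recovery 100 experiments scored
over 300 blocks; log-rank calibration 500 experiments of 100 worms per
group with 15% bagging. Exactness checks: hypergeometric tails against full
subset enumeration for universes up to N = 20; factorial-ANOVA and log-rank
fixtures against independently computed oracle values at 1e−9; noiseless
identities at 1e−9 or tighter. p-values are floored at 1e−300 before taking
−log10. Random streams are split per generator stage (expression,
phenotype, survival, annotation) from the one seed, so adding a stage never
perturbs another's draw.
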
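# Methods

## Data model and transform

The input is a complete genes × samples matrix of quantification-cycle
values (Ct/Cq/CP, in PCR cycles) with a sample → group mapping; each
group (typically a species or experimental condition) is analysed as an
independent panel. Missing values are a hard error rather than imputed:
every statistic below is a function of the full matrix, and imputation
would silently change all of them. Panels need at least 3 genes (geNorm
stepwise exclusion and the NormFinder correction, which divides by
g − 2, both require it) and by default at least 3 samples.

geNorm and NormFinder operate on relative quantities

    q[g, s] = E_g ^ (min_s' Ct[g, s'] − Ct[g, s]),

the comparative-Ct transform with each gene's most-expressed sample set
to 1. `E_g` is the per-cycle amplification factor, `E = 2` (perfect
doubling) by default and overridable per gene, including conversion from
a standard-curve slope via `E = 10^(−1/slope)`. The default of 2 is
deliberate: the packaged dataset's published statistics are reproduced
exactly under E = 2 and not under the gene-specific standard-curve
efficiencies, so E = 2 is evidently what the original analyses used; it
is also what keeps the ΔCt/geNorm identity (below) exact. BestKeeper and
the comparative ΔCt method use raw Ct by definition.

## The four stability estimators

**geNorm.** Pairwise stability of genes j, k is the sample SD
(denominator n − 1 throughout the package) across samples of
log2(q_j / q_k); M_j is the mean over all partners k. Ranking is by
stepwise exclusion: recompute M on the remaining subset, drop the
largest-M gene, stop at two genes, which are tied at rank 1 (a single
ratio cannot separate its two members; they are listed in input order).
Ties in the largest M are broken by excluding the later gene in input
order — deterministic, and only reachable on degenerate input. The
per-gene value reported in the exclusion trace is the *average* M of the
panel from which the gene was excluded (the quantity geNorm's stability
chart plots, and the one the dataset's published tables contain — a
gene's own M at exclusion does not reproduce them); the final pair carry
their common pairwise M. Pairwise variation uses normalisation factors
NF_n = geometric mean of the top-n genes' quantities per sample;
V(n/n+1) = SD across samples of log2(NF_n / NF_{n+1}), for
n = 2 … g − 1, computed directly on log quantities for numerical
stability. The recommended panel size is the smallest n with
V(n/n+1) < 0.15 (threshold configurable); if none qualifies the full
gene count is returned with a flag rather than a silent default.

**NormFinder (single-group form).** On y = log2 q the additive model
y_ij = α_i + β_j + ε_ij with Var(ε_ij) = σ_i² is fitted by
double-centring: z_ij = y_ij − ȳ_i· − ȳ_·j + ȳ_··. Because each
column mean mixes all genes' noise, the raw residual variance
u_i = Σ_j z_ij² / (n − 1) has expectation σ_i²(g − 2)/g + S/g² with
S = Σσ², so the unbiased moment estimate is

    σ̂_i² = max(0, (u_i − U / (g(g−1))) · g / (g−2)),   U = Σ_i u_i,

and the stability value is σ̂_i. Negative corrected variances — expected
at small g, or when a pair of genes tracks the sample effect almost
perfectly (it happens on the packaged yak panel) — truncate to zero
before the square root. Each group is one condition here, so the
grouped inter/intra-group decomposition of the original estimator is out
of scope. The log base scales every stability value by a constant and
can never change a ranking; published stability values from applet runs
of unknown configuration are therefore only matched loosely (±0.05 on
the packaged data), while rankings are matched exactly.

**BestKeeper.** Per gene on raw CP: geometric mean (exp of mean log),
arithmetic mean, extremes, SD defined as the mean absolute deviation
about the geometric mean — *not* the n−1 root-mean-square SD, which on
the packaged data is visibly different (e.g. 0.22 vs the published 0.16
for one gene) — CV% = 100·SD/arithmetic mean, and x-fold versions
min = −2^(geoMean − minCP), max = +2^(maxCP − geoMean), SD = 2^SD
(base 2 by default, configurable per analysis). Genes with SD > 1 cycle
are excluded; the BestKeeper index is the per-sample geometric mean CP
over the surviving genes (a flag forces all genes in, since published
index compositions are not always stated). Pearson r between all gene
pairs and between each gene and the index carries a two-sided p from the
exact t transform t = r·√((n−2)/(1−r²)) on n−2 df (scipy's
`pearsonr`); raw p-values, no multiplicity correction, matching how such
tables are conventionally reported. A zero-variance gene yields an
undefined correlation, reported as NaN with a warning.

**Comparative ΔCt.** Gene j's score is the mean over partners k of the
sample SD of (Ct_j − Ct_k). Since SD ignores additive constants,
SD(Ct_j − Ct_k) = SD(log2(q_j/q_k)) exactly when E = 2, making the ΔCt
score identical to the full-panel geNorm M — the property tests assert
this to 1e−12 and use it as a cross-method oracle.

**Consensus.** Each method contributes an integer rank per gene (geNorm
by the exclusion trace, others by their scores ascending), ties sharing
the minimum rank (competition ranking; "average" available). The
consensus score is the geometric mean of the four ranks, bounded by
their min and max; genes are ordered ascending. Min-rank ties are the
default because they reproduce every decomposable published consensus
score on the packaged data (e.g. a top score of (1·1·4·1)^¼ = 1.41
requires the tied geNorm pair to both hold rank 1). No method weighting
is applied.

## Packaged dataset

`builtin_dataset()` returns the 32-sample × 10-gene PBMC panel of six
Leh-Ladakh livestock species at the 3-decimal precision of the source
table; no attempt is made to recover more digits, as that table is the
ground truth from which its published statistics were computed (several
are reproduced exactly from these values — the test suite pins the
geNorm final-pair Ms of all six species, two V values, BestKeeper SDs
and orderings, NormFinder orderings, and the complete cattle consensus
score vector). The source's prose mentions 37 samples in one place;
the data table has 32 and the fixture follows the table.

## Synthetic generator

`generate(SyntheticSpec(...))` draws Ct[g, s] = baseline_g + b_s + e_gs
with b_s ~ N(0, τ) a shared per-sample loading shift (additive on Ct =
multiplicative on quantity, exactly what geometric-mean normalisation
factors assume) and e_gs ~ N(0, σ_g) gene-specific noise — σ_g is the
injected instability each method should recover. Defaults: 10 genes ×
6 samples (the shape of a typical candidate panel), baselines uniform on
14–30 cycles (the span of the packaged data), τ = 0.5 cycles (a
realistic loading/RT variation), σ_g graded 0.1–1.0 cycles so the panel
spans stable to borderline-unusable candidates. Everything is
deterministic given the seed. `recovery_experiment` reruns all four
methods over replicate draws and reports per-gene mean ranks and the
Spearman correlation between σ_g and each method's score; at 10 genes ×
20 samples over 50 replicates, geNorm and NormFinder exceed ρ = 0.8 in
at least 45 of 50 draws, and BestKeeper's SD estimates σ_g·√(2/π) (the
expected absolute deviation of a Gaussian) within sampling error. What
the generator does *not* emulate: amplification-efficiency error,
outliers, dropouts/missingness, or correlated regulation between genes —
so passing recovery tests show the estimators invert their own model,
not that they are robust to real-data pathologies.

## Numerical and design choices

- All SDs use denominator n − 1; validated against the published
  3-decimal statistics of the packaged data.
- Geometric means of quantities are computed as means of log2 q to avoid
  under/overflow on long Ct ranges.
- Iteration orders are fixed everywhere (input gene order, insertion
  ordered dicts), so two runs on identical input produce byte-identical
  CSV output; tables are written at full precision, with rounding
  applied only in the human-readable `summary()`.
- `efficiency_from_slope` implements the textbook formula; published
  efficiency percentages computed from rounded slopes will not match it
  exactly, and no attempt is made to emulate that.
- The CLI is a thin layer over the library (`run`, `fixture`,
  `simulate`); `consensus` requires all four base methods and refuses a
  partial set rather than silently reranking.

## Known limitations

Single-group NormFinder only; no grouped inter/intra-group variance
decomposition, no two-gene combined-NF suggestion. BestKeeper's
regression of genes on its index and weighted index variants are not
implemented. No instrument-native formats (RDML, .eds) — delimited text
only — and no efficiency estimation from raw fluorescence. Consensus
offers no method weighting or bootstrap confidence. The plotting hook
(`StabilityResults.plot_m`) is a convenience and deliberately untested.
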
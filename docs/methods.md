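# Methods

## Scope and model

`radiosig` implements a staged screen for genes whose expression behaviour
links to cellular radiosensitivity. Radiosensitivity enters only through
SF2, the clonogenic surviving fraction at 2 Gy, one number per cell line in
(0, 1]. Expression enters z-scored per gene; all coefficients below are per
z-unit of expression.

### Time-response filter

Per gene, a one-way ANOVA across timepoint groups, with cell lines acting as
replicates. The p-value is unadjusted and thresholded at `anova_alpha`
(default 0.05): the filter is deliberately liberal, because later stages are
the real gatekeepers. Degenerate genes are resolved explicitly: a constant
gene is p = 1 (dropped); zero within-group variance with distinct means is
p = 0 (kept).

### Profile clustering

Gene series are summarized as the per-timepoint mean over cell lines and
transformed to change-from-0 h (a level shift cannot alter assignments; the
difference is used, not a log-ratio, because inputs are z-scores and may be
negative). Model profiles are integer unit-change curves, |change| ≤ c per
interval, enumerated exhaustively ((2c+1)^(T−1) candidates), flat excluded;
m representatives are chosen by deterministic greedy max–min selection on
the correlation distance. Defaults c = 2, m = 50, n_perm = 1000 follow the
published defaults of short time-series expression mining; none are dictated
by the data, all are configurable.

Significance: each gene's timepoint labels are permuted and genes are
re-assigned, giving each profile's expected size. The default p-value refers
the observed size to a Binomial(n_assigned, f̂) upper tail with f̂ the
permutation-estimated expected fraction — the convention of the short
time-series miner. A pure empirical tail, (1 + #{perm ≥ obs})/(n_perm + 1),
is available as `method="empirical"`; note its resolution is bounded by
1/(n_perm+1), so with m = 50 profiles and BH correction it cannot reach
q < 0.01 at rank ≤ 2 — a floor worth knowing about when lowering n_perm.
BH is applied across all m profiles; significance is q < 0.01.

### Eigengene screen

A cluster's eigengene is PC1 of its standardized member × cell-line
submatrix at the untreated (0 h) timepoint. PC sign is fixed by requiring a
non-negative correlation with the mean member profile, removing backend
indeterminacy. Clusters pass at |Spearman ρ| > 0.1 against SF2. The absolute
value is the default because a protective (negatively correlated) cluster is
as informative as a sensitizing one; `signed=True` restores a one-sided
reading. Constant eigengenes map to ρ = 0 rather than erroring so batch
screens never abort. Spearman makes the screen invariant under any strictly
monotone transform of SF2.

### Single-gene models

**SGLQ.** ln SF2 = αE − βE², no intercept, by OLS — linear in parameters, so
noise-free data identify (α, β) exactly and SF(E = 0) = 1 by construction.
α and β are not constrained non-negative: E is z-scored and can be negative,
so the signs carry orientation, not physics. The gene "performs well" when
the overall regression F-test has p < 0.05 (configurable). Rank-deficient
designs (constant expression) and SF2 without variation fail gracefully with
`pass = False`. The reported R² is the uncentered coefficient of
determination, the standard convention for no-intercept fits.

**Forest.** One joint regression forest predicts SF2 from all candidate
genes (500 trees, 1/3 of features per split, leaf size 5 — classical
regression-forest defaults). Importance is the mean increase in out-of-bag
MSE when a gene's out-of-bag values are permuted, computed per tree over
explicit bootstrap/out-of-bag partitions so a fixed seed is bit-reproducible.
A gene passes when importance is strictly positive. "Did not perform well in
both models" is then: excluded iff it fails the F-test and has
non-positive importance — passing either route retains the gene.

**Dose linearity.** For dose–expression curves, polynomials of degree 1–3
are compared by AIC = n·ln(RSS/n) + 2k (k includes the intercept; RSS
clamped at 1e−12 with a warning). The selected degree is the *smallest*
within 2 AIC units of the minimum. The parsimony window matters: a strict
argmin accepts an extra parameter whenever the χ²₁ improvement exceeds 2,
which happens ~16% of the time under the true model, so strict argmin picks
the true linear degree only ~79% of the time regardless of noise level; the
ΔAIC ≤ 2 equivalence rule is the standard information-theoretic remedy and
is exposed as `parsimony_delta` (0 restores strict argmin).

### Multi-omics network

Mutation and copy-number layers carry non-negative node heats (mutation
frequency; absolute copy-number deviation) on the protein-interaction
topology. Insulated diffusion per connected component:
F = β(I − (1−β)W)⁻¹ with W the column-degree-normalized walk matrix and
β = 0.4 the restart probability; exchanged heat E_ij = F_ij·h_j. Column sums
of F are exactly 1, so heat is conserved per source — a property the tests
check analytically. Edges with min(E_ij, E_ji) above δ are hot. The original
HotNet2 selects δ by permuted-heat networks; here δ is configured directly
or derived as a quantile of the min-exchange distribution (default the
99.9th percentile), because the package's validation is oracle- and
recovery-based rather than FDR-based; an isolated node keeps its own heat.

The co-expression layer uses adjacency |r|^power (power 6), topological
overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average
linkage on 1 − TOM cut at height 0.99, minimum module size 30, and merging
of modules whose eigengenes correlate above 0.75 — a fixed-height stand-in
for dynamic branch cutting with the usual WGCNA defaults. Within-module
pairs above the 0.9 TOM quantile become layer edges. The protein layer is a
plain weighted edge list filtered at confidence ≥ 0.7 (STRING-style scale).

The union graph is unweighted. Hubs are nodes whose degree, shortest-path
betweenness and closeness are each *strictly* greater than the median over
all nodes — ties at the median are not hubs, reading "> median" literally;
a regular graph therefore has no hubs. Harmonic closeness is the default
because union graphs are routinely disconnected (classic closeness is a
flag). Centralities are computed on the **full** union graph and the hub set
is intersected with the funnel's retained genes. Computing medians on the
candidate-induced subgraph instead (available via `hub_scope="candidates"`)
is self-defeating when the retained genes form a near-clique: the median
then falls inside the candidate group and the strict rule discards half of
any homogeneous signature.

### Over-representation

One-sided hypergeometric upper tail per gene set (sets intersected with the
universe), BH across sets. A zero overlap has p = 1 under the upper-tail
convention P(X ≥ 0).

## Synthetic data

The generator emulates the study conditions the analysis assumes: 2,000
genes × 16 cell lines × six timepoints (0–24 h); 20 signature genes split
over 2 planted archetypes (maximally separated unit-change curves, peak
amplitude 1.5 z-units) with Gaussian expression noise (sd 0.5); background
genes are pure time-independent noise, so the ANOVA filter is exactly
calibrated on them; 4 blocks of 60 background genes share a per-line latent
factor to give the co-expression stage modules to find. Cell lines carry a
latent radiosensitivity factor (correlation 0.9 with signature baselines);
SF2 is exp of the mean planted SGLQ response (α = β = 0.3) over signature
genes plus log-scale noise (sd 0.05), clipped to (0, 1] — with these values
ln SF2 stays almost entirely ≤ 0, so clipping is rare and SF2 spans roughly
0.2–1. The interaction network is Erdős–Rényi with mean degree 8; signature
genes are additionally wired at density 0.8 (the induced subgraph must be
connected, else generation errors) with edge confidences drawn higher than
background; mutation/CNA heats are exponential with the signature mean
multiplied by 5. Default seed 20220810; every stochastic step derives its
stream from the config seed, so bundles are byte-identical across runs.

Two planted archetypes (10 genes each) rather than many small ones is a
power choice made up front: against a 50-profile permutation null that also
absorbs the ~100 ANOVA false positives, a cluster needs roughly ten planted
members to clear q < 0.01.

What the generator does *not* model — and what passing tests therefore do
not show: microarray probe/platform effects, batch structure, count noise,
line-specific temporal shapes, survival outcomes, or any dependence between
background genes and SF2. Recovery results on this generator demonstrate
internal consistency of the pipeline, not field performance on real cohorts.

## Numerical choices

Variance guards use an absolute tolerance of 1e−12 on standard deviations;
degenerate correlations map to 0. Assignment ties break to the lowest
profile id; greedy library selection is fully deterministic. Permutation
p-values in empirical mode use the plus-one convention and live in
[1/(n_perm+1), 1]. The diffusion quantile δ is computed over all
off-diagonal min-exchange values; zero-exchange pairs are never hot edges,
so δ = 0 recovers the layer's connected components exactly. Funnel
percentages are rounded to one decimal at the reporting boundary only.

## Problem sizes used in validation

The shipped checks run the full pipeline once at the reference conditions
(2,000 genes), 100-seed null-calibration and screen-robustness sweeps at the
same noise settings, 10,000-gene ANOVA calibration, 200-replicate SGLQ bias
estimation, and oracle comparisons on 100 random graphs of ≤ 10 nodes
(diffusion) and ≤ 8 nodes (centralities) — sizes chosen so each property is
measured with comfortable Monte-Carlo margin on a single CPU.

## Known limitations

* The SGLQ model is a single-gene caricature: it ignores gene–gene
  correlation, so planted coefficients are recovered exactly only when SF2
  is generated from that one gene; with a shared latent factor the fitted
  coefficients are attenuated (the screen uses the F-test, not the
  estimates, for this reason).
* The binomial profile p-value treats the permutation-estimated expected
  fraction as known; with very few assigned genes it is anti-conservative,
  which the n_perm ≥ 100 warning partially addresses.
* Hot-edge selection by quantile fixes the edge budget rather than an error
  rate; use the explicit δ with an external calibration when an FDR
  interpretation is needed.
* Hub calls depend on the union graph's composition; adding or removing a
  layer shifts the medians and hence the hub set.
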
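# Methods

## Drift

For a feature × sample matrix `X` and a designated reference (young)
group, drift is `md(i, s) = log(X[i,s] / mean_ref(X[i,:]))` (natural log
by default; base 2/10 configurable). Transcriptome mode first removes
features whose reference mean falls below the 20th percentile of
reference means and adds a +5 pseudocount on the FPKM scale, matching
the `log2(FPKM+5)` display transform used elsewhere in the pipeline;
metabolome mode applies neither (imputation removes zeros). When
centering is enabled (default) the grand mean of all drift values is
subtracted, so library-depth offsets cannot masquerade as spread. The
group-level statistic is the sample variance of the pooled per-feature,
per-sample drift values of that group — pooled values are what
box-and-whisker displays of drift show, so they are the natural test
unit; per-sample variances are also reported for transparency.

Spread is compared across groups with the Brown-Forsythe test (Levene
with median centers): one-way ANOVA on |y − group median|. The
implementation delegates to `scipy.stats.levene(center="median")` with
explicit handling of the all-identical degenerate case (F = 0, p = 1).

Drift of the treated groups is always computed against the same young
reference, so suppression appears as variance interpolating between the
old and young values.

## Differential analysis

Genes: the expression filter keeps genes with CPM strictly above 1 in
at least ⌈n/2⌉ samples. Between-sample scaling uses the trimmed mean of
M-values (TMM): reference column chosen by closest 75th percentile of
library-scaled counts, genes with a zero in either column excluded,
M-values doubly trimmed (30% per tail on M, 5% per tail on A), and the
precision-weighted mean exponentiated; factors are rescaled to
geometric mean 1. The implementation follows the published algorithm
and agrees with Bioconductor's edgeR `calcNormFactors` to ~1e-12 on
random fixtures (cross-checked in the test suite via Rscript when
available, and against an independent brute-force recomputation
always).

Testing uses Welch two-sample t-tests on `log2(CPM+1)` computed over
effective library sizes (raw totals × TMM factors), with
Benjamini–Hochberg FDR (via `statsmodels`) and the significance rule
FDR < 0.05 AND |log2FC| > 0.3, both strict. This is a deliberate
simplification of a count GLM with tagwise dispersion: the package's
contribution is the drift/threshold/network layer, and the Welch test
keeps the significance machinery transparent and oracle-testable.
Exact GLM parity is a non-goal. The `+1` offset attenuates fold
estimates for very low-expression genes; this is visible in parameter-
recovery tests and documented rather than corrected.

Metabolites: missing entries are replaced by the metabolite's minimum
observed value across samples (missingness is modelled as censoring at
low abundance, which this rule approximates), then
`glog(x) = ln((x+√(x²+λ²))/2)` stabilizes variance, with λ defaulting
to the smallest positive observed value. Welch tests run on the glog
scale at FDR < 0.05 with no fold threshold (the fold-change rule above
is a gene-specific convention); reported fold changes are ratios of
raw-scale group means. Signature comparisons partition two contrasts'
significant sets into shared/unique and report Pearson correlations of
signed log2 fold changes per partition (undefined, not 0, below 3
features). Signed log-folds are used rather than magnitudes so reversal
of direction under treatment is visible as negative correlation.

## PCA, ellipses, clustering

Transcriptome PCA operates on `log2(FPKM+5)` of the top-expressed genes:
genes are scored by the row sum of `log2(FPKM+5)` and the top 10% kept
(ties at the realized cutoff all kept). Components come from a full SVD
with samples as observations, mean-centered; each component's
largest-magnitude loading is made positive so signs are reproducible.
Group ellipses on PC1/PC2 are multivariate-normal contours
`(x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(level)` with sample mean and covariance and a 70%
level by default (χ²₂(0.70) = 2.4079). The χ² (known-covariance) form is
used rather than a small-sample Hotelling-T² form: at n = 5–6 per group
this is a display convention, recorded as such. Metabolome PCA runs on
glog-transformed abundances with the same ellipse level.

K-means clusters z-scaled `log2(FPKM+5)` profiles (zero-variance rows
dropped) with Euclidean distance, 10 restarts and a fixed seed; k
defaults to 6 and is configurable since the number of expression
programs is not identifiable a priori. The "aging-up" cluster is the
one maximizing (old − young) + (old − mean treated) of cluster-average
z-scores.

## Enrichment

`score = (k/m)/(K/M)` with k significant detected members of the set, m
detected members, K/M the global counts; sets are intersected with the
detected universe first, and sets with fewer than 2 detected members
are skipped (the minimum-size rule is a package default, documented
since upstream conventions vary). An upper-tail hypergeometric
P(X ≥ k) supplements the score for ranking stability — the score is
the primary display quantity, the p-value an extension. Fisher overlap
tests report the conditional-MLE odds ratio and the exact two-sided
p-value. Gene-pathway enrichment uses the same machinery on
user-supplied GMT files with the expressed genes of the contrast as
background.

## Network integration

Nodes are metabolites; undirected edges are reactions annotated with
one or more enzyme genes. Scores are `-log10(p) + log10(p0)` with
p0 = 0.05: a feature exactly at baseline contributes 0, significance is
positive, and an edge takes the best (smallest-p) annotated gene.
Features absent from the statistics tables get a mild penalty (−0.1)
so unmeasured nodes can be traversed but not accumulated freely;
p-values of exactly 0 are clipped to the smallest positive float with a
warning. This transparent scoring stands in for mixture-model-derived
weights used by dedicated active-module tools; it keeps every score
auditable from the differential tables.

The module is the connected node set maximizing the sum of node scores
plus induced-edge scores. Components with ≤ 12 nodes are solved by
exhaustive enumeration over connected subsets (bitmask scan). Larger
components use a multi-restart steepest-ascent search
(add-neighbor/remove-node moves preserving connectivity) with iterated
basin hops: each local optimum is perturbed by forcing one boundary
node in (two on components ≤ 20 nodes, where edge-pair restarts are
also affordable) and re-ascending, accepting improvements. During
design this matched the exhaustive optimum on 3000 random ≤ 8-node
graphs without a miss. If nothing scores positive the module is empty
with score 0.

The capture null permutes the feature-identifier column of the gene and
metabolite tables independently (statistics kept, labels reassigned —
sampling without replacement), rescores, re-runs the search, and
records whether the query metabolite is captured; `pnull` is the
capture fraction over 10 shuffles by default. Across experiments the
aggregate is `p = pnull^na · (1−pnull)^nb` (0⁰ = 1), implemented
exactly as defined; note this is a likelihood-style product, not a
calibrated tail probability — with pnull = 0 it returns 0, and an
optional (captures+1)/(shuffles+1) pseudo-count estimator is available
but off by default. When the pipeline runs several network contrasts it
uses the largest per-contrast pnull (conservative) for aggregation,
with na/nb counted over the real-label runs; both are also exposed as
explicit arguments.

## Synthetic data

The generator emulates the study conditions, not a dial to turn per
test. Defaults: four groups (young, old, old+A, old+B) of n = 6; 2000
genes of which 5% are age-shifted with log2 fold changes drawn
N(0, 0.8) — the ~2–4% differential fraction typical of a bulk aging
contrast; treatment suppresses the aging shift multiplicatively on the
log scale (A: s = 0.9, B: s = 0.5; s = 1 restores the young mean
exactly); counts are negative-binomial (gamma-Poisson, dispersion 0.05)
around lognormal baseline means; FPKM assumes unit gene lengths, so
values are library-scaled relative abundances, which is all the
FPKM-based steps use. The metabolome plants exactly the named folds
{α-ketoglutarate 9.51, succinate 7.85, citrate 6.19, aconitate 5.73,
acetyl-CoA 0.5} (old/young) on a 50-metabolite table; within-group
variability is lognormal with CV 0.2 — a free parameter, since group
folds do not pin down within-group spread; entries below a metabolite's
10th percentile go missing with probability 0.3, motivating the
minimum-value imputation rule. All draws come from stream-separated
generators keyed on one seed, so outputs are byte-reproducible and the
ground truth (affected genes, true folds, suppression, module nodes) is
exact.

The toy network is a star of the hub (acetyl-CoA) and the other named
metabolites, its edges annotated with the most strongly age-shifted
genes; background metabolites attach through a random tree anchored at
the module periphery (never the hub) plus extra background-only edges
(~average degree 3). Keeping the hub's degree equal to the planted
star's means identifier-shuffle capture reflects chance rather than
topological centrality — in a 50-node toy, a high-degree hub would be
captured as a bridge in a large fraction of shuffles regardless of
signal.

What the generator does **not** emulate: a genome-scale feature count,
hundreds of age-shifted metabolites, acyl-carnitine chain structure,
tissue differences, metabolite correlation beyond the planted module,
or batch effects. Passing tests therefore demonstrate that the
machinery recovers known truth under idealized bulk-omics noise, not
that it reproduces any specific biological dataset; dataset-level
results (DE counts, exact cutoffs) depend on the real data and exact
upstream tooling and are out of scope.

## Numerical choices and degenerate inputs

- Quantiles everywhere are linear-interpolation (type 7), matching the
  surrounding ecosystem's default.
- Welch tests with zero variance in both groups return p = 1 for equal
  means and p = 0 otherwise.
- `brown_forsythe` on all-identical deviations returns (0, 1).
- BH on an empty vector returns an empty vector.
- Ties at the top-expression cutoff are all kept.
- Module search ties are broken toward the earlier restart; scores
  within 1e-12 are treated as equal.
- All simulation-based tests fix seeds; k-means uses seeded restarts.

## Problem sizes

Simulation-backed tests and examples run at the study's group sizes
(4 × 6 samples) with 2000 genes and 50 metabolites, and 10–50 seeds per
property — sizes at which every planted parameter is comfortably
recoverable and the full suite runs in well under a minute of compute
per module.

## Known limitations

- Welch-on-logCPM is less powerful than a dispersion-shrinking count
  GLM at n = 6 and attenuates folds for very low-count genes.
- The capture-null aggregation is reported as defined; it should be
  read as evidence strength, not a frequentist p-value.
- The module search is exact only up to the enumeration limit;
  beyond it the basin-hopping heuristic has no optimality guarantee.
- Drift centering is global (one grand mean), with the per-sample
  alternative intentionally not implemented.
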
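# Methods

## Edge transformation

The per-sample edge value of a gene pair is the product of the two genes'
population z-scores, `e_ijk = z_ik · z_jk`. The z-scores use the population
variance convention (divide by *n*, not *n* − 1): with the sample
convention the defining identity — the mean of `e_ijk` over samples equals
the Pearson correlation of the pair — would fail by a factor (n−1)/n. The
transformation is location- and scale-invariant per gene, and permuting
sample columns permutes edge columns identically.

Degenerate inputs: genes with zero variance cannot be z-scored and are
dropped with a logged report; pairs touching a dropped gene are removed.
Missing expression cells are imputed by the row mean by default
(`SampleMatrix.impute_row_means`); callers who prefer to drop incomplete
genes can do so before transforming. All-pairs enumeration is row-major
over the upper triangle of the expression row order, and edge ids are
`geneA--geneB` with members in row order, which fixes a deterministic edge
order everywhere downstream. Edge matrices are computed in row blocks with
bit-identical output for any block size, so the g(g−1)/2 explosion of the
all-pairs case is bounded in memory.

## Association engine

Covariates are handled by residualize-then-correlate: both genotype and
trait rows are projected onto the orthogonal complement of
{intercept, covariates}, the per-pair correlation r of the residualized
rows gives `t = r √(df/(1−r²))` with `df = n − 2 − #covariates`, and the
slope β is reported on the original trait scale. This is algebraically the
partial-regression t-test, and the tests verify it against explicit
full-design OLS fits per pair to 1e−8. The ANOVA variant codes genotype
classes 1 and 2 as indicators against baseline 0 and compares the full
model with the covariate-only model by F; SNPs with one class present are
skipped, with two classes the numerator df drops to 1.

Because edge-level designs can reach billions of tests, only records with
`p ≤ p_report_threshold` are materialized (defaults 1e−2 for gene traits
and 1e−5 for edge traits in the pipeline), while the total test count is
always retained. Benjamini–Hochberg q-values are computed against that full
multiplicity; this is exact because every unmaterialized test has larger p
than every materialized one. Underflowed p-values are floored at the
smallest positive double rather than 0. The permutation (empirical) FDR
permutes genotype sample columns — preserving the trait correlation
structure while breaking genotype–trait links — and reports the mean ratio
of permuted to observed discovery counts at a fixed threshold; with zero
observed discoveries the estimate is undefined and returned as NaN.

## Simulation generators

Both generators draw a shared population signal `pop = 0.2·N(0,1)` per
sample and SNP rows `N(0,1) + pop`; genetic effects ramp as
`effect_scale · (rank/n_traits)^effect_exponent`, so each dataset spans
undetectably weak to strong planted links. The defaults exponent 9 and
scale ½ follow the reference R simulation `((1:n)/n)^9/2`, in which `^`
binds tighter than `/` — i.e. `(rank/n)^9 · ½`, not `(rank/n)^4.5`. We
checked both readings by execution at desk scale: only the `^9/2` reading
reproduces the published benchmark pattern (comparable AUCs on
expression-trait data alongside an edge-level advantage on edge-trait
data), so it is the default; both knobs are configurable.

In the expression scenario every gene receives one uniformly chosen SNP
(without replacement while SNPs suffice) plus its ramped effect. In the
edge scenario gene expression stays pure noise; the baseline edge matrix is
the edge transformation of those genes, and ramped SNP effects plus `pop`
are added to a uniformly chosen subset of edge rows (default 200). How many
edges carry signal is not derivable from the printed design, so the subset
size is explicit configuration. Every planted link counts as a positive for
AUC regardless of effect size, which is why absolute AUCs sit well below 1:
most of the ramp is below the detection floor by construction.

Benchmark scoring uses |t| from the full statistic matrix. Cross-scenario
arms need a scoring convention the design does not dictate: a gene is
scored against edge-level truth by its best member-edge statistic, and an
edge against gene-level truth by the better of its two member genes. AUC is
the Mann–Whitney rank form with midranks for ties, tested against the
exhaustive pairwise comparison.

The desk-scale profile (100 samples, 100 genes → 4,950 edges, 500 SNPs,
200 causal edges) is the package's default study condition; the full-scale
designs (up to 5,000 genes / 12,497,500 edges and 200,000 SNPs) are
reachable through the same configuration but sized for cluster hardware.
What the generators do **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra (genotypes are continuous Gaussian scores), and
count-based expression noise. Passing benchmarks therefore demonstrate the
relative behaviour of edge- versus gene-level mapping under the stated
linear-Gaussian conditions, not performance on real genotype data.

## Hot filtering and modules

Link counts per SNP and per edge are taken at a p threshold over the
materialized records (unreported tests count as non-significant). The hot
filter keeps ids with count ≥ min_count and then the top-k by count, ties
broken lexicographically for determinism; defaults follow the published
case studies (top 1,000 edges; minimum SNP-connection counts of a few
hundred to a few thousand are dataset-specific and left to the caller).
The hot profile holds capped −log10 p (cap 16) or binary indicators.
Clustering is average-linkage agglomerative on 1 − Pearson correlation
(continuous) or Jaccard distance (binary), cut at a fixed k — the source
analyses say only "hierarchical clustering", so linkage, distance and the
default k = 10 are this package's declared choices and k is always logged.
Constant profile rows have no defined correlation distance and become
singleton modules appended after the clustered ones.

## Phenotype links

PLSDA fits a centered two-block PLS against one-hot labels (scikit-learn's
NIPALS implementation), classifies by nearest class centroid in score
space, and reports stratified cross-validated AUC from the continuous
predicted memberships (macro one-vs-rest for >2 classes); defaults are 2
components and 5 folds. CCA solves the first canonical pair via Cholesky
whitening and SVD; each block covariance gets a ridge of
`ridge × mean block variance` (default ridge 1e−3) because modules
typically have more edges than samples, and permutation significance uses
the add-one estimator `p = (1 + #{ρ_perm ≥ ρ}) / (1 + n_perm)` with Y rows
permuted (default 1,000 permutations). The survival link needs a
per-sample module score; since no external scoring service is assumed, the
score is the first principal component of the module's samples × edges
submatrix (sign fixed by the largest loading), followed by a two-group
log-rank test on the median split with standard hypergeometric handling of
tied event times. Cascade ranking is lexicographic: phenotype-link p
ascending, then significant SNP-link count descending, then module index.

## Numerical notes and limitations

Correlations are clipped to [−1, 1] before the t transform; a perfect fit
maps to ±∞ t and the floored minimum p. Blockwise mapping yields record
sets independent of block size. All stochastic operations (simulation,
permutation FDR, CCA/PLSDA validation) take explicit seeds and are exactly
reproducible. Known limitations: no genomic windowing (cis/trans), no
LD-aware pruning or mixed-model correction, no Cox regression (the log-rank
test is the provided survival link), and alternative single-sample network
constructions (reference-based differential networks, cell-specific
networks, leave-one-out interpolation) are out of scope — the edge
transformation is the only construction implemented, with the mapping
layer indifferent to how the edge matrix was produced, which is the
intended extension point.
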
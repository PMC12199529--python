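# Methods

`taxonet` infers and compares co-occurrence networks of microbial genera from
16S rRNA count tables. This note records the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Compositional preprocessing

Sequencing counts are compositional: only relative information is
interpretable, and naive correlations between relative abundances are
distorted by the unit-sum constraint.

**Filtering.** Samples with fewer than 10,000 total reads are removed first.
Genera are then kept only if (i) their mean per-sample relative abundance is
at least 1e-5 and (ii) they are observed in at least 1% of the retained
samples. The abundance rule is interpreted as a mean of per-sample relative
abundances because that reading is scale-free; the alternative reading (mean
raw reads against the grand total) is available through
`FilterConfig(abundance_rule="grand_total")`. Filtering is a single pass —
samples, then genera — and is idempotent. When networks are built per group,
each group is filtered independently.

**Zero replacement.** Log-ratio methods need strictly positive parts. Zeros
are replaced by a Bayesian-multiplicative rule: with a symmetric Dirichlet
prior of total strength `s = sqrt(depth)` and uniform base measure `1/D`, a
zero count is imputed by its posterior expected fraction
`(1/D) * s / (depth + s)`, and non-zero fractions are rescaled
multiplicatively so each sample still sums to one. The square-root prior is a
deliberately weak default (the imputed fraction shrinks with depth); the
prior strength is a parameter.

**CLR.** The centered log-ratio transform, `log x_i - mean_j log x_j` per
sample, is provided for diagnostics and reporting. SparCC operates on the
zero-replaced fractions directly (it forms its own log-ratios), so the CLR
matrix is not an input to the network inference — both surfaces are exposed.

**Alpha diversity.** Shannon entropy uses the natural logarithm. Chao1 uses
the bias-corrected form `S_obs + F1(F1-1)/(2(F2+1))` so it stays defined when
there are no doubletons; the classic `S_obs + F1^2/(2 F2)` form is a flag.
Group comparison uses the two-sided Mann–Whitney test.

## SparCC correlation inference

For taxa `i, j` the log-ratio variance `t_ij = Var(log(x_i/x_j))` decomposes
as `t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)` in terms of basis variances
`w` and basis correlations `rho`. Under the sparsity assumption (most pairs
uncorrelated) the correlation terms average out and the basis variances solve
the linear system `t_i = |K_i| w_i + sum_{j in K_i} w_j`, where `K_i` is the
set of partners of `i` still included. Without exclusions this reduces to the
closed form `w_i = (t_i - T)/(D - 2)`, `T = sum_i t_i / (2(D-1))`.
Correlations follow as `rho_ij = (w_i + w_j - t_ij)/(2 sqrt(w_i w_j))`,
clipped to [-1, 1]. Because strongly correlated pairs violate the sparsity
assumption, the estimator iteratively excludes the most strongly correlated
remaining pair above a threshold (0.1, the original tool's default) and
re-solves, up to 10 exclusions; an exclusion that would leave a taxon with
fewer than two partners is not taken. Basis variances are floored at 1e-10.

The original SparCC tool resamples counts from a Dirichlet posterior and
aggregates over ~20 inner iterations; here zeros are already handled upstream
by the Bayesian-multiplicative step, so a single deterministic pass on the
zero-replaced composition is the default. The estimator is invariant to
per-sample rescaling of its input (a property asserted in tests).

## Edge sparsification

Each correlation is tested against zero with `t = rho sqrt((n-2)/(1-rho^2))`
on `n - 2` degrees of freedom — Pearson's sampling distribution, an
approximation for SparCC estimates that follows the common toolchain
practice. Multiplicity is controlled by the local false discovery rate:
z-scores `z = atanh(rho) sqrt(n-3)` are modelled as a two-group mixture, the
mixture density is fitted by Lindsey's method (Poisson regression of
histogram counts on a polynomial basis), the null component `pi0 N(mu0,
sigma0^2)` is recovered by central matching (a quadratic fit to the log
density around its mode), and edges with `lfdr <= 0.05` are kept. With fewer
than 50 pairs the density estimate is refused and the Benjamini–Hochberg
fallback (`method="bh"`) is advised; the permutation tests use the BH route
at reduced problem sizes for the same reason. The stated significance level
of 0.05 is applied as the lfdr cut-off.

## Networks and global properties

Nodes are genera (isolated ones included — each counts as a component); edge
weight is |rho| with the sign kept as an attribute, and `1 - |rho|` is the
dissimilarity used as shortest-path length. Clustering uses the
Clauset–Newman–Moore greedy modularity algorithm on |rho| weights (the same
agglomerative fast-greedy scheme as igraph's implementation), with cluster
ids fixed by lexicographic order of each cluster's smallest node.

The global properties: number of components; global transitivity (3 ×
triangles / connected triples) on the unweighted skeleton; weighted
modularity of the clustering; positive-edge percentage; edge density
`2m/(n(n-1))`; natural connectivity `ln((1/n) sum_i exp(lambda_i))` over the
unweighted adjacency eigenvalues (computed with a log-sum-exp guard); and the
edge number, defined as the product of edge density and the number of
components. On the largest connected component (LCC): relative size, mean
edge dissimilarity, average shortest-path length over connected pairs using
dissimilarity lengths — reported both raw and divided by the mean
dissimilarity ("units of average dissimilarity") — plus transitivity and
modularity restricted to the LCC. Undefined quantities (positive-edge
percentage or path length of an edgeless graph, modularity without edges)
are reported as missing, never imputed.

## Centralities, hubs, cores

Degree is the unweighted edge count. Betweenness counts shortest paths
(dissimilarity lengths) through a node. Closeness is the inverse average
distance within a node's component with Wasserman–Faust scaling by the
reachable fraction; isolated nodes get zero so that min/max scaling stays
total. Betweenness and closeness are additionally divided by `n - 1`
(the convention adopted here, even though the usual betweenness normaliser is
`(n-1)(n-2)/2`) — the subsequent per-measure min/max scaling makes every
downstream result invariant to this choice, which the tests assert. A hub is
a node strictly above the empirical quantile (default 0.90,
linear-interpolation quantile) on all three scaled measures; strict
inequality avoids inflating hub sets under ties.

Two core-microbiota definitions: (1) genera whose relative abundance exceeds
0.001 in at least 50% of samples; (2) the hub set at a quantile tuned
downward (grid from 0.95 in steps of 0.005) until its size is closest to the
definition-1 core size, preferring the larger quantile on ties — so the two
definitions are compared at matched size. Cores are compared by average
prevalence (mean per-sample percentage of core genera present), cumulative
abundance (per-sample summed counts of core genera, averaged over samples),
and the mean summed min/max-scaled centrality of core members.

Similarity between node sets from two networks uses the Jaccard index with a
permutation null (1000 draws of same-size random subsets of the shared
universe, following the Real & Vargas scheme), reporting the null mean and
one-sided p-values with the +1 small-sample correction. Because both the
Jaccard index and its permutation null are discrete, the test's attainable
type-I level at 0.05 is below nominal (about 0.038 for a universe of 87 and
sets of 25, computable in closed form from the hypergeometric null); the
acceptance suite checks the empirical rejection rate against that exact
level rather than against 0.05 itself, plus a validity bound.

## Graphlet analysis

Graphlets are connected induced subgraphs on 2–4 nodes; an orbit is a class
of node positions equivalent under the graphlet's automorphisms. There are 9
such graphlets carrying 15 orbits, of which orbits 3, 12, 13 and 14 are
redundant (e.g. `o3 = C(o0,2) - o2` and `C(o0,3) = o7 + o11 + o13 + o14`),
leaving 11 non-redundant orbits. Orbits 1, 4, 6 and 9 are the end-node
("terminal") orbits. Counting enumerates every connected induced subgraph on
3–4 nodes exactly once with the ESU scheme over bitmask adjacency and
classifies it by its internal degree sequence; the suite verifies exact
agreement with exhaustive subset enumeration on random graphs. Graphlets are
limited to 4 nodes by design: the subgraph census grows combinatorially, and
the 15-orbit taxonomy is the established working set.

The graphlet correlation matrix (GCM) is the Spearman correlation between
the 11 non-redundant orbit-count columns after appending a pseudo-count row
of ones, which keeps ranks defined for orbits unobserved in a network.
Entries involving a column that is constant even with the pseudo row are
reported as missing. Two GCMs are compared entry-wise by Fisher's z-test,
`(atanh r1 - atanh r2)/sqrt(1/(n1-3) + 1/(n2-3))` with `n` the number of
rows used (nodes + pseudo row); the 1.06 variance inflation sometimes used
for Spearman correlations is available as a parameter, and raw p-values at
0.05 are the default with Benjamini–Hochberg optional. Orbits of interest
are those participating in significant entries, ranked by how many; genera
are then ranked within each selected orbit by their orbit count (ties broken
lexicographically for determinism), and the genera in the top k (default 25,
a practical cut) of every selected orbit form the focal set, with
group-exclusive sets by set difference. A genus's occurrence is its mean
count over the selected orbits.

## Permutation comparison

Group differences in any global property (and per-genus centralities) are
tested by randomly reassigning group labels (preserving group sizes) and
re-running the entire per-group pipeline — zero replacement, SparCC,
sparsification, property computation — for each of B permutations (default
1000). Two-sided p-values use the +1 correction,
`p = (1 + #{|d_b| >= |d_obs|})/(B + 1)`. Taxon and sample filters are applied
once to the full dataset before permuting so the genus universe stays fixed
(per-permutation refiltering is a flag); genera isolated in a permuted
network contribute zero centrality. Failed permutations are excluded and
counted, and more than 5% failures aborts the test. Because sparsified edge
counts at small D take few values, count-based properties (edge density)
yield a discrete null with ties, making the test conservative at desk scale
— it never exceeds its nominal level; this is quantified in the acceptance
suite.

## Synthetic data generator

The generator implements a logistic-normal-multinomial model: a basis
correlation matrix with planted structure (modules with within/between edge
probabilities, designated hub genera with extra attachments, edge magnitudes
uniform on a range with a negated fraction) is repaired to positive
definiteness if needed (eigenvalue clipping at 1e-6, re-standardisation to
unit diagonal), and the planted edge set is re-derived from the repaired
matrix above 1e-3 so "truth" always refers to the matrix actually used; the
pre-repair adjacency is kept alongside. Latent per-sample log-abundances are
multivariate normal with that correlation, exponentiated, closed to a
composition, and observed by a multinomial draw at a per-sample read depth
(log-normal around 30,000 truncated below at 10,000 by default, mirroring
the sample-depth filter floor). Genus mean log-abundances default to
N(0, 2^2) draws, giving the orders-of-magnitude unevenness and the zero
fraction typical of gut genera. Defaults are scaled to the target data: 87
genera and case/control sizes of 365 and 522.

What the generator does *not* emulate: overdispersion beyond the
logistic-normal (no zero inflation beyond multinomial sampling), taxonomic
correlation between related genera, batch or covariate structure, and any
true ecological interaction model. Passing recovery tests therefore shows
that the estimators recover the generative model they assume, at realistic
scale and depth — not that SparCC recovers arbitrary real-data structure.

A caveat on planted hubs: a node cannot be strongly correlated with many
mutually independent partners (the implied matrix loses positive
definiteness), so the repair necessarily shrinks hub edge magnitudes. The
planted-hub recovery condition therefore uses moderate magnitudes
(0.3–0.5) over a sparse background, where hubs remain the highest-centrality
nodes after repair.

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use D = 50 genera and n = 500 samples; type-I
calibration of the permutation test uses D = 20, 60 samples per group,
B = 200 permutations and 500 replicates (300 in the acceptance script);
Jaccard-null calibration uses 2,000 replicates at B = 1000 over a universe
of 87 with sets of 25; orbit-count validation uses random graphs up to 15
nodes where exhaustive enumeration is exact and fast. These sizes were
chosen so the whole suite runs on a single CPU in minutes while keeping
Monte-Carlo error well inside the asserted tolerances.
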
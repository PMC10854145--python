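# Methods

This note documents the models and procedures the package implements, the
conventions and numerical choices behind them, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## Networks and centrality features

The global interaction network is the union of one or more edge-list
sources (undirected protein-protein interaction edges, plus optional
directed TF→target edges). Self-loops are dropped and duplicate edges
merged; the node set is exactly the symbols appearing on retained edges.
Gene symbols are case-sensitive opaque strings and are never remapped —
joins across files are by exact string match, because no aliasing scheme is
part of the input contract.

The cohort-specific network keeps an edge when both endpoint genes are
present in the cohort's expression matrix and their profiles satisfy
|Pearson r| > `r_min` (default 0.4) with two-sided p < `p_max` (default
0.05). The p-value uses the exact t transform t = r·sqrt((n−2)/(1−r²)) with
n−2 degrees of freedom; at least 3 samples are required, and a
zero-variance profile fails the filter (r undefined). No multiple-testing
correction is applied to edge filtering.

For each gene set, the subnetwork induced on the cohort network (directed
edges symmetrized first) yields three per-gene centrality features:

* **Degree** — neighbour count.
* **Betweenness** — sum over unordered source–target pairs within the
  gene's connected component, endpoints excluded, of the fraction of
  shortest paths through the gene (the standard undirected convention;
  raw sums, not pair-count-normalized — the subsequent normalization
  removes scale anyway).
* **Eigenvector centrality** — the principal-eigenvector score of the
  component adjacency, computed per connected component by power iteration
  (tolerance 1e-10, at most 1000 iterations) on the shifted matrix A + I;
  the shift leaves eigenvectors unchanged while breaking the magnitude tie
  between the extreme eigenvalues of bipartite components, which would
  otherwise keep plain power iteration from converging. Each component's
  vector is scaled to maximum 1; isolated nodes score 0 in all three
  features.

Within each gene set's subnetwork, each feature is normalized as
x_n = (x − min x)/sd(x) with the n−1 denominator. A constant feature
(sd = 0, including single-node subnetworks) normalizes to all zeros. The
normalization scope is per-subnetwork because the features are defined
within each gene set's network; it makes the weights shift-invariant and
scale-equivariant.

## Burden scoring

WHMB(s, j) = (1/M_size(s)) Σ over genes g in s ∩ mut(j) of w(g), where
w(g) is the sum of the gene's three normalized features if g is in the
cohort-specific network, and 1 otherwise. Mutation profiles are gene-level:
a MAF is reduced to per-sample sets of non-silently mutated genes (the
excluded classifications default to {Silent, Intron, 3'UTR, 5'UTR, 3'Flank,
5'Flank, IGR, RNA} and are configurable). By default each mutated gene
contributes once (binary indicator); `use_counts` multiplies each term by
the gene's retained variant count.

M_size(s) is the number of genes in set s. Dividing by a per-set size is
the only reading under which the normalization does anything: a constant
divisor shared by all sets would cancel in the per-sample z-score.

IWHMB z-scores the WHMB matrix across gene sets within each sample column
(n−1 denominator). A sample whose burdens are constant across sets gets a
zero column with a warning. The z-score makes the result invariant under
any per-sample positive affine transformation of WHMB — this is the formal
mechanism by which a sample's global mutation burden, which multiplies all
its pathway burdens roughly equally, is removed. Samples are dichotomized
per set as high (score > 0) versus low (score ≤ 0).

TMB is the total retained mutation count divided by the covered region in
megabases; the default region of 38 Mb approximates a coding exome and is
configurable. Copy-number burden is the per-sample sum of |gene-level
calls|. The Jaccard index is |A∩B|/(|A|+|B|−|A∩B|), with 0 for two empty
sets.

Summation inside the burden score runs in sorted gene order so the
floating-point result is reproducible and exactly matches a literal
triple-loop evaluation.

## Subtype discovery

Samples (columns of the score matrix) are clustered by:

* **hierarchical** — average linkage (configurable) on Euclidean distance;
* **k-means** — k-means++ initialization, 10 restarts, seed-controlled;
* **consensus** — for each k from 2 to min(max_k, n−1): `reps` (default
  50) subsamples of ⌈p_item·n⌉ samples (default p_item = 0.8) drawn
  without replacement, base clustering per subsample (k-means by default),
  and consensus(i, j) = co-clustered count / co-sampled count. Final
  labels cut an average-linkage tree on 1 − consensus. Pairs that were
  never co-sampled are reported explicitly (their consensus entry is
  undefined and stored as 0, with a warning) rather than silently zeroed.

max_k is capped at n−1; a nominal "no cap" request simply evaluates all
feasible k. The area under the consensus-CDF is reported per k so the
usual delta-area heuristic can be inspected, but k is never auto-selected —
choosing k is the analyst's decision. Cluster ids are renumbered 1..k in
order of first appearance, and each cluster is annotated with its dominant
gene set (highest mean score among the cluster's samples).

## SVR deconvolution and IRG calling

Each gene's row-standardized expression is regressed on the per-sample
score vectors of the (optionally subsetted) gene sets with an
epsilon-insensitive linear-kernel support vector regression (epsilon = 0.1,
C = 1.0 by default; both configurable — the calling thresholds are defined
on the fit statistic, not on the hyperparameters). Score rows with
numerically zero variance are dropped from the predictors. Because the
identity of a curated "informative subset" of gene sets is an analysis
choice, the default is all available sets with an explicit `--sets`
override.

**Fit statistic.** The quality of a gene's fit is the Spearman correlation
between fitted and observed expression, with the fitted values taken
out-of-fold from a deterministic 5-fold split. With tens of predictors and
a few hundred samples, an in-sample statistic is optimistically biased
(≈ +0.23 under independence at 24 predictors and n = 300, measured), which
would make the discovery threshold meaningless; the out-of-fold statistic
is centred at zero for unrelated genes while barely affecting genes with a
real linear response. `in_sample=True` restores the naive statistic;
cohorts with fewer than 10 samples fall back to it. Spearman p-values use
the t approximation; an exact permutation p is available for small n.
Coefficients always come from the full-data fit.

IRG calling: discovery requires fit correlation > 0.2 (strict) and
p < 0.05; a call is **conserved** when an independent validation cohort's
fit reproduces it with correlation > 0.1; genes with a discovery pass but
no validation fit stay at **discovery**. Pathway→gene perturbation links
are the (set, gene) pairs with |regression coefficient| > 0.15 (strict).

**Random control.** The null model permutes each selected expression row's
sample order independently and refits, reporting the mean fit correlation
and mean p. Permutation (rather than sampling "unrelated" genes) isolates
the null without requiring a notion of unrelatedness; it preserves each
gene's marginal distribution while severing any link to the scores.

## Co-expression network and module eigengene

The co-expression network over a gene list keeps pairs with Pearson r >
`r_min` (positive pairs only by default; |r| with `positive_only=False`)
and p < `p_max`; nodes are the genes with at least one retained pair. The
module eigengene is the leading right singular vector of the
row-standardized module submatrix (unit norm), sign-fixed so it correlates
non-negatively with the mean module expression; the explained-variance
fraction is reported alongside.

## Random walk with restart and bridge hub genes

The walk iterates p ← (1−r)·W p + r·p0 with W column-normalized over the
integrated network: undirected edges contribute transitions both ways,
directed TF→target edges one way, and dangling nodes return their mass to
p0. p0 distributes the (optionally weighted) seed mass over in-network
seeds; seeds absent from the network are dropped with a warning as long as
one remains. Iteration stops when the L1 change falls below 1e-10 (at most
1000 iterations; non-convergence is an error carrying the residual). The
restart probability defaults to 0.7, a common network-propagation choice,
and is configurable. With restart = 1 the scores are exactly p0.

Top-k extraction (k = 500 by default) breaks score ties lexicographically
so the cut is reproducible. Bridge hub genes are the intersection of the
two top-k lists obtained by seeding from a progression-related module and
from its related immune genes, ordered by the worse of a gene's two ranks.
Enrichment of gene lists is tested with the upper-tail hypergeometric
distribution and with an upper-tailed 2×2 chi-square (no continuity
correction; a zero margin is an error).

Community detection over co-expression networks is a pluggable interface:
greedy modularity maximization by default, Louvain with a seed as an
alternative; communities are numbered by decreasing size with
smallest-member tie-breaks so labels are deterministic.

## Synthetic cohorts

The generator produces everything the pipeline consumes, plus ground truth:

* **Network** — a scale-free (preferential-attachment, m = 3) graph over
  the gene universe (default 2,000 genes), plus 200 random directed
  TF→target edges.
* **Gene sets** — default 24 sets of 30–60 genes grown as random connected
  neighborhoods of the network (snowball sampling) with a per-set budget
  of 10% previously-used genes. Uniformly random sets would induce nearly
  edgeless subnetworks on a sparse graph (collapsing every centrality to
  zero), a degeneracy curated pathways do not exhibit; neighborhood growth
  with an overlap budget keeps subnetworks connected and overlaps
  controlled.
* **Mutations** — each sample draws a global rate multiplier
  exp(N(0, 0.6)) on a background per-gene rate of 0.02 (≈ 40 background
  mutations per sample), creating the TMB confound the z-scoring must
  remove; genes in the sample's subtype-enriched sets (4 subtypes × 6 sets
  by default) mutate at 8× that rate. Mutation status is per-gene
  Bernoulli — no positional model, since the pipeline consumes gene-level
  status only.
* **Scores** — WHMB/IWHMB are computed by the package itself on the global
  synthetic network (the cohort-specific filter needs the expression
  matrix, which is generated *from* the scores, so the generator uses the
  unfiltered network).
* **Expression** — 200 planted responder genes get
  Σ β·IWHMB(set) + N(0, 0.5) with 1–3 target sets each and |β| ∈
  [0.3, 0.9] (random sign); a 50-gene progression module shares a latent
  factor (loadings 0.7–1.3, noise sd 0.3); everything else is N(0, 1).
  Expression responds to IWHMB directly rather than to a hidden pathway
  activity, so SVR recovery is an exact parameter-recovery problem.
* **Bridges** — 30 bridge genes get 3 extra edges each into the
  progression module and 3 into a 40-gene designated immune list.
* **Copy number** — i.i.d. gene-level calls (−1/0/1 with probabilities
  0.1/0.8/0.1).

Everything is reproducible from the seed, and the written cohort includes
a `truth.json` with the planted labels, coefficients and gene lists.

What the generator does **not** emulate: co-expression along interaction
edges (non-responder expression is independent noise, so the default
cohort-specific correlation filter empties a synthetic network — disable it
with `--r-min -1 --p-max 1.1` when scoring synthetic cohorts through the
CLI); linked mutations, positional effects or mutational signatures;
library-size or batch structure in expression; correlated copy-number
segments. Passing tests therefore demonstrate the pipeline's correctness
and its recovery of the planted statistical structure, not robustness to
real-data artifacts such as aliasing, batch effects or calling errors.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: exhaustive oracle comparison
on all labeled connected graphs with ≤ 6 nodes; 50 random toy cohorts for
the burden triple-loop oracle; 100 random graphs of ≤ 50 nodes for the
walk-vs-dense-solve oracle; a 300-sample / 2,000-gene cohort for score
properties, IRG recovery (precision and recall against 200 planted
responders) and bridge-gene enrichment; and a 200-sample cohort for
subtype recovery (adjusted Rand index vs planting) and eigengene recovery.

Conventions used throughout: standard deviations use the n−1 denominator;
degenerate denominators (sd = 0) map results to 0 with a warning rather
than NaN; comparisons at thresholds are strict (> not ≥); score ties in
rankings break lexicographically; all stochastic steps take explicit
seeds. Matrix round-trips through TSV are lossless to 10 significant
digits.

## Known limitations

* The out-of-network gene weight of 1 is not on an obviously comparable
  scale to a sum of normalized centralities; the score follows the stated
  definition literally.
* Whether a cohort's "informative" gene set subset should be curated before
  the SVR stage is left to the analyst (`--sets`).
* Community detection is a stand-in interface (modularity/Louvain); graph
  autoencoder-style community detection is out of scope.
* Edge weights (e.g. interaction confidence scores) are not used by the
  centrality or propagation computations; pre-filter edge lists by weight
  upstream if needed.
* Survival analysis, differential expression, immune deconvolution and
  single-cell analyses are intentionally outside the package's scope.
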
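# iwhmb

Network-weighted, per-sample-standardized pathway mutation burden scoring,
with the downstream analysis pipeline that the score feeds: mutation-subtype
discovery, deconvolution of scores into transcriptomic features, co-expression
module summarization, and network propagation to prioritize bridge hub genes.

## Who this is for

Cancer genomics analysts who have per-sample somatic mutation calls (MAF), a
gene set collection (GMT, e.g. the 50 MSigDB hallmark sets), a protein-protein
interaction network (edge lists in the style of STRING/BIOGRID/KEGG exports)
and an expression matrix, and who want pathway-level mutation scores that are
comparable **between pathways within a patient** rather than dominated by the
patient's global tumor mutational burden (TMB).

## The score

For a gene set *s* with *M*<sub>size</sub>(*s*) genes and a sample *j* with
mutated gene set mut(*j*), the weighted burden is

    WHMB(s, j) = (1 / M_size(s)) * Σ_{g ∈ s ∩ mut(j)} w(g)

where the weight of an in-network gene is the sum of its three normalized
network centrality features — degree, betweenness and eigenvector
centrality — computed inside the subnetwork induced by *s* on a
cohort-specific interaction network (edges kept when |Pearson r| > 0.4 and
p < 0.05 between the endpoints' expression profiles), each feature
normalized within the subnetwork as

    x_n = (x - min x) / sd(x)

and the weight of a gene outside the network is 1. The individualized score
z-scores the burden across gene sets within each sample:

    IWHMB(s, j) = (WHMB(s, j) - mean_s WHMB(·, j)) / sd_s WHMB(·, j)

Because the z-score is invariant to any positive affine rescaling of a
sample's burdens, a sample's global TMB — which scales all of its pathway
burdens together — cancels out. IWHMB > 0 is read as the pathway's mutation
status being "activated" in that patient.

Downstream, the package clusters the IWHMB matrix into pathway-mutation
subtypes (hierarchical, k-means, and a from-scratch consensus clustering),
regresses each gene's z-scored expression on the IWHMB vector with a
linear-kernel support vector regression to call IWHMB-related genes (IRGs:
fit correlation > 0.2, p < 0.05; |coefficient| > 0.15 marks a perturbing
pathway), builds the positive co-expression network over the called genes,
summarizes gene modules by their eigengene (first principal component), and
intersects top-500 random-walk-with-restart rankings seeded from a
progression module and from its related immune genes to define bridge hub
genes (BHGs).

No external cohort is required: `iwhmb simulate` generates fully synthetic
cohorts with planted subtypes, planted IWHMB→expression responses, a planted
co-expression module and planted bridge genes, so every stage can be
exercised and validated against known ground truth.

## Worked example

Generate a small synthetic cohort (60 samples, 300 genes, 8 gene sets, two
planted subtypes), score it, and cluster it:

```sh
iwhmb simulate --config gen.yaml --seed 7 --out cohort
iwhmb score --maf cohort/cohort.maf --gmt cohort/sets.gmt \
    --edges cohort/ppi_edges.tsv --expr cohort/expression.tsv \
    --r-min -1 --p-max 1.1 --out iwhmb.tsv
iwhmb subtype --iwhmb iwhmb.tsv --method consensus --k 2 --seed 7 \
    --out subtypes.tsv
```

(`--r-min -1 --p-max 1.1` disables the co-expression edge filter: synthetic
expression carries no co-expression along interaction edges, so the default
filter would empty the network — see `docs/methods.md`.)

The score matrix has gene sets in rows and samples in columns; each column
has mean 0 and sd 1:

```
set      S0000  S0001  S0002  S0003
SET_00  -0.614 -0.602 -0.354  1.769
SET_01   0.433 -0.602 -0.354  0.038
SET_02  -0.614 -0.602 -0.354  1.363
SET_03  -0.614  1.621 -0.354 -0.634
```

S0003's mutations concentrate in SET_00/SET_02 (scores ≈ 1.8 and 1.4: those
pathways are activated relative to the rest of its own profile), while S0001
is dominated by SET_03. Cross-tabulating the consensus clusters against the
planted subtypes from `cohort/truth.json`:

```
subtype    1   2
cluster
1          3  32
2         23   2
```

55 of 60 samples land with their planted subtype (adjusted Rand index 0.689
at this small size; ≥ 0.94 at the standard 200-sample setting used by the
test suite). Every output file starts with `#` provenance lines (package
version, seed, config hash); reruns with an identical configuration are
byte-identical. `iwhmb irg`, `iwhmb bhg` and `iwhmb run-all` drive the
remaining stages; `iwhmb run-all --config run.yaml --out dir` executes
score → subtype → irg → co-expression → eigengene → bhg in one call.

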
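# dcim — differential co-expression infinite mixture

`dcim` is an unsupervised Bayesian nonparametric framework for gene
expression data (bulk or single-cell summaries) that groups **samples by
the way their genes co-cluster rather than by expression-level
similarity**.  It is aimed at analysts looking for *contexts* — disease
subtypes, tissue states, treatment regimes — whose signature is a
rewiring of co-expression structure, and for the genes whose co-expression
partners change between such contexts.

## Model

Let **X** be an *N* × *M* expression matrix (genes × samples).  Three
coupled allocation structures are inferred jointly:

* **C** (length *N*): genes → *global clusters*; genes in cluster *q* share
  an *M*-dimensional Gaussian expression pattern.
* **D** (length *M*): samples → *contexts*; samples in a context share the
  same local gene co-clustering.
* **L** (*Q* × *R*): within each context *r*, global clusters whose
  patterns are indistinguishable there are merged into *local clusters*
  (`l_qr = t`).

All three levels carry Dirichlet-process (Chinese-restaurant) priors with
concentrations α, β, φ, so no cluster or context counts are fixed in
advance.  Pattern means and variances receive conjugate
Normal–Inverse-Gamma priors, one independent dimension per (context, local
cluster, sample), and are integrated out: the collapsed Gibbs sampler only
ever evaluates closed-form marginals and Student-t predictives.  Posterior
summaries are **posterior pairwise probabilities** (PPPs): the fraction of
retained sweeps in which two genes (or two samples) were co-grouped.
Average-linkage trees built on the distance 1 − PPP give dendrograms whose
cut at height 1 − *p* yields clusters with average internal PPP above *p*.

The **differential co-expression score** of gene *i* between two contexts
is

    DCS(i) = max over clusters g (from all cut levels of both context
             trees, i in g) of  sum_{j in g, j != i} |PPP_c1 − PPP_c2|_ij / (|g| − 1)

a value in [0, 1] that is large when some tight cluster of co-expression
partners of *i* changes almost completely between the contexts.

## Worked example

Simulate the planted-structure benchmark (4 gene clusters of sizes
20/20/80/80, 3 contexts of 5 samples, σ = 0.5), fit the model, and score
differential co-expression:

```sh
dcim simulate --scenario A --sigma 0.5 --seed 1 --out-dir sim/
dcim fit sim/expression.tsv --out-dir fit/ --seed 2 --burnin 300 --keep 700
dcim dcs sim/expression.tsv --contexts fit/contexts.tsv \
    --out-dir dcs/ --seed 3 --burnin 300 --keep 700
head -4 dcs/dcs.tsv
```

```
gene_id	score	context	cluster_size	rank
g001	0.775134	1	102	31
g002	0.771372	1	102	34
g003	0.776139	1	102	22
```

Genes `g001`–`g040` are the planted context-informative genes (their
co-clustering partners change between contexts); they receive DCS scores
around 0.78 and fill the top of the ranking (36 of the top 40 in this
run), while the 160 background genes average about 0.35.  `fit/contexts.tsv` holds the discovered sample contexts
(the k = 2 cut of the sample tree; `--k` changes the cut), and the
`manifest.json` in each output directory records the seed, configuration
and file checksums needed to replay the run exactly.

The same pipeline is available as a library (`dcim.run_chain`,
`dcim.dcs_genes`, ...), and `dcim benchmark` reproduces the
context-recovery comparison against Euclidean / Pearson average-linkage
clustering:

```sh
dcim benchmark --scenario D --sigma 0.5 --reps 10 --seed 1 --out bench.tsv
```

In scenario D expression levels are sign-flipped in selected samples while
co-clustering structure is preserved; traditional distance-based
clustering drops to AUC ≈ 0.54 there while the model stays at ≈ 1.0.

## Preprocessing

For real expression matrices, `dcim preprocess` median-centers each gene
and applies the COPA (Cancer Outlier Profile Analysis) variation filter:
genes are scored by the 95th percentile of their median-centered,
MAD-scaled values and the top *k* retained (`--top-k`).
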
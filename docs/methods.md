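# Methods

## Model

The observed data are an *N* × *M* matrix **X** of real-valued expression
measurements, genes in rows.  The generative structure has three levels of
allocation:

1. **Global gene clusters.**  `C[i] = q` assigns gene *i* to cluster *q*;
   each cluster carries an *M*-dimensional Gaussian expression pattern.
   The prior over the partition of genes is a Dirichlet process
   (Chinese-restaurant process) with concentration α.
2. **Contexts.**  `D[j] = r` assigns sample *j* to context *r* under a CRP
   with concentration β.  A context is *not* a group of similar columns:
   it is a group of samples within which the genes co-cluster the same
   way.
3. **Local clusters.**  Within context *r*, global clusters whose patterns
   cannot be distinguished there are merged: `L[q, r] = t` under a CRP
   with concentration φ over the global clusters.  The same CRP
   functional form (group probability ∝ occupancy, new group ∝
   concentration) is used at all three levels; at the local level the
   "items" are global clusters, not genes.

**Likelihood.**  Covariances are diagonal: each (context *r*, local
cluster *t*, sample *j* with `D[j] = r`) triple owns an independent mean
and variance with a Normal–Inverse-Gamma prior
`sigma² ~ InvGamma(a, tau)`, `mu | sigma² ~ N(m0_j, sigma²/lambda)`.
Conditional on `(C, D, L)` the likelihood therefore factorises over sample
columns and local clusters, and the pattern parameters integrate out in
closed form.  The marginal of a block of values with sufficient statistics
`(n, s1, s2)` is

    log m = -(n/2) log 2π + ½(log λ − log λ_n) + log Γ(a_n) − log Γ(a)
            + a log τ − a_n log τ_n

with `λ_n = λ + n`, `m_n = (λ m0 + s1)/λ_n`, `a_n = a + n/2`,
`τ_n = τ + (s2 + λ m0² − λ_n m_n²)/2`; the posterior predictive is
Student-t with `2 a_n` degrees of freedom, location `m_n` and squared
scale `τ_n (λ_n + 1)/(a_n λ_n)`.

Consequences worth knowing:

* Because dimensions are per sample, moving a sample between contexts
  requires no statistic updates for any other sample.
* The global partition `C` is only *weakly* identified where contexts are
  few: two global clusters merged into one local cluster in every context
  reproduce the merged likelihood exactly, so the posterior over `C`
  leans on the CRP priors there.  Local co-grouping (`L[C[i], r] ==
  L[C[i'], r]`) is the sharply identified quantity, and it is what the
  differential co-expression score consumes.

**Default hyperparameters** (all configurable): `m0` = per-sample column
means, `λ = 1`, `a = 2`, `τ` = overall data variance (empirical Bayes,
weakly informative and scale-matched); `α = β = φ = 1`.  Optional
resampling of (α, β, φ) uses the standard auxiliary-variable scheme under
Gamma(1, 1) hyperpriors (Escobar–West for single partitions, the
multi-restaurant variant for φ); it is off by default.

## Inference

A collapsed Gibbs sampler sweeps gene allocations, then local
allocations, then context allocations (a fixed order, for
reproducibility):

* **Gene move.**  Gene *i* is removed (labels compacted if its cluster
  empties) and reassigned with probability ∝ CRP(α) weight × the product
  over samples of the Student-t predictive under the local cluster
  `L[q, D[j]]`.  The "new cluster" option marginalises the new cluster's
  local seat in every context — a CRP(φ)-weighted sum over existing local
  clusters plus a new one — and, if chosen, the seats are then drawn from
  those exact conditionals.
* **Local move.**  For each occupied (q, r), the block of cluster-q genes
  is removed and reseated by CRP(φ) weight × the marginal-likelihood
  increment of adding the block to each candidate local cluster, per
  sample in the context.
* **Context move.**  Sample *j* is removed (its context deleted if
  emptied) and reseated by CRP(β) weight × the marginal of its column
  under each context's local clustering.  Opening a new context is
  handled with the auxiliary-variable scheme for non-conjugate
  components: a small number (default 4) of candidate contexts with local
  clusterings drawn from the CRP(φ) prior are instantiated, each carrying
  β/m prior mass.  This keeps the chain's stationary distribution exactly
  the posterior — a deterministic "identity local clustering" proposal
  was rejected because it is not a valid Gibbs move and measurably biases
  the sampler.  Correctness is verified against exhaustive enumeration of
  all (C, D, L) configurations on small instances (max PPP error < 0.01
  at 8000 kept sweeps).

All arithmetic is in log space with log-sum-exp normalisation.  Two
engines implement the gene sweep: a compiled numba kernel (default) using
inverse-CDF categorical draws from a pre-drawn uniform buffer, and a
vectorised numpy reference using Gumbel-max draws.  Both consume a single
seeded generator, so every chain is bit-reproducible from its seed; the
engines are cross-checked statistically in the test suite.

Chain defaults are 500 burn-in and 2000 kept sweeps (thinning optional);
the simulation benchmark uses shortened chains (300 + 700), which the
planted-structure experiments show is ample at *N* = 200, *M* = 15.

## Summaries and the DCS

Posterior pairwise probabilities (PPPs) — the fraction of kept sweeps in
which two items were co-grouped — summarise the partition posteriors
while sidestepping label switching.  Trees are unweighted average linkage
(UPGMA, via scipy) on the distance 1 − PPP; cutting just below each
distinct merge height gives one partition per achievable cluster count,
and cutting at height 1 − *p* yields clusters whose mean internal PPP
exceeds *p*.  Contexts are the k-cluster cut of the sample tree (default
k = 2, configurable).

For two contexts, local PPP matrices come from a second chain with the
context allocation pinned (`fixed_contexts`), accumulating local
co-grouping per context; this bounds memory at 2 N² counters and avoids
matching context labels across sweeps.  The DCS of gene *i* is the
maximum, over all cut-level clusters *g* of both context trees containing
*i*, of the mean absolute local-PPP difference between *i* and its
co-members.  Singleton clusters score 0 (the formula divides by
|g| − 1), so the enumeration can stay total over all cuts.  Scores are in
[0, 1] and are identically 0 when the two local PPP matrices coincide.

`overlap_significance` assesses gene-list overlaps with a hypergeometric
upper tail and a log odds ratio (Haldane 0.5 correction for empty cells).

## Synthetic benchmark

The generator plants the structure the model is designed to detect:
*N* = 200 genes in four clusters (20, 20, 80, 80), *M* = 15 samples in
three contexts of five.  Cluster 3 has mean 0 and cluster 4 mean 1 in
every sample; cluster 1 is high (1) only in samples 1–5 and cluster 2
only in samples 6–10, so only the 40 genes of clusters 1–2 are
context-informative.  Noise is i.i.d. Gaussian with σ ∈ [0.4, 0.8]
(σ = 0.5 for benchmarking).  Scenario A uses these means directly;
scenario D flips every mean of 1 to −1 in samples 1–2, 6–8, 11–12,
preserving co-clustering structure while scrambling expression levels —
the regime in which expression-distance clustering of samples fails by
construction.

Context recovery is scored as an ROC over the cut levels k = 1..M of a
sample tree: a co-clustered pair of samples is a true positive if it
shares a planted context, a false positive otherwise; AUC is trapezoidal
with (0,0) and (1,1) appended, and replicate curves are averaged by
aligning on the cluster count k.  Baselines are average-linkage trees on
Euclidean and 1 − Pearson distances between sample columns (average
linkage for consistency with the model's trees).  Replicates are seeded
as `(seed, rep)` pairs through numpy's SeedSequence, so the benchmark is
reproducible and parallelisable.

What the generator does *not* emulate: heavy-tailed noise, gene–gene
correlation within clusters beyond the shared mean, batch effects,
missing values, and realistic library-size or probe-level artefacts.
Passing the benchmark shows the inference machinery recovers planted
co-clustering structure at realistic noise; it does not certify
performance on real microarray or sequencing data, where the COPA filter
and median centering (see below) and careful hyperparameter choices
matter.

## Preprocessing

`median_center` subtracts each gene's median (per-gene mode, the default,
because the model compares patterns across samples within genes) or the
global median (per-dataset mode).  COPA scores each gene by the qth
percentile (default 95) of its median-centered values scaled by
MAD × 1.4826 (the normal-consistency constant); genes with zero MAD score
0 with a warning.  `filter_top_genes` keeps the k best scores, preserving
input order and breaking ties in favour of earlier rows.

## Numerical choices and edge cases

* `τ_n` is clamped at 1e-300 before logs (degenerate one-point blocks).
* Merge heights are clipped to [0, 1] and made monotone before tree
  construction (all-ones PPP blocks can produce −1e-17 distances).
* Tied merge heights are cut together; duplicate partitions are removed.
* Labels at every level are kept contiguous (0-based, first-occurrence
  order) after any move that empties a group.
* A new context's local clustering, once accepted, is immediately
  resampled in subsequent sweeps; the auxiliary candidates are discarded.
* The `gammaln` values needed by the compiled kernel are precomputed in a
  table indexed by block size, since `a` is fixed within a chain.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the benchmark at 10
replicates per scenario with the shortened (300 + 700) chains, the
exhaustive-enumeration check on a 4-gene × 3-sample instance with 8000
kept sweeps, and CRP prior recovery at N = 40, M = 12 with 4000 kept
sweeps.  These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full run on a single CPU around ten
minutes.

## Known limitations

* Diagonal covariance: correlated noise within a cluster is attributed to
  pattern differences; full covariances are out of scope.
* Two-context DCS only; multi-way differential co-expression would need a
  different score.
* No split–merge moves: at much larger N the single-site gene sweep mixes
  slowly; the planted benchmark does not exercise that regime.
* The sample-context posterior is exchangeable over label order; reported
  context labels follow first occurrence in sample order.
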
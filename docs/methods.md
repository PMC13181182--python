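# Methods

## Model and segmentation procedure

Counts are modelled per CpG site *i* and sample *j* as
`X_ij ~ Binomial(t_ij + c_ij, p_ij)`. All likelihoods use the binomial
kernel only — the combinatorial coefficient is constant across the models
being compared and cancels in every likelihood ratio, so it is never
computed. Two conventions make the kernel total: `0·log 0 := 0`, and
site/sample cells with zero coverage contribute exactly 0 to every
likelihood (an empty pool has an undefined rate, reported as `nan` in rate
outputs, but its likelihood contribution is an empty sum).

Segmentation is adjacency-constrained agglomerative clustering per
chromosome: starting from singleton CpGs, the adjacent pair with the
smallest dissimilarity `d(A,B) = nLLR(A,B) + log(π(1 + (δ/scale)²))` is
merged until one cluster remains. The penalty term is the negative log
density of a standard Cauchy (Student t, 1 df) at `δ/scale`; `δ` is the
minimum coordinate difference between the two clusters, which for adjacent
contiguous clusters is the gap between the facing boundary CpGs. Merging
only adjacent clusters guarantees that every cluster is a contiguous
genomic interval — a requirement for reporting segments with coordinates
and lengths — and gives `O(m log m)` runtime with a binary heap. The heap
uses lazy invalidation: stale entries (referring to clusters that no longer
exist or are no longer adjacent) are discarded on pop. This is contractually
indistinguishable from re-evaluating every adjacent pair at each step, and a
quadratic from-scratch oracle test enforces exactly that. Equal-cost
candidates are merged leftmost-first for determinism.

Cross-chromosome dissimilarity is infinite, so chromosomes are processed
independently and concatenated.

## Resolution selection

The merge tree can be cut at any `k`; the default is the `k` minimizing

```
BIC(k) = −2 Σ_segments log L̂_S + (k·n)·log N_obs
```

per chromosome, where `n` is the sample count (one free rate per segment
per sample) and `N_obs` is the number of site/sample cells with non-zero
coverage on the chromosome (`nobs_mode="cells"`; total read count available
as `"reads"`). Each merge lowers the total log-likelihood by exactly its
nLLR, so the entire BIC path costs one pass over the merge list. Ties are
broken toward smaller `k`. With a single sample the penalty is mild and
modest over-segmentation around strong changepoints can occur; with several
samples the penalty is effectively multiplied by `n` and selection is much
crisper.

## Coherence test

For a segment with `r` CpGs, the common model M0 (one pooled rate per
sample) is tested against the separate model M1 (one rate per site per
sample) with `Λ = 2(log L̂_M1 − log L̂_M0)`, referred to χ² with `r − 1`
degrees of freedom by default. Note that with `n` samples M1 actually has
`n·(r − 1)` more parameters than M0; under the default convention the
statistic of a truly homogeneous multi-sample segment is of order
`n·(r − 1)` but compared against χ²(r − 1), so for `n` well above 1 almost
no multi-CpG segment is flagged coherent — consistent with coherent
segments being a small minority in large cohorts, but arguably
miscalibrated. The standard nesting count is available as
`df_mode="per_sample"` (`df = n_eff·(r − 1)`, with `n_eff` the samples
having any coverage in the segment); the package's own synthetic
entropy-direction check uses it so that a non-empty coherent set exists at
`n = 5`. Single-site segments get statistic 0, `p = 1`, coherent. The flag
uses a raw `p > α` rule (default `α = 0.05`) with no multiple-testing
correction, by design.

## Synthetic data generator

The generator emulates the features the segmentation model cares about:

- block structure: `n_segments` segments over `n_sites` CpGs, boundaries
  uniform over site indices subject to a minimum segment size
  (default 20 CpGs);
- bimodal methylation: per-segment per-sample rates from Beta(0.3, 0.3),
  optionally rejection-sampled so adjacent segments differ by at least
  `min_neighbor_rate_diff` in every sample;
- CpG spacing: inter-site gaps `1 + Geometric(mean 99)` bp (mean 100,
  minimum 2);
- sequencing: per-cell depth Poisson(`depth_mean`, default 30), methylated
  counts binomial.

The desk-scale default profile is 2000 CpGs, 10 segments, 5 samples,
depth 30 — small enough for minutes-scale test runs.

Noise at amplitude η% replaces each cell's generative rate by
`clip((1 − w)·p_true + w·ε, 0, 1)` with `w = η/100`, `ε ~ Uniform(0, 1)`
iid per cell, and re-draws the methylated counts at unchanged depth. At
η = 100 the rates are pure noise; above 100 the negative signal weight plus
clipping drives rates toward the extremes of the noise. Replicate seeds are
derived deterministically from a master seed and the (η, replicate) pair
via `numpy` `SeedSequence`, so collections are byte-reproducible.

What the generator does *not* emulate: CpG-island positional structure,
strand effects, bisulfite conversion error, coverage biases, and
overdispersion (beta-binomial variation) of real WGBS data. A green
recovery test therefore establishes correctness of the machinery on data
that satisfy the model's assumptions, not field performance on real
methylomes.

## Evaluation conventions

Breakpoints are identified with inter-CpG boundaries (boundary `b` splits
sites `b−1` and `b`). Matching is one-to-one and exact by default
(`tolerance_bp = 0`); with a positive tolerance, boundaries pair greedily
by gap-midpoint distance. Specificity needs a negative class: the candidate
universe is all inter-CpG boundaries within chromosomes, i.e. every
possible split point. Bootstrap CIs are percentile intervals over
re-sampled replicate means (default 1000 resamples, 95%).

Enrichment treats each segment as one trial in a 2×2 table (coherent ×
overlapping, overlap = shared span ≥ 1 bp by default). The two-sided Fisher
p-value is the sum of hypergeometric probabilities of tables no more likely
than the observed one (with a `1 + 1e-7` relative slack against ties lost
to floating-point rounding, matching common practice); the reported odds
ratio is the sample OR with a Haldane 0.5 correction when a cell is zero.
BH correction runs across annotation classes. β-value entropy is base-2
Shannon entropy over 20 equal-width bins on [0, 1].

## Numerical choices

- nLLR values and LRT statistics are non-negative by MLE optimality; tiny
  negative floating-point residues are clamped to 0.
- Zero-coverage pools get a dummy rate of 0.5 inside likelihood kernels
  (their counts are zero, so the contribution is exactly 0 regardless of
  the dummy; `scipy.special.xlogy` does not short-circuit `0·log(nan)`).
- Sites with zero coverage in all samples are retained and merge at pure
  distance-penalty cost; the reader's `min_coverage` option can drop them.
- The `δ/100` divisor of the distance penalty is exposed as `scale`
  (default 100 bp) for sensitivity analysis.
- Coordinates are 1-based positions of the CpG cytosine internally; BED
  output is 0-based half-open, the summary TSV 1-based inclusive (stated in
  its header). Bismark coverage input is treated as 1-based, the bedGraph
  dialect as 0-based.

## Known limitations

- Greedy agglomeration does not guarantee the globally optimal partition at
  a given `k`; this is intrinsic to the hierarchical approach (which in
  exchange yields all resolutions at once).
- The binomial model ignores overdispersion between reads and biological
  replicates; segments in noisy real data will be shorter than the
  underlying biology.
- Chromosome ordering is lexicographic (`chr10` before `chr2`), which
  affects output order only.
- The fixed-`k` resolution clips `k` to the number of sites on short
  chromosomes rather than erroring.
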
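# methblocks

Data-driven, multi-sample segmentation of whole-genome bisulfite sequencing
(WGBS) methylation data into spatially homogeneous CpG blocks.

DNA methylation at neighbouring CpG sites is strongly correlated and acts in
blocks, but most segmentation tools impose fixed windows rather than letting
the observed methylation pattern define the blocks. `methblocks` derives
segments directly from the joint count data of a sample cohort: blocks are
shared across samples, while each sample keeps its own methylation level in
every block. The output is a cohort-level partition of the genome usable for
segment-level differential methylation testing, variability or entropy
analyses, and annotation enrichment.

## Model

Methylated read counts at CpG site *i* in sample *j* follow
`X_ij ~ Binomial(t_ij + c_ij, p_ij)` with methylated/unmethylated counts
`c`/`t`. For a site set *S* the per-sample pooled MLE is
`p̂_S,j = Σ_S c_ij / Σ_S (t_ij + c_ij)`, and the log-likelihood at the MLE is

```
log L̂_S = Σ_{i∈S} Σ_j [ c_ij log p̂_S,j + t_ij log(1 − p̂_S,j) ].
```

Adjacent site sets A, B are merged agglomeratively using the dissimilarity

```
d(A,B) = nLLR(A,B) − log T(δ(A,B)/100; 1),   nLLR = −log L̂_{A∪B} + log L̂_A + log L̂_B,
```

where `T(x; 1)` is the Student-t (Cauchy) density and `δ` the shortest
genomic distance between the sets — a heavy-tailed penalty that favours
merging nearby CpGs. Each chromosome is agglomerated independently into a
full merge tree; any resolution can be cut out, and the default cut
minimizes a Schwarz BIC (`−2 log L̂ + k·n·log N_obs`, one free rate per
segment per sample). Each segment is then tested for *coherence* — a
likelihood-ratio test of one common rate per sample across all its CpGs
against free per-site rates, referred to χ² — and flagged coherent when
`p > 0.05`.

A synthetic-data module generates piecewise-constant ground-truth cohorts
with binomial read sampling and graded uniform-mixture noise, and the
evaluation module scores breakpoint recovery (preserved / lost / gained,
sensitivity / specificity / precision / F1 with bootstrap CIs), annotation
enrichment (Fisher exact + Benjamini–Hochberg), and β-value entropy.

## Worked example

```python
import methblocks as mb

# 2000 CpGs, 10 true segments, 5 samples, mean depth 30
data, truth = mb.simulate_baseline(seed=1, min_neighbor_rate_diff=0.3)
seg = mb.segment_genome(data, resolution="bic")
mb.annotate_segmentation(seg, data, df_mode="per_sample")

cmp = mb.compare_breakpoints(truth.breakpoints["chr1"],
                             seg.breakpoints(data)["chr1"], data.positions)
print(seg.k_per_chrom, cmp)
```

prints

```
{'chr1': 10} BreakpointComparison(preserved=9, lost=0, gained=0, candidate_negatives=1990)
```

i.e. the BIC cut selects exactly the 10 true segments and recovers all 9
internal boundaries with no spurious ones. Raising the noise amplitude
degrades precision long before sensitivity (`mb.build_collection` +
`mb.run_noise_experiment` reproduce the full curve):

```
eta=   20%  sensitivity=1.000  precision=1.000  gained_prop=0.000
eta=   60%  sensitivity=0.778  precision=0.041  gained_prop=0.948
eta=  100%  sensitivity=0.644  precision=0.004  gained_prop=0.994
```

From the shell, the same pipeline is available as `methblocks segment`
(Bismark coverage / bedGraph inputs → BED + summary TSV + segment-by-sample
matrix), `methblocks simulate`, `methblocks evaluate` and
`methblocks enrich`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch at desk scale — baseline simulation,
BIC segmentation, breakpoint recovery, a three-amplitude noise sweep,
coherence/entropy summaries and a synthetic enrichment analysis — printing
the measured numbers and writing the results JSON.

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions and known limitations.
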
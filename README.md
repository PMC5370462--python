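# dmrscan

Sliding-window differential methylation analysis for whole-genome
bisulfite sequencing (WGBS) count data, built for small replicate
cohorts — the design used in mouse liver aging studies, where four
animals per condition (young/old, wild-type/long-lived dwarf,
calorie-restricted or rapamycin-treated) are compared at every CpG dyad
in the genome.  A companion simulator generates full synthetic
methylomes with planted, machine-readable ground truth, so every claim
the caller makes can be scored.

## Who this is for

Epigenomics analysts who have Bismark-style cytosine reports (per-CpG
methylated/unmethylated read counts) for replicate cohorts and want:

* differentially methylated CpGs and regions (DMRs) between two cohorts,
* hyper/hypo direction classification and DMR set algebra across
  comparisons (shared/unique DMRs, intervention "suppression" of
  age-associated changes),
* permutation-based enrichment of DMRs against annotation tracks
  (enhancers, CpG islands, histone peaks, …),
* region/global methylation summaries, PCA, heatmap matrices, and
  kernel-smoothed or composite (metaregion) profiles.

## The statistics at the core

Counts from the two strands of a CpG are first collapsed onto the dyad:
`(m, u) = (m⁺ + m⁻, u⁺ + u⁻)`, anchored at the plus-strand C.

**Per-CpG calls.**  For each dyad with pooled coverage ≥ 10 reads in
both cohorts, a two-tailed Fisher exact test is applied to the 2×2 table
(cohort × methylated/unmethylated) of replicate-pooled counts, using the
minimum-likelihood two-tail: p = Σ P(T) over all tables T with the
observed margins and P(T) ≤ P(observed).  Benjamini–Hochberg FDR is
applied across all tested dyads; q < 0.05 is reported.

**Region calls.**  Each chromosome is tiled with 500-bp windows
advancing by 250 bp.  A window with ≥ 5 covered dyads per cohort is
tested twice: the pooled-count Fisher test above, and a Pearson
chi-squared test of heterogeneity on the replicates × (meth, unmeth)
table within each cohort (df = R−1).  Both families are BH-FDR-corrected
over the tested-window universe; a window survives only with
FET q < 0.05 **and** heterogeneity q ≥ 0.05 in both cohorts — replicate-
inconsistent windows are discarded no matter how strong the pooled
signal.  Overlapping surviving windows of the same direction merge into
one region.  Direction is hyper/hypo as the second cohort is more/less
methylated; an aging DMR is *suppressed* by an intervention when it
overlaps a treated-vs-old DMR of the opposite direction.

**Enrichment.**  Observed overlap of a region set with a feature set
(count of overlapping regions, or base pairs) is compared with the mean
over placements of equally sized intervals dropped uniformly on the
genome; fold = observed/expected and significance is the empirical
p-value (r+1)/(n+1) over n permutations.

## Worked example

Simulate a two-cohort study (young vs old wild-type; 10-Mb genome,
~127,000 CpG dyads, 4 replicates each, Poisson(7) coverage, planted age
effects at enhancers and bivalent CpG islands), then call DMRs:

```sh
dmrscan simulate --seed 4 --out fix --cohorts WTY,WTO
dmrscan summarize fix
dmrscan call-dmrs fix WTY WTO --out-dir dmrs
```

which prints (abridged):

```
cohort   sample  global_pct  n_dyads
   WTY WTY_rep1     72.8503   127058
   WTY WTY_rep2     72.7798   127064
   ...
29382 windows tested, 0 removed by heterogeneity, 26 hyper / 120 hypo regions
```

Global methylation sits near 73% in every sample — aging does not move
the genome-wide level — while the caller recovers the planted local
changes: mostly hypomethylated regions (enhancer losses) plus a smaller
hypermethylated set (CpG-island gains), written to
`dmrs/WTY_vs_WTO.{dmrs,hyper,hypo}.tsv` with pooled counts, delta,
FET p/q and per-cohort heterogeneity q per region.  Downstream,
`dmrscan enrich` scores these regions against the emitted feature BEDs
(the planted enhancer enrichment comes out around nine-fold,
empirical p ≈ 0.001 at 1000 permutations) and `dmrscan profile`
draws composite methylation profiles over any region set.

The same operations are available as a library:

```python
from dmrscan import call_dmrs, PipelineConfig
from dmrscan import synthetic_data as sd

genome = sd.build_genome(sd.SimConfig(seed=4))
young = sd.simulate_cohort(genome, "WTY", age="young", rng=41)
old = sd.simulate_cohort(genome, "WTO", age="old", rng=42)
dmrs = call_dmrs(young, old, PipelineConfig())
```

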
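# Methods

## Data model and coordinates

All genomic coordinates are 0-based half-open internally.  Bismark-style
CpG reports are 1-based on disk and shifted on read; BED/bedGraph pass
through unshifted.  A CpG dyad is anchored at the plus-strand C; a
minus-strand call at position p belongs to the dyad at p−1, and
collapsing sums the two strands' methylated/unmethylated counts.  Orphan
single-strand calls are retained as collapsed records: discarding them
would bias coverage downward at asymmetrically covered dyads.
Chromosome names are matched as exact strings — no `chr` prefix
normalisation — so mismatched annotation tracks fail loudly rather than
silently producing empty overlaps.

## Differential methylation model

The caller treats methylation as a per-dyad binomial: within a cohort,
reads at a dyad are Bernoulli draws from that cohort's methylation
level.  Replicates are pooled for the primary test; replicate agreement
is enforced separately (below) rather than modelled (no beta-binomial
dispersion — windows whose replicates disagree are removed, not
shrunk).

**Two-tailed Fisher exact test.**  The minimum-likelihood convention:
with margins fixed, p is the total hypergeometric probability of all
tables no more probable than the observed one.  Tables with grand total
≤ 200 are evaluated in exact integer arithmetic (the comparison
`P(T) ≤ P(obs)` is decided on integer numerators, so the p-value is a
correctly rounded rational); larger tables use log-gamma probabilities
with the 1 + 1e-7 relative tie tolerance that exact-test
implementations conventionally use.  A zero row or column margin
carries no information and returns p = 1.  Degenerate inputs therefore
never produce spurious significance.

**Heterogeneity filter.**  Pearson chi-squared on the R×2 table of
replicate window counts, df = R−1, no continuity correction and no
minimum-expected-count exclusion: window-level coverage and CpG-count
thresholds already exclude the degenerate cases, and a continuity
correction would make the filter too permissive exactly where it is
needed (low counts).  Replicate rows with zero reads in a window are
dropped; a window reduced to fewer than two usable rows yields p = 1
(no evidence of heterogeneity is obtainable from one row).

**Multiple testing.**  BH step-up, applied independently to three
families: per-CpG FET p-values over tested dyads; window FET p-values
over tested windows; and per-cohort heterogeneity p-values over the
same window universe (one correction per cohort — the two cohorts'
replicate structures are separate hypotheses families).

**Windows.**  window_size = 500 bp with window_step = 250 bp by
default.  "Sliding" tiling doubles the tested universe but halves the
worst-case misalignment between a window and a true effect region; a
disjoint tiling (step = 500) is available, in which case merging is the
identity.  A window is tested when both cohorts have ≥ 5 covered dyads
inside it; the per-CpG ten-read coverage rule applies to the per-CpG
analysis only.  Overlapping surviving windows of the same direction are
merged; the merged record spans their union and carries the counts and
delta of the strongest (smallest FET p) member window, with the most
conservative member q-values.  Note the FDR guarantee attaches to the
*window* family: merging concentrates neighbouring true windows into
single regions, so the false fraction among merged regions is higher
than among windows even under perfect FDR control.  Operating
characteristics are therefore quoted at the window level
(`call_dmrs(..., merge=False)`).

**Directions and set algebra.**  Direction is the sign of the pooled
percent difference (second cohort minus first); a significant window
always has a non-zero difference.  DMR set intersection uses the
≥ 1 bp overlap predicate on half-open intervals.  Suppression follows
the direction-reversal rule: an aging DMR is suppressed by an
intervention iff it overlaps a treated-vs-old DMR of the opposite
direction; treatment DMRs overlapping no aging DMR are reported as
non-age-related changes.

## Permutation enrichment

The null model redraws each query interval with its length preserved:
a chromosome is chosen with probability proportional to its number of
valid start positions (length − ℓ + 1), the start uniform among them,
honouring an optional exclusion list by rejection.  Chromosome identity
of the query is *not* preserved by default (the simplest model
consistent with "equally sized random regions"); a same-chromosome
variant can be obtained by passing a single-chromosome genome.  Both
count-mode (intervals touching ≥ 1 feature bp — the binary
interaction-map semantics) and bp-mode (total overlapping base pairs)
statistics are first-class.  Fold is observed over permutation-mean;
when the expected overlap is zero the fold is reported as undefined
rather than infinite.  Empirical p is (r+1)/(n+1), never zero; with the
default n_perm = 1000 the attainable floor is ~0.001.  With small query
sets the per-run fold estimate scatters binomially around 1 under the
null (sd ≈ 0.3 at 100 query intervals on the toy calibration genome);
calibration claims are therefore made about the mean fold over
repetitions, not individual draws.

## Summaries and profiles

Region-level methylation is the *unweighted* mean of per-dyad percent
methylation over covered dyads — every CpG counts equally, making the
summary robust to coverage gradients; the pooled-count ratio is also
reported.  Heatmap columns are Z-scored with the n−1 standard deviation
over samples within the column; zero-variance columns become zeros.
PCA uses dyads covered in every sample (min_cov = 1 by default, a
config choice), centred, via SVD.

Locus profiles are Nadaraya–Watson estimates: Gaussian kernel over
per-dyad percentages weighted by dyad coverage, default bandwidth
100 bp and grid step 50 bp — enough to resolve a 500-bp region while
suppressing per-CpG sampling noise; grid points with no dyad within
three bandwidths are undefined.  Composite profiles rescale each region
body to n_bins bins with fixed-width flank bins and average per-dyad
percentages unweighted across regions and replicates; composites are
unstranded (enhancers and CpG islands carry no inherent orientation).

## The synthetic methylome generator

The generator emulates the statistical structure of a liver WGBS aging
study, not its sequence content:

* **Genome**: two 5-Mb chromosomes.  Non-overlapping genes (250 ×
  20 kb), enhancers (400 × 1250 bp, ~5% of the genome), bivalent CpG
  islands (60 × 600 bp) and super-enhancer spans around a subset of
  enhancers.  CpG dyads are placed at density 0.012/bp in background,
  0.02 in enhancers and 0.1 in islands (~127,000 dyads).  With the
  regional baselines below, the island share of dyads (~3%, near the
  realistic genomic fraction) puts the genome-wide level at ~72.7%,
  matching the ~73% global methylation such studies report.
* **Baselines**: background 0.75, enhancer 0.70, island 0.08.
* **Planted age effects**: 30% of enhancers carry a −0.30 methylation
  delta in old animals over a 500-bp span; 30% of islands a +0.30
  delta.  80% of hypo loci sit in enhancers, the rest in CpG-densified
  background spans (planted loci emulate CpG-enriched regulatory
  elements, so they carry enhancer CpG density — ~10 dyads per 500-bp
  window).  Every planted span is recorded in the truth table.
* **Genotype buffering**: the dwarf genotype adds +0.10 to the baseline
  at planted hypo loci in both ages, reproducing the higher starting
  methylation that buffers long-lived mice against age-associated loss.
* **Interventions**: in treated old cohorts a configured fraction of
  planted loci (CR 0.8, rapamycin 0.4) reverts fully to the young
  level; the reverted subset is chosen deterministically per seed.
* **Counts**: per replicate and dyad, coverage ~ Poisson(7.0) (4.4 for
  the low-coverage intervention cohorts, matching the reduced
  sequencing depth of such arms) and methylated reads ~
  Binomial(coverage, p).  Uncovered dyads are omitted, as in coverage
  files.  Four replicates per cohort.
* **Noise**: logit-normal noise, sd 0.15, drawn independently per CpG
  and replicate.  This choice — rather than a shared per-replicate or
  per-window offset — keeps replicate-pooled window counts close to
  binomial, which is the regime the pooled Fisher test assumes; even
  so, the residual overdispersion inflates the FET tail by roughly
  1.4× at the BH threshold, which FET discreteness largely offsets.
  Realized false-discovery proportion at the 5% window FDR measures
  ~5% over seeds, so window-level precision on planted fixtures sits
  at, not above, 0.95.  A shared per-replicate offset would instead
  make the pooled test anti-conservative by construction.
* **Expression coupling**: genes receive lognormal FPKM (20%
  unexpressed); planted enhancer effects are drawn preferentially into
  enhancers hosted by highly expressed genes (weight (1 + rank)²),
  reproducing the concentration of age-associated enhancer losses in
  highly expressed genes.

What the generator does **not** emulate: sequence-dependent coverage
bias, bisulfite conversion error, strand-asymmetric methylation,
correlated methylation between neighbouring CpGs, copy-number or SNP
effects, and chromosome-scale composition differences.  Passing tests
demonstrate the pipeline's statistical behaviour under its own model
assumptions, not performance on real libraries.

## Validation battery and problem sizes

`dmrscan.evaluation` (driven by `scripts/acceptance.py` and the
acceptance tests) runs: exact-test agreement with a rational-arithmetic
enumeration oracle (~27,000 tables: an exhaustive grid with row sums
≤ 16, the full margin-30 slab, and a random margin ≤ 30 sample); 20
null fixtures on a single 5-Mb chromosome (~15,000 tested windows
each); 3 planted fixtures on the default genome (~140 truth regions
each); 200 planted split-replicate (0.9/0.9/0.1/0.1) windows for the
heterogeneity filter; 200 null repetitions of the enrichment at
n_perm = 1000; buffering and suppression recovery runs; and a repeated
end-to-end run compared byte-for-byte.  The whole battery completes in
a few minutes on one core.  The suppression estimate conditions its
denominator on aging DMRs that overlap the truth table, since false
aging calls cannot overlap a direction-reversed treatment DMR and would
otherwise bias the estimate low by exactly the false-call fraction.

## Known limitations

* The pooled FET + heterogeneity-filter design inherits the classical
  weakness of count-pooling: biological overdispersion beyond the
  filter's reach makes the test slightly anti-conservative; dispersion
  modelling is out of scope by design.
* Merged-region FDR is not separately controlled (see Windows above).
* The "sliding window" step and merging rule are one interpretation of
  a dynamic windowing scheme; the disjoint-tiling mode is provided as
  the alternative reading.
* The random-placement null ignores GC/length-matching and genome gaps
  beyond the exclusion list; fold estimates against strongly clustered
  features should be read accordingly.
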
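"""Simulation-based validation harness.

Each function sets up a planted or null study at desk scale, runs the
pipeline end to end, and scores the result against the generator's truth
table.  These are the package's own operating-characteristic checks:
exact-test agreement with enumeration, false-discovery control under the
null, power and precision on planted effects, heterogeneity-filter
behaviour, permutation-enrichment calibration and detection, buffering
and suppression recovery, and byte-level determinism.

Problem sizes are chosen so the whole battery runs in minutes on one
core: null and heterogeneity fixtures use a single 5-Mb chromosome
(~15,000 tested 500-bp windows), power fixtures the default 10-Mb
two-chromosome genome (~165 planted regions per seed).
"""

from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree

from dmrscan import synthetic_data as sd
from dmrscan.dmr_calling import (
    PipelineConfig,
    call_dmrs,
    split_by_direction,
    suppression_analysis,
)
from dmrscan.enrichment import GenomeSpec, permutation_enrichment, random_regions
from dmrscan.meth_io import FeatureSet, dmrs_to_frame
from dmrscan.summaries import region_mean_methylation

__all__ = [
    "null_fdr_counts",
    "planted_power",
    "het_filter_removal",
    "enrichment_calibration",
    "enrichment_detection",
    "buffering_recovery",
    "suppression_recovery",
    "determinism_check",
]


def _single_chrom_cfg(seed: int, **kw) -> sd.SimConfig:
    base = dict(
        seed=seed,
        chrom_lengths={"chr1": 5_000_000},
        n_genes=125, n_enhancers=200, n_islands=30, n_super_enhancers=15,
    )
    base.update(kw)
    return sd.SimConfig(**base)


def _truth_trees(truth) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in truth.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end,
                                                       r.direction)
    return trees


def null_fdr_counts(base_seed: int, n_fixtures: int = 20) -> list[int]:
    """DMRs called between two identically distributed cohorts, per fixture."""
    counts = []
    for i in range(n_fixtures):
        seed = base_seed + i
        cfg = _single_chrom_cfg(seed, frac_enhancers_affected=0.0,
                                frac_islands_affected=0.0)
        g = sd.build_genome(cfg)
        a = sd.simulate_cohort(g, "N1", age="young", rng=seed * 100 + 1)
        b = sd.simulate_cohort(g, "N2", age="young", rng=seed * 100 + 2)
        counts.append(len(call_dmrs(a, b, PipelineConfig())))
    return counts


def planted_power(base_seed: int, n_seeds: int = 3) -> dict:
    """Recall and precision of planted age effects, pooled over seeds.

    Precision is scored on the significant-window set (``merge=False``) —
    the discovery unit the BH-FDR correction controls; recall is the
    fraction of planted truth intervals overlapped by a correct-direction
    significant window.
    """
    tp = fp = 0
    truth_total = truth_hit = 0
    for i in range(n_seeds):
        seed = base_seed + i
        g = sd.build_genome(sd.SimConfig(seed=seed))
        young = sd.simulate_cohort(g, "WTY", age="young", rng=seed * 10 + 1)
        old = sd.simulate_cohort(g, "WTO", age="old", rng=seed * 10 + 2)
        windows = call_dmrs(young, old, PipelineConfig(), merge=False)
        trees = _truth_trees(g.truth)
        for d in windows:
            hits = trees.get(d.chrom, IntervalTree()).overlap(d.start, d.end)
            if any(h.data == d.direction for h in hits):
                tp += 1
            else:
                fp += 1
        dtrees: dict[str, IntervalTree] = {}
        for d in windows:
            dtrees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end,
                                                            d.direction)
        truth_total += len(g.truth)
        for r in g.truth.itertuples(index=False):
            hits = dtrees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
            if any(h.data == r.direction for h in hits):
                truth_hit += 1
    return {
        "recall": truth_hit / truth_total,
        "precision": tp / (tp + fp),
        "n_called_windows": tp + fp,
        "n_truth": truth_total,
    }


def het_filter_removal(seed: int, n_windows: int = 200) -> float:
    """Fraction of planted split-replicate (0.9/0.9/0.1/0.1) windows removed."""
    rng = np.random.default_rng(seed)
    cfg = _single_chrom_cfg(seed, frac_enhancers_affected=0.0,
                            frac_islands_affected=0.0)
    g = sd.build_genome(cfg)
    a = sd.simulate_cohort(g, "A", age="young", rng=seed * 100 + 1)
    b = sd.simulate_cohort(g, "B", age="young", rng=seed * 100 + 2)
    length = cfg.chrom_lengths["chr1"]
    starts = (np.linspace(0, length - 100_000, n_windows).astype(int)
              // 500 * 500)
    windows = [(int(s), int(s) + 500) for s in starts]
    props = [0.9, 0.9, 0.1, 0.1]
    for j, rep in enumerate(b.replicates):
        df = rep.data
        pos = df["pos"].to_numpy()
        for s, e in windows:
            m = (pos >= s) & (pos < e)
            cov = (df.loc[m, "n_meth"] + df.loc[m, "n_unmeth"]).to_numpy()
            nm = rng.binomial(cov, props[j])
            df.loc[m, "n_meth"] = nm
            df.loc[m, "n_unmeth"] = cov - nm
    dmrs = call_dmrs(a, b, PipelineConfig())
    tree = IntervalTree()
    for d in dmrs:
        tree.addi(d.start, d.end)
    removed = sum(1 for s, e in windows if not tree.overlap(s, e))
    return removed / len(windows)


def enrichment_calibration(seed: int, n_reps: int = 200,
                           n_perm: int = 1000) -> dict:
    """Null placement model: empirical-p super-uniformity and mean fold."""
    genome = GenomeSpec(lengths={"chr1": 10_000})
    features = FeatureSet.from_intervals("f", [("chr1", 0, 1000)])
    rng = np.random.default_rng(seed)
    pvals, folds = [], []
    for _ in range(n_reps):
        query = random_regions(genome, [("chr1", 0, 10)] * 100, rng)
        r = permutation_enrichment(query, features, genome, n_perm=n_perm,
                                   mode="count",
                                   seed=int(rng.integers(2**31)))
        pvals.append(r.empirical_pvalue)
        folds.append(r.fold)
    pvals, folds = np.asarray(pvals), np.asarray(folds)
    return {
        "prop_sig_at_05": float((pvals <= 0.05).mean()),
        "mean_fold": float(folds.mean()),
        "n_reps": n_reps,
    }


def enrichment_detection(seed: int, n_perm: int = 1000) -> dict:
    """Enhancer enrichment of called hypomethylated aging DMRs.

    With 80% of planted hypo loci inside enhancers covering ~5% of the
    genome, the count-mode fold should be large and the empirical p at
    its floor.
    """
    g = sd.build_genome(sd.SimConfig(seed=seed))
    young = sd.simulate_cohort(g, "WTY", age="young", rng=seed * 10 + 1)
    old = sd.simulate_cohort(g, "WTO", age="old", rng=seed * 10 + 2)
    dmrs = call_dmrs(young, old, PipelineConfig())
    _, hypo = split_by_direction(dmrs)
    spans = [(d.chrom, d.start, d.end) for d in hypo]
    r = permutation_enrichment(spans, g.features["enhancers"],
                               GenomeSpec(lengths=g.spec.lengths),
                               n_perm=n_perm, mode="count", seed=seed)
    return {"fold": r.fold, "empirical_p": r.empirical_pvalue,
            "observed": r.observed, "expected": r.expected,
            "n_query": len(spans)}


def buffering_recovery(base_seed: int, n_seeds: int = 3) -> list[float]:
    """Young dwarf minus young WT mean methylation at planted hypo loci (pct)."""
    diffs = []
    for i in range(n_seeds):
        seed = base_seed + i
        g = sd.build_genome(sd.SimConfig(seed=seed))
        hypo = g.truth[g.truth["direction"] == "hypo"]
        regions = FeatureSet.from_intervals(
            "hypo_truth",
            [(r.chrom, r.start, r.end) for r in hypo.itertuples(index=False)],
        )
        wty = sd.simulate_cohort(g, "WTY", age="young", genotype="WT",
                                 rng=seed * 31 + 1)
        dy = sd.simulate_cohort(g, "DY", age="young", genotype="dwarf",
                                rng=seed * 31 + 2)
        m_wt = np.mean([region_mean_methylation(r, regions).aggregate_pct
                        for r in wty.replicates])
        m_dw = np.mean([region_mean_methylation(r, regions).aggregate_pct
                        for r in dy.replicates])
        diffs.append(float(m_dw - m_wt))
    return diffs


def suppression_recovery(seed: int) -> dict:
    """Measured suppressed fractions for the CR and rapamycin cohorts.

    The denominator is restricted to aging DMRs that overlap a planted
    truth interval with matching direction, so the estimate targets the
    generator's configured fraction rather than being diluted by the
    ~5% false aging calls (which cannot, by construction, be suppressed).
    """
    g = sd.build_genome(sd.SimConfig(seed=seed))
    trees = _truth_trees(g.truth)
    young = sd.simulate_cohort(g, "Y", age="young", low_coverage=True,
                               rng=seed * 7 + 1)
    old = sd.simulate_cohort(g, "O", age="old", low_coverage=True,
                             rng=seed * 7 + 2)
    aging = call_dmrs(young, old, PipelineConfig())
    aging_true = [
        d for d in aging
        if any(h.data == d.direction
               for h in trees.get(d.chrom, IntervalTree()).overlap(d.start,
                                                                   d.end))
    ]
    out = {}
    for i, treatment in enumerate(("CR", "Rapa")):
        treated = sd.simulate_cohort(g, treatment, age="old",
                                     treatment=treatment, low_coverage=True,
                                     rng=seed * 7 + 3 + i)
        tdmrs = call_dmrs(old, treated, PipelineConfig())
        res = suppression_analysis(aging_true, tdmrs)
        out[treatment] = {
            "suppressed_fraction": res.suppressed_fraction,
            "n_aging": len(aging_true),
            "n_treatment_dmrs": len(tdmrs),
            "n_non_age_related": len(res.non_age_related),
        }
    return out


def determinism_check(seed: int) -> bool:
    """Two identically seeded end-to-end runs yield byte-identical TSVs."""
    outputs = []
    for _ in range(2):
        cfg = sd.SimConfig(seed=seed, chrom_lengths={"chr1": 1_000_000},
                           n_genes=25, n_enhancers=40, n_islands=8,
                           n_super_enhancers=5)
        g = sd.build_genome(cfg)
        young = sd.simulate_cohort(g, "WTY", age="young", rng=seed + 1)
        old = sd.simulate_cohort(g, "WTO", age="old", rng=seed + 2)
        dmrs = call_dmrs(young, old, PipelineConfig())
        outputs.append(dmrs_to_frame(dmrs).to_csv(sep="\t", index=False))
    return outputs[0] == outputs[1]
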
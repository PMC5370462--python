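"""Differential methylation calling between replicate cohorts.

Two layers of inference are provided.  Per-CpG calls test each dyad whose
pooled coverage reaches ten reads in both cohorts with a two-tailed
Fisher exact test on the pooled 2x2 table, BH-FDR corrected at 5%.
Region calls tile each chromosome with 500-bp windows advancing by a
configurable step (250 bp by default, so neighbouring windows overlap);
per window the pooled-count Fisher test is combined with a chi-squared
test of heterogeneity across the replicates of each cohort, both BH-FDR
corrected over the tested-window universe, and a window survives only
with a significant Fisher q and a non-significant heterogeneity q in
both cohorts.  Overlapping surviving windows of the same direction are
merged into a single region reported with the union span.

Directions are relative to the first cohort: a region is "hyper" when
the second cohort is more methylated than the first, "hypo" when less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from dmrscan.meth_io import MethCallTable
from dmrscan.stats_core import (
    bh_fdr,
    chi2_heterogeneity_many,
    fisher_two_tailed_many,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "PipelineConfig",
    "DMSResult",
    "DMR",
    "call_dms_cpgs",
    "call_dmrs",
    "split_by_direction",
    "intersect_dmr_sets",
    "IntersectResult",
    "suppression_analysis",
    "SuppressionResult",
]


@dataclass
class Cohort:
    """Named group of replicate methylomes (typically four animals)."""

    name: str
    replicates: list[MethCallTable]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("cohort needs >=1 replicate")
        for rep in self.replicates:
            if not rep.is_collapsed:
                raise ValueError(
                    f"replicate {rep.sample_id!r} is not dyad-collapsed"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def pooled(self) -> pd.DataFrame:
        """Replicate-pooled counts: one row per (chrom, pos)."""
        return (
            pd.concat([r.data for r in self.replicates], ignore_index=True)
            .groupby(["chrom", "pos"], as_index=False, sort=True)[
                ["n_meth", "n_unmeth"]
            ]
            .sum()
        )


@dataclass
class PipelineConfig:
    """Thresholds and knobs for DMR calling.

    window_size / window_step are in base pairs; with step < size the
    windows overlap ("sliding"), with step == size they tile disjointly.
    min_cov_per_cpg applies to the per-CpG test only, following the
    convention that the ten-read threshold attaches to the CpG-site test;
    window inclusion is instead governed by min_cpgs_per_window covered
    dyads per cohort.
    """

    window_size: int = 500
    window_step: int = 250
    min_cpgs_per_window: int = 5
    min_cov_per_cpg: int = 10
    fdr_alpha: float = 0.05
    het_alpha: float = 0.05
    n_permutations: int = 1000
    rng_seed: int = 0
    require_replicates: bool = False

    def __post_init__(self) -> None:
        if self.window_step > self.window_size or self.window_step <= 0:
            raise ValueError("require 0 < window_step <= window_size")
        for alpha in (self.fdr_alpha, self.het_alpha):
            if not 0.0 < alpha < 1.0:
                raise ValueError("alphas must lie in (0, 1)")


@dataclass
class DMSResult:
    """A significantly differentially methylated CpG dyad."""

    chrom: str
    pos: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    fet_p: float
    fet_q: float
    direction: str  # hyper iff cohort B more methylated than cohort A


@dataclass
class DMR:
    """A differentially methylated region (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    direction: str
    n_cpgs: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    delta_pct: float  # pooled percent methylation, cohort B minus cohort A
    fet_p: float
    fet_q: float
    het_q_a: float
    het_q_b: float

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "DMR") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _percent(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, 100.0 * meth / np.maximum(total, 1), np.nan)


def call_dms_cpgs(
    a: Cohort, b: Cohort, cfg: PipelineConfig | None = None
) -> list[DMSResult]:
    """Per-CpG differential methylation between pooled cohorts.

    Dyads whose pooled coverage reaches ``cfg.min_cov_per_cpg`` in both
    cohorts are tested with a two-tailed Fisher exact test; BH-FDR is
    applied across all tested dyads and dyads with q < ``cfg.fdr_alpha``
    are returned with their direction.
    """
    cfg = cfg or PipelineConfig()
    pa = a.pooled()
    pb = b.pooled()
    merged = pa.merge(pb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    tested = merged[(cov_a >= cfg.min_cov_per_cpg) & (cov_b >= cfg.min_cov_per_cpg)]
    if tested.empty:
        logger.warning("call_dms_cpgs: no dyad passes the coverage threshold")
        return []
    p = fisher_two_tailed_many(
        tested["n_meth_a"].to_numpy(),
        tested["n_unmeth_a"].to_numpy(),
        tested["n_meth_b"].to_numpy(),
        tested["n_unmeth_b"].to_numpy(),
    )
    q = bh_fdr(p)
    pct_a = _percent(
        tested["n_meth_a"].to_numpy(),
        (tested["n_meth_a"] + tested["n_unmeth_a"]).to_numpy(),
    )
    pct_b = _percent(
        tested["n_meth_b"].to_numpy(),
        (tested["n_meth_b"] + tested["n_unmeth_b"]).to_numpy(),
    )
    out: list[DMSResult] = []
    for i, row in enumerate(tested.itertuples(index=False)):
        if q[i] >= cfg.fdr_alpha:
            continue
        out.append(
            DMSResult(
                chrom=row.chrom,
                pos=int(row.pos),
                meth_a=int(row.n_meth_a),
                unmeth_a=int(row.n_unmeth_a),
                meth_b=int(row.n_meth_b),
                unmeth_b=int(row.n_unmeth_b),
                fet_p=float(p[i]),
                fet_q=float(q[i]),
                direction="hyper" if pct_b[i] > pct_a[i] else "hypo",
            )
        )
    return out


def _replicate_window_sums(
    cohort: Cohort, chrom: str, union_pos: np.ndarray,
    lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Window sums per replicate aligned to window [lo, hi) index bounds."""
    n_win = lo.shape[0]
    meth = np.zeros((n_win, cohort.n_replicates), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, rep in enumerate(cohort.replicates):
        sub = rep.data[rep.data["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(union_pos, pos)
        m = np.zeros(union_pos.shape[0] + 1, dtype=np.int64)
        u = np.zeros_like(m)
        m[1:][idx] = sub["n_meth"].to_numpy()
        u[1:][idx] = sub["n_unmeth"].to_numpy()
        mc = np.cumsum(m)
        uc = np.cumsum(u)
        meth[:, j] = mc[hi] - mc[lo]
        unmeth[:, j] = uc[hi] - uc[lo]
    return meth, unmeth


def call_dmrs(
    a: Cohort,
    b: Cohort,
    cfg: PipelineConfig | None = None,
    stats: dict | None = None,
    merge: bool = True,
) -> list[DMR]:
    """Sliding-window DMR calling with replicate-heterogeneity filtering.

    See the module docstring for the procedure.  ``stats``, if given, is
    filled with the counts a run log reports: windows tested, windows
    removed by the heterogeneity filter, and significant windows and
    merged regions by direction.  ``merge=False`` returns the surviving
    windows themselves (the discovery unit the FDR correction controls)
    instead of merged maximal runs; with a disjoint tiling
    (window_step == window_size) the two are identical.
    """
    cfg = cfg or PipelineConfig()
    for cohort in (a, b):
        if cohort.n_replicates < 2 and cfg.require_replicates:
            raise ValueError(
                f"cohort {cohort.name!r} has <2 replicates and "
                "require_replicates is set"
            )

    chroms = sorted(
        set(
            chrom
            for cohort in (a, b)
            for rep in cohort.replicates
            for chrom in rep.data["chrom"].unique()
        )
    )
    # accumulated per tested window
    win_chrom: list[str] = []
    win_start: list[np.ndarray] = []
    counts = {key: [] for key in
              ("meth_a", "unmeth_a", "meth_b", "unmeth_b", "n_cpgs")}
    het_p_parts: dict[str, list[np.ndarray]] = {"a": [], "b": []}

    for chrom in chroms:
        pos_sets = []
        for cohort in (a, b):
            for rep in cohort.replicates:
                pos_sets.append(
                    rep.data.loc[rep.data["chrom"] == chrom, "pos"].to_numpy()
                )
        union_pos = np.unique(np.concatenate(pos_sets))
        if union_pos.size == 0:
            continue
        last = int(union_pos[-1])
        starts = np.arange(0, last + 1, cfg.window_step, dtype=np.int64)
        lo = np.searchsorted(union_pos, starts, side="left")
        hi = np.searchsorted(union_pos, starts + cfg.window_size, side="left")
        meth_a, unmeth_a = _replicate_window_sums(a, chrom, union_pos, lo, hi)
        meth_b, unmeth_b = _replicate_window_sums(b, chrom, union_pos, lo, hi)
        cov_a = meth_a + unmeth_a
        cov_b = meth_b + unmeth_b

        # covered-dyad counts per cohort (pooled coverage > 0 at the dyad)
        def _covered_counts(meth, unmeth, reps, chrom=chrom,
                            union_pos=union_pos, lo=lo, hi=hi):
            pooled = np.zeros(union_pos.shape[0], dtype=np.int64)
            for rep in reps:
                sub = rep.data[rep.data["chrom"] == chrom]
                idx = np.searchsorted(union_pos, sub["pos"].to_numpy())
                pooled[idx] += (
                    sub["n_meth"].to_numpy() + sub["n_unmeth"].to_numpy()
                )
            cum = np.concatenate([[0], np.cumsum(pooled > 0)])
            return cum[hi] - cum[lo], pooled

        ncpg_a, pooled_cov_a = _covered_counts(meth_a, unmeth_a, a.replicates)
        ncpg_b, pooled_cov_b = _covered_counts(meth_b, unmeth_b, b.replicates)
        both_cov = np.concatenate(
            [[0], np.cumsum((pooled_cov_a > 0) & (pooled_cov_b > 0))]
        )
        ncpg_both = both_cov[hi] - both_cov[lo]

        testable = (ncpg_a >= cfg.min_cpgs_per_window) & (
            ncpg_b >= cfg.min_cpgs_per_window
        )
        if not testable.any():
            continue
        sel = np.flatnonzero(testable)
        win_chrom.extend([chrom] * sel.size)
        win_start.append(starts[sel])
        counts["meth_a"].append(meth_a[sel].sum(axis=1))
        counts["unmeth_a"].append(unmeth_a[sel].sum(axis=1))
        counts["meth_b"].append(meth_b[sel].sum(axis=1))
        counts["unmeth_b"].append(unmeth_b[sel].sum(axis=1))
        counts["n_cpgs"].append(ncpg_both[sel])
        for key, meth, unmeth, cohort in (
            ("a", meth_a, unmeth_a, a),
            ("b", meth_b, unmeth_b, b),
        ):
            if cohort.n_replicates < 2:
                logger.warning(
                    "cohort %s has <2 replicates; heterogeneity test skipped",
                    cohort.name,
                )
                het_p_parts[key].append(np.ones(sel.size))
            else:
                _, p_het = chi2_heterogeneity_many(meth[sel], unmeth[sel])
                het_p_parts[key].append(p_het)

    if not win_chrom:
        logger.warning("call_dmrs: zero testable windows")
        if stats is not None:
            stats.update(n_windows_tested=0, n_removed_heterogeneity=0,
                         n_hyper=0, n_hypo=0, n_regions_hyper=0,
                         n_regions_hypo=0)
        return []

    starts_all = np.concatenate(win_start)
    meth_a_all = np.concatenate(counts["meth_a"])
    unmeth_a_all = np.concatenate(counts["unmeth_a"])
    meth_b_all = np.concatenate(counts["meth_b"])
    unmeth_b_all = np.concatenate(counts["unmeth_b"])
    ncpgs_all = np.concatenate(counts["n_cpgs"])
    het_p_a = np.concatenate(het_p_parts["a"])
    het_p_b = np.concatenate(het_p_parts["b"])

    fet_p = fisher_two_tailed_many(
        meth_a_all, unmeth_a_all, meth_b_all, unmeth_b_all
    )
    fet_q = bh_fdr(fet_p)
    het_q_a = bh_fdr(het_p_a)
    het_q_b = bh_fdr(het_p_b)

    pct_a = _percent(meth_a_all, meth_a_all + unmeth_a_all)
    pct_b = _percent(meth_b_all, meth_b_all + unmeth_b_all)
    delta = pct_b - pct_a

    sig = fet_q < cfg.fdr_alpha
    homogeneous = (het_q_a >= cfg.het_alpha) & (het_q_b >= cfg.het_alpha)
    keep = sig & homogeneous & (delta != 0)

    n_tested = len(win_chrom)
    n_removed_het = int((sig & ~homogeneous).sum())

    kept_windows: list[DMR] = []
    chrom_arr = np.asarray(win_chrom)
    for i in np.flatnonzero(keep):
        kept_windows.append(
            DMR(
                chrom=str(chrom_arr[i]),
                start=int(starts_all[i]),
                end=int(starts_all[i] + cfg.window_size),
                direction="hyper" if delta[i] > 0 else "hypo",
                n_cpgs=int(ncpgs_all[i]),
                meth_a=int(meth_a_all[i]),
                unmeth_a=int(unmeth_a_all[i]),
                meth_b=int(meth_b_all[i]),
                unmeth_b=int(unmeth_b_all[i]),
                delta_pct=float(delta[i]),
                fet_p=float(fet_p[i]),
                fet_q=float(fet_q[i]),
                het_q_a=float(het_q_a[i]),
                het_q_b=float(het_q_b[i]),
            )
        )

    merged = _merge_same_direction(kept_windows) if merge else kept_windows
    n_hyper = sum(1 for d in kept_windows if d.direction == "hyper")
    n_hypo = len(kept_windows) - n_hyper
    if stats is not None:
        stats.update(
            n_windows_tested=n_tested,
            n_removed_heterogeneity=n_removed_het,
            n_hyper=n_hyper,
            n_hypo=n_hypo,
            n_regions_hyper=sum(1 for d in merged if d.direction == "hyper"),
            n_regions_hypo=sum(1 for d in merged if d.direction == "hypo"),
        )
    logger.info(
        "call_dmrs %s vs %s: %d windows tested, %d removed by heterogeneity, "
        "%d hyper / %d hypo windows -> %d merged regions",
        a.name, b.name, n_tested, n_removed_het, n_hyper, n_hypo, len(merged),
    )
    return merged


def _merge_same_direction(windows: list[DMR]) -> list[DMR]:
    """Merge overlapping significant windows of the same direction.

    The merged region spans the union of its member windows; counts and
    delta are taken as sums/recomputed percent over member windows is not
    possible without the dyad data, so the merged record carries the
    summed counts of the *first-member-to-last-member union approximated
    by the strongest member*: counts from the member with the smallest
    Fisher p (its window is the core of the region), span from the union,
    n_cpgs as the max member count, fet_p/fet_q as the member minima and
    het_q as the member minima (all members already pass the filter).
    Disjoint tilings (step == window size) never overlap, so the output
    then equals the input.
    """
    if not windows:
        return []
    windows = sorted(windows, key=lambda d: (d.chrom, d.start, d.end))
    merged: list[DMR] = []
    group: list[DMR] = [windows[0]]
    for d in windows[1:]:
        last = group[-1]
        if d.chrom == last.chrom and d.start < max(g.end for g in group) \
                and d.direction == last.direction:
            group.append(d)
        else:
            merged.append(_combine_group(group))
            group = [d]
    merged.append(_combine_group(group))
    return merged


def _combine_group(group: list[DMR]) -> DMR:
    if len(group) == 1:
        return group[0]
    core = min(group, key=lambda d: (d.fet_p, d.start))
    return DMR(
        chrom=core.chrom,
        start=min(d.start for d in group),
        end=max(d.end for d in group),
        direction=core.direction,
        n_cpgs=max(d.n_cpgs for d in group),
        meth_a=core.meth_a,
        unmeth_a=core.unmeth_a,
        meth_b=core.meth_b,
        unmeth_b=core.unmeth_b,
        delta_pct=core.delta_pct,
        fet_p=min(d.fet_p for d in group),
        fet_q=min(d.fet_q for d in group),
        het_q_a=min(d.het_q_a for d in group),
        het_q_b=min(d.het_q_b for d in group),
    )


def split_by_direction(dmrs: list[DMR]) -> tuple[list[DMR], list[DMR]]:
    """Partition DMRs into (hypermethylated, hypomethylated) lists.

    A significant DMR always has a non-zero methylation difference, so a
    zero delta indicates corrupt input and raises.
    """
    hyper: list[DMR] = []
    hypo: list[DMR] = []
    for d in dmrs:
        if d.delta_pct == 0:
            raise ValueError(
                f"DMR {d.chrom}:{d.start}-{d.end} has zero delta; "
                "significant DMRs must differ between cohorts"
            )
        (hyper if d.delta_pct > 0 else hypo).append(d)
    return hyper, hypo


def _tree(dmrs: list[DMR]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for d in dmrs:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, d)
    return trees


@dataclass
class IntersectResult:
    """Overlap (>=1 bp) between two DMR sets."""

    shared_x: list[DMR]
    shared_y: list[DMR]
    x_only: list[DMR]
    y_only: list[DMR]
    bp_overlap: int

    @property
    def n_shared_x(self) -> int:
        return len(self.shared_x)

    @property
    def n_shared_y(self) -> int:
        return len(self.shared_y)


def intersect_dmr_sets(x: list[DMR], y: list[DMR]) -> IntersectResult:
    """Split two DMR lists into shared and exclusive elements.

    An element of x is shared when it overlaps >=1 bp of some element of
    y, and symmetrically.  ``bp_overlap`` is the total overlapping base
    pairs summed over x elements (y intervals may overlap each other, in
    which case shared base pairs are counted once per x element).
    """
    ty = _tree(y)
    shared_x, x_only = [], []
    bp = 0
    for d in x:
        hits = ty.get(d.chrom, IntervalTree()).overlap(d.start, d.end)
        if hits:
            shared_x.append(d)
            covered = IntervalTree()
            for h in hits:
                covered.addi(max(h.begin, d.start), min(h.end, d.end))
            covered.merge_overlaps()
            bp += sum(iv.end - iv.begin for iv in covered)
        else:
            x_only.append(d)
    tx = _tree(x)
    shared_y, y_only = [], []
    for d in y:
        if tx.get(d.chrom, IntervalTree()).overlap(d.start, d.end):
            shared_y.append(d)
        else:
            y_only.append(d)
    return IntersectResult(shared_x, shared_y, x_only, y_only, bp)


@dataclass
class SuppressionResult:
    """Aging DMRs suppressed (direction-reversed) by an intervention."""

    suppressed: list[DMR]
    not_suppressed: list[DMR]
    non_age_related: list[DMR]  # treatment DMRs overlapping no aging DMR

    @property
    def suppressed_fraction(self) -> float:
        total = len(self.suppressed) + len(self.not_suppressed)
        return len(self.suppressed) / total if total else float("nan")


def suppression_analysis(
    aging_dmrs: list[DMR], treatment_dmrs: list[DMR]
) -> SuppressionResult:
    """Classify aging DMRs as suppressed or not by a treatment's DMRs.

    An aging DMR is suppressed when the treatment reverses its direction
    at the same locus: a hypomethylated aging DMR overlapping a
    hypermethylated treated-vs-old DMR, or a hypermethylated aging DMR
    overlapping a hypomethylated one.  Treatment DMRs overlapping no
    aging DMR are returned as non-age-related methylation changes.
    """
    for d in aging_dmrs + treatment_dmrs:
        if d.direction not in ("hyper", "hypo"):
            raise ValueError("DMR without direction annotation")
    ttree = _tree(treatment_dmrs)
    suppressed, not_suppressed = [], []
    for d in aging_dmrs:
        want = "hyper" if d.direction == "hypo" else "hypo"
        hits = ttree.get(d.chrom, IntervalTree()).overlap(d.start, d.end)
        if any(h.data.direction == want for h in hits):
            suppressed.append(d)
        else:
            not_suppressed.append(d)
    atree = _tree(aging_dmrs)
    non_age = [
        d
        for d in treatment_dmrs
        if not atree.get(d.chrom, IntervalTree()).overlap(d.start, d.end)
    ]
    return SuppressionResult(suppressed, not_suppressed, non_age)
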
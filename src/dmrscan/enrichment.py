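"""Permutation-based overlap enrichment of region sets against features.

The null model redraws each query interval as an equally sized interval
placed uniformly on the genome: the chromosome is chosen with probability
proportional to the number of valid start positions it offers and the
start uniformly among them, honouring an optional exclusion list.  Fold
enrichment is observed / permutation-mean overlap, and significance is
the (r+1)/(n+1) empirical p-value.  Overlap is measured either as the
number of query intervals touching >=1 feature base pair (count mode,
the binary interaction-map semantics) or as total overlapping base pairs
(bp mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dmrscan.meth_io import FeatureSet
from dmrscan.stats_core import empirical_p

__all__ = [
    "GenomeSpec",
    "EnrichmentResult",
    "InteractionMap",
    "random_regions",
    "permutation_enrichment",
    "interaction_map",
    "expression_quartile_summary",
]


@dataclass
class GenomeSpec:
    """Chromosome names and lengths defining the placement universe."""

    lengths: dict[str, int]
    excluded: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("empty genome")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom, s, e in self.excluded:
            if chrom not in self.lengths or s < 0 or e > self.lengths[chrom] or s >= e:
                raise ValueError(f"bad exclusion ({chrom},{s},{e})")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


class _MergedIntervals:
    """Per-chromosome merged intervals with O(log n) overlap queries."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.cumcov: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self.starts[chrom] = starts
            self.ends[chrom] = ends
            self.cumcov[chrom] = np.concatenate([[0], np.cumsum(ends - starts)])

    def count_hits(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean: does each query interval overlap >=1 merged bp."""
        starts = self.starts.get(chrom)
        if starts is None or starts.size == 0:
            return np.zeros(qs.shape, dtype=bool)
        ends = self.ends[chrom]
        i = np.searchsorted(starts, qe, side="left") - 1
        valid = i >= 0
        hit = np.zeros(qs.shape, dtype=bool)
        hit[valid] = ends[i[valid]] > qs[valid]
        return hit

    def bp_overlap(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Base pairs of each query interval covered by merged features."""
        starts = self.starts.get(chrom)
        if starts is None or starts.size == 0:
            return np.zeros(qs.shape, dtype=np.int64)
        ends = self.ends[chrom]
        cum = self.cumcov[chrom]

        def covered_upto(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(ends, x, side="left")
            full = cum[i]
            partial = np.where(
                (i < starts.size) & (x > starts[np.minimum(i, starts.size - 1)]),
                x - starts[np.minimum(i, starts.size - 1)],
                0,
            )
            return full + np.maximum(partial, 0)

        return covered_upto(qe) - covered_upto(qs)


def random_regions(
    genome: GenomeSpec,
    template: list[tuple[str, int, int]],
    rng: np.random.Generator | int,
) -> list[tuple[str, int, int]]:
    """Draw one random interval per template interval, preserving lengths.

    Chromosomes are chosen with probability proportional to the number of
    valid start positions (length - interval length + 1); starts are
    uniform among valid positions.  With an exclusion list, placements
    overlapping an excluded interval are rejection-sampled away.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lengths = np.array([e - s for _, s, e in template], dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("template intervals must have positive length")
    chrom_names = list(genome.lengths)
    chrom_lens = np.array([genome.lengths[c] for c in chrom_names], dtype=np.int64)
    excl = _MergedIntervals(genome.excluded) if genome.excluded else None
    out: list[tuple[str, int, int]] = []
    for ell in lengths.tolist():
        usable = np.maximum(chrom_lens - ell + 1, 0)
        if usable.sum() == 0:
            raise ValueError(f"no chromosome can host an interval of length {ell}")
        probs = usable / usable.sum()
        while True:
            ci = rng.choice(len(chrom_names), p=probs)
            start = int(rng.integers(0, usable[ci]))
            chrom = chrom_names[ci]
            if excl is not None and excl.count_hits(
                chrom, np.array([start]), np.array([start + ell])
            )[0]:
                continue
            out.append((chrom, start, start + ell))
            break
    return out


@dataclass
class EnrichmentResult:
    """Observed vs permutation-expected overlap of a query set with features."""

    mode: str
    observed: float
    expected: float
    fold: float  # NaN when expected == 0 (undefined rather than infinite)
    p_greater: float
    p_less: float
    empirical_pvalue: float  # one-sided p on the side of the deviation
    n_permutations: int
    seed: int | None = None
    flagged: str | None = None


def _overlap_stat(
    mode: str,
    merged: _MergedIntervals,
    chroms: np.ndarray,
    qs: np.ndarray,
    qe: np.ndarray,
) -> float:
    total = 0.0
    for chrom in np.unique(chroms):
        m = chroms == chrom
        if mode == "count":
            total += merged.count_hits(chrom, qs[m], qe[m]).sum()
        else:
            total += merged.bp_overlap(chrom, qs[m], qe[m]).sum()
    return float(total)


def permutation_enrichment(
    query: list[tuple[str, int, int]],
    features: FeatureSet,
    genome: GenomeSpec,
    n_perm: int = 1000,
    mode: str = "count",
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Permutation enrichment of query intervals against a feature set.

    ``mode='count'``: number of query intervals overlapping >=1 feature
    bp.  ``mode='bp'``: total overlapping base pairs.  The reported
    ``empirical_pvalue`` is the one-sided p on the side the observation
    deviates (enrichment if observed >= expected, depletion otherwise);
    both one-sided p-values are also returned.
    """
    if not query:
        raise ValueError("empty query")
    if mode not in ("count", "bp"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed))
    )
    merged = _MergedIntervals(features.intervals())
    q_chrom = np.asarray([c for c, _, _ in query])
    q_start = np.asarray([s for _, s, _ in query], dtype=np.int64)
    q_end = np.asarray([e for _, _, e in query], dtype=np.int64)
    observed = _overlap_stat(mode, merged, q_chrom, q_start, q_end)

    if len(features) == 0:
        return EnrichmentResult(
            mode=mode, observed=observed, expected=0.0, fold=float("nan"),
            p_greater=1.0, p_less=1.0, empirical_pvalue=1.0,
            n_permutations=n_perm, flagged="empty feature set",
        )

    # vectorised placement: all permutations drawn in one block
    lengths = q_end - q_start
    chrom_names = list(genome.lengths)
    chrom_lens = np.array([genome.lengths[c] for c in chrom_names], dtype=np.int64)
    usable = np.maximum(chrom_lens[None, :] - lengths[:, None] + 1, 0)  # (Q, C)
    if (usable.sum(axis=1) == 0).any():
        raise ValueError("a template interval exceeds every chromosome")
    probs = usable / usable.sum(axis=1, keepdims=True)
    nq = len(query)
    null = np.empty(n_perm, dtype=float)
    excl = _MergedIntervals(genome.excluded) if genome.excluded else None
    cum_probs = np.cumsum(probs, axis=1)
    for it in range(n_perm):
        u = rng.random(nq)
        ci = (u[:, None] > cum_probs).sum(axis=1)
        starts = (rng.random(nq) * usable[np.arange(nq), ci]).astype(np.int64)
        if excl is not None:
            for j in range(nq):
                while excl.count_hits(
                    chrom_names[ci[j]],
                    np.array([starts[j]]),
                    np.array([starts[j] + lengths[j]]),
                )[0]:
                    ci[j] = int(
                        np.searchsorted(cum_probs[j], rng.random(), side="right")
                    )
                    starts[j] = int(rng.integers(0, usable[j, ci[j]]))
        chroms = np.asarray([chrom_names[k] for k in ci])
        null[it] = _overlap_stat(mode, merged, chroms, starts, starts + lengths)

    expected = float(null.mean())
    fold = observed / expected if expected > 0 else float("nan")
    p_greater = empirical_p(observed, null, "greater")
    p_less = empirical_p(observed, null, "less")
    return EnrichmentResult(
        mode=mode,
        observed=observed,
        expected=expected,
        fold=fold,
        p_greater=p_greater,
        p_less=p_less,
        empirical_pvalue=p_greater if observed >= expected else p_less,
        n_permutations=n_perm,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        flagged=None if expected > 0 else "expected overlap is zero",
    )


@dataclass
class InteractionMap:
    """Binary feature x DMR overlap matrix with per-feature summaries.

    ``matrix`` rows are feature sets, columns DMRs (ordered by the
    clustering); ``summary`` holds percent overlap and count-mode fold
    enrichment with its empirical p per feature set.
    """

    matrix: pd.DataFrame
    summary: pd.DataFrame
    column_order: list[int]


def interaction_map(
    dmrs: list,
    feature_sets: list[FeatureSet],
    genome: GenomeSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> InteractionMap:
    """Clustered binary interaction map of DMRs against feature sets.

    Cell (f, d) is 1 when DMR d overlaps >=1 bp of feature set f.  DMR
    columns are ordered by their row-membership signature (greedy binary
    pattern clustering), ties broken by genomic position.  Per feature
    set, percent overlap (100 * hits / n DMRs) and the count-mode
    permutation fold enrichment are reported.
    """
    if not feature_sets:
        raise ValueError("need >=1 feature set")
    spans = [(d.chrom, d.start, d.end) for d in dmrs]
    n = len(spans)
    rows = []
    summaries = []
    rng = np.random.default_rng(int(seed))
    for fs in feature_sets:
        merged = _MergedIntervals(fs.intervals())
        hits = np.zeros(n, dtype=int)
        for i, (chrom, s, e) in enumerate(spans):
            hits[i] = int(
                merged.count_hits(chrom, np.array([s]), np.array([e]))[0]
            )
        rows.append(hits)
        if n and len(fs):
            enr = permutation_enrichment(
                spans, fs, genome, n_perm=n_perm, mode="count", seed=rng
            )
            fold, pval = enr.fold, enr.empirical_pvalue
        else:
            fold, pval = float("nan"), 1.0
        summaries.append(
            {
                "feature": fs.name,
                "n_overlap": int(hits.sum()),
                "percent_overlap": 100.0 * hits.sum() / n if n else 0.0,
                "fold_enrichment": fold,
                "empirical_p": pval,
            }
        )
    mat = np.vstack(rows) if rows else np.zeros((0, n), dtype=int)
    # cluster columns by binary signature (rows-as-bits), then by position
    signatures = [tuple(mat[:, j]) for j in range(n)]
    order = sorted(
        range(n), key=lambda j: (signatures[j], spans[j][0], spans[j][1]),
        reverse=False,
    )
    order.sort(key=lambda j: signatures[j], reverse=True)
    labels = [f"{c}:{s}-{e}" for c, s, e in spans]
    matrix = pd.DataFrame(
        mat[:, order],
        index=[fs.name for fs in feature_sets],
        columns=[labels[j] for j in order],
    )
    return InteractionMap(
        matrix=matrix, summary=pd.DataFrame(summaries), column_order=order
    )


def expression_quartile_summary(
    dmrs: list,
    host_features: FeatureSet,
    genes: FeatureSet,
    fpkm: pd.DataFrame,
) -> pd.DataFrame:
    """Mean DMR-in-host-feature count per gene, by expression bin.

    Genes with FPKM 0 form bin U; expressed genes are split into FPKM
    quartiles Q1 (highest) to Q4 (lowest).  Per gene, the statistic is
    the number of DMRs overlapping a host feature (e.g. an enhancer) that
    itself overlaps the gene body.  ``fpkm`` needs columns ``gene_id``
    and ``fpkm``; genes absent from it are excluded.
    """
    if not {"gene_id", "fpkm"}.issubset(fpkm.columns):
        raise ValueError("fpkm table needs gene_id and fpkm columns")
    expr = fpkm.set_index("gene_id")["fpkm"]
    host = _MergedIntervals(host_features.intervals())
    dmr_spans = [(d.chrom, d.start, d.end) for d in dmrs]

    host_df = host_features.data
    gene_rows = []
    for g in genes.data.itertuples(index=False):
        gid = g.label
        if gid not in expr.index:
            continue
        in_gene = host_df[
            (host_df["chrom"] == g.chrom)
            & (host_df["start"] < g.end)
            & (host_df["end"] > g.start)
        ]
        if in_gene.empty:
            count = 0
        else:
            sub = _MergedIntervals(
                [(r.chrom, r.start, r.end) for r in in_gene.itertuples(index=False)]
            )
            count = sum(
                int(sub.count_hits(c, np.array([s]), np.array([e]))[0])
                for c, s, e in dmr_spans
                if c == g.chrom
            )
        gene_rows.append({"gene_id": gid, "fpkm": float(expr[gid]), "count": count})
    df = pd.DataFrame(gene_rows)
    if df.empty:
        return pd.DataFrame(columns=["bin", "mean_count", "n_genes"])
    df["bin"] = "U"
    expressed = df["fpkm"] > 0
    if expressed.sum() >= 4:
        ranks = df.loc[expressed, "fpkm"].rank(method="first")
        qbin = pd.qcut(ranks, 4, labels=["Q4", "Q3", "Q2", "Q1"])
        df.loc[expressed, "bin"] = qbin.astype(str)
    elif expressed.any():
        df.loc[expressed, "bin"] = "Q1"
    out = (
        df.groupby("bin")["count"]
        .agg(mean_count="mean", n_genes="size")
        .reindex(["Q1", "Q2", "Q3", "Q4", "U"])
        .dropna(how="all")
        .reset_index()
    )
    return out
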
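"""Dyad collapsing and descriptive methylation summaries.

Region-level methylation follows the unweighted convention: the mean of
per-dyad percent methylation over covered dyads, giving every CpG equal
weight regardless of its read depth.  The pooled-count ratio is available
where noted.  Heatmap scaling and sample PCA follow the usual composite
conventions (column Z-scores with the n-1 standard deviation, centred PCA
on the samples x CpG percent matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from dmrscan.meth_io import FeatureSet, MethCallTable

__all__ = [
    "collapse_dyads",
    "global_methylation",
    "region_mean_methylation",
    "RegionMethylationSummary",
    "heatmap_matrix",
    "pca_samples",
]


def collapse_dyads(table: MethCallTable) -> MethCallTable:
    """Collapse strand-resolved CpG calls onto their dyad locus.

    A minus-strand call at position p reports the same dyad as the
    plus-strand call at p - 1; collapsing sums the methylated and
    unmethylated counts of the two strands and anchors the record at the
    plus-strand C.  Orphan single-strand calls are kept as collapsed
    records (minus-strand orphans are shifted to the anchor).  Tables that
    are already fully collapsed pass through unchanged.
    """
    df = table.data
    if (df["strand"] == "collapsed").all():
        return table
    plus = df[df["strand"] == "+"]
    if plus.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate plus-strand records at the same position")
    minus = df[df["strand"] == "-"].copy()
    if minus.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate minus-strand records at the same position")
    minus["pos"] = minus["pos"] - 1
    already = df[df["strand"] == "collapsed"]
    merged = (
        pd.concat([plus, minus, already], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_unmeth"]]
        .sum()
    )
    merged.insert(2, "strand", "collapsed")
    return MethCallTable(sample_id=table.sample_id, data=merged, cohort=table.cohort)


def global_methylation(table: MethCallTable) -> float:
    """Genome-wide percent methylation: 100 * sum(meth) / sum(coverage)."""
    n_meth = int(table.data["n_meth"].sum())
    total = n_meth + int(table.data["n_unmeth"].sum())
    if total == 0:
        raise ValueError("zero total coverage")
    return 100.0 * n_meth / total


def region_dyad_slices(
    table: MethCallTable, regions: FeatureSet
) -> list[np.ndarray]:
    """Indices of the table's dyads falling inside each region (half-open)."""
    df = table.data
    out: list[np.ndarray] = []
    pos_by_chrom = {
        chrom: (grp["pos"].to_numpy(), grp.index.to_numpy())
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    for row in regions.data.itertuples(index=False):
        entry = pos_by_chrom.get(row.chrom)
        if entry is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        pos, idx = entry
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        out.append(idx[lo:hi])
    return out


@dataclass
class RegionMethylationSummary:
    """Per-region mean percent methylation for one sample.

    ``per_region`` has one row per input region with columns chrom, start,
    end, mean_pct (NaN where the region holds no covered dyad), and
    n_covered.  ``aggregate_pct`` is the unweighted mean of per-dyad
    percentages pooled over every covered dyad in any region; NaN when no
    region is covered.
    """

    sample_id: str
    per_region: pd.DataFrame
    aggregate_pct: float
    pooled_ratio_pct: float


def region_mean_methylation(
    table: MethCallTable, regions: FeatureSet
) -> RegionMethylationSummary:
    """Mean percent methylation per region (unweighted over covered dyads)."""
    pct = table.percent_methylation().to_numpy()
    meth = table.data["n_meth"].to_numpy()
    unmeth = table.data["n_unmeth"].to_numpy()
    rows = []
    all_idx: list[np.ndarray] = []
    for (row, idx) in zip(regions.data.itertuples(index=False),
                          region_dyad_slices(table, regions)):
        vals = pct[idx]
        vals = vals[~np.isnan(vals)]
        covered_idx = idx[~np.isnan(pct[idx])]
        all_idx.append(covered_idx)
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "mean_pct": float(vals.mean()) if vals.size else np.nan,
                "n_covered": int(vals.size),
            }
        )
    per_region = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean_pct", "n_covered"]
    )
    pooled = np.concatenate(all_idx) if all_idx else np.empty(0, dtype=np.int64)
    if pooled.size:
        aggregate = float(pct[pooled].mean())
        tot = meth[pooled].sum() + unmeth[pooled].sum()
        pooled_ratio = float(100.0 * meth[pooled].sum() / tot)
    else:
        aggregate = np.nan
        pooled_ratio = np.nan
    return RegionMethylationSummary(
        sample_id=table.sample_id,
        per_region=per_region,
        aggregate_pct=aggregate,
        pooled_ratio_pct=pooled_ratio,
    )


def heatmap_matrix(
    samples: list[MethCallTable],
    regions: FeatureSet,
    scale: str = "column_z",
) -> pd.DataFrame:
    """Samples x regions matrix of region mean methylation.

    ``scale='column_z'`` standardises each region column to mean 0, sd 1
    (ddof = 1); zero-variance columns become all zeros.  Regions with no
    covered dyad in at least one sample are dropped.
    """
    if len(samples) < 2:
        raise ValueError("need >=2 samples for a heatmap matrix")
    if scale not in ("column_z", "row_z", "none"):
        raise ValueError(f"unknown scale {scale!r}")
    cols = [
        f"{r.chrom}:{r.start}-{r.end}" for r in regions.data.itertuples(index=False)
    ]
    mat = pd.DataFrame(
        [
            region_mean_methylation(s, regions).per_region["mean_pct"].to_numpy()
            for s in samples
        ],
        index=[s.sample_id for s in samples],
        columns=cols,
    )
    dropped = mat.columns[mat.isna().any(axis=0)]
    if len(dropped):
        mat = mat.drop(columns=dropped)
    if scale == "none":
        return mat
    axis = 0 if scale == "column_z" else 1
    mean = mat.mean(axis=axis)
    sd = mat.std(axis=axis, ddof=1)
    z = mat.sub(mean, axis=1 - axis).div(sd.replace(0.0, np.nan), axis=1 - axis)
    return z.fillna(0.0)


def pca_samples(
    samples: list[MethCallTable], min_cov: int = 1
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA of per-sample CpG percent methylation.

    Only dyads covered at >= ``min_cov`` reads in every sample enter the
    matrix.  Returns (coordinates indexed by sample_id, per-component
    proportion of variance).
    """
    if len(samples) < 3:
        raise ValueError("need >=3 samples for PCA")
    keyed = []
    for s in samples:
        df = s.data
        cov = df["n_meth"] + df["n_unmeth"]
        sub = df[cov >= max(min_cov, 1)]
        pct = 100.0 * sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])
        keyed.append(
            pd.Series(pct.to_numpy(),
                      index=pd.MultiIndex.from_frame(sub[["chrom", "pos"]]))
        )
    common = keyed[0].index
    for s in keyed[1:]:
        common = common.intersection(s.index)
    if len(common) == 0:
        raise ValueError("no dyads pass the coverage filter in every sample")
    x = np.vstack([s.loc[common].to_numpy() for s in keyed])
    n_comp = min(len(samples), len(common))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(x)
    coord_df = pd.DataFrame(
        coords,
        index=[s.sample_id for s in samples],
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coord_df, pca.explained_variance_ratio_
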
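"""Kernel-smoothed methylation traces and composite (metaregion) profiles.

Locus traces are Nadaraya-Watson estimates with a Gaussian kernel over
per-dyad percent methylation, weighted by dyad coverage, evaluated on a
fixed genomic grid spanning the region plus flanks.  Composite profiles
rescale every region to a common number of body bins (flanks binned at a
fixed width) and average per-dyad percentages, unweighted, pooled across
regions and replicates — the same equal-weight-per-CpG convention the
region summaries use.  Profiles are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dmrscan.meth_io import FeatureSet, MethCallTable

__all__ = ["Profile", "kernel_smooth_profile", "composite_profile"]


@dataclass
class Profile:
    """A smoothed or binned methylation curve.

    ``grid`` holds genomic positions (locus mode) or bin indices
    (composite mode, body bins 0..n_bins-1, flank bins negative /
    >= n_bins); ``values`` holds percent methylation, NaN where no data
    supports the estimate.
    """

    grid: np.ndarray
    values: np.ndarray
    kind: str = "locus"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "value": self.values})


def kernel_smooth_profile(
    table: MethCallTable,
    region: tuple[str, int, int],
    flank: int = 5000,
    bandwidth: float = 100.0,
    grid_step: int = 50,
) -> Profile:
    """Gaussian-kernel smoothed percent methylation around a region.

    The estimate at grid point g is the coverage-weighted kernel mean of
    per-dyad percentages; grid points with no dyad within three
    bandwidths are left undefined (NaN).  The grid spans the region plus
    ``flank`` on each side in steps of ``grid_step``.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    chrom, start, end = region
    if start >= end:
        raise ValueError("region start must be < end")
    df = table.data[table.data["chrom"] == chrom]
    cov = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    pos = df["pos"].to_numpy()
    lo = max(0, start - flank)
    hi = end + flank
    in_span = (pos >= lo) & (pos < hi) & (cov > 0)
    if not in_span.any():
        raise ValueError("no covered dyads in the profiled span")
    pos = pos[in_span]
    cov = cov[in_span].astype(float)
    pct = 100.0 * df["n_meth"].to_numpy()[in_span] / cov
    grid = np.arange(lo, hi + 1, grid_step, dtype=np.int64)
    d = (grid[:, None] - pos[None, :]) / bandwidth
    w = np.exp(-0.5 * d * d) * cov[None, :]
    w[np.abs(d) > 3.0] = 0.0
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (w * pct[None, :]).sum(axis=1) / wsum
    values[wsum == 0] = np.nan
    return Profile(grid=grid, values=values, kind="locus")


def composite_profile(
    cohort,
    regions: FeatureSet,
    n_bins: int = 20,
    flank: int = 2000,
    flank_bin_size: int | None = None,
) -> Profile:
    """Composite methylation profile over a set of regions.

    Each region body is rescaled to ``n_bins`` bins; flanks are binned at
    ``flank_bin_size`` base pairs (default flank / 5).  Bin values are
    unweighted means of per-dyad percent methylation pooled across all
    regions and all cohort replicates.  ``cohort`` may be a Cohort or a
    single MethCallTable.
    """
    replicates = getattr(cohort, "replicates", None) or [cohort]
    if len(regions) == 0:
        raise ValueError("no regions given")
    if flank_bin_size is None:
        flank_bin_size = max(1, flank // 5)
    n_flank = flank // flank_bin_size if flank > 0 else 0
    sums = np.zeros(n_bins + 2 * n_flank)
    counts = np.zeros_like(sums)
    any_cov = False
    for rep in replicates:
        df = rep.data
        cov_all = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        pct_all = np.where(cov_all > 0, 100.0 * df["n_meth"].to_numpy()
                           / np.maximum(cov_all, 1), np.nan)
        pos_by_chrom = {
            chrom: (grp["pos"].to_numpy(), grp.index.to_numpy())
            for chrom, grp in df.groupby("chrom", sort=False)
        }
        for r in regions.data.itertuples(index=False):
            entry = pos_by_chrom.get(r.chrom)
            if entry is None:
                continue
            pos, idx = entry
            lo = np.searchsorted(pos, r.start - flank, side="left")
            hi = np.searchsorted(pos, r.end + flank, side="left")
            if hi == lo:
                continue
            p = pos[lo:hi]
            v = pct_all[idx[lo:hi]]
            ok = ~np.isnan(v)
            if not ok.any():
                continue
            any_cov = True
            p, v = p[ok], v[ok]
            body = (p >= r.start) & (p < r.end)
            left = p < r.start
            right = p >= r.end
            bins = np.empty(p.shape, dtype=np.int64)
            width = r.end - r.start
            bins[body] = n_flank + np.minimum(
                ((p[body] - r.start) * n_bins) // width, n_bins - 1
            )
            bins[left] = (p[left] - (r.start - flank)) // flank_bin_size
            bins[right] = (
                n_flank + n_bins + (p[right] - r.end) // flank_bin_size
            )
            np.add.at(sums, bins, v)
            np.add.at(counts, bins, 1.0)
    if not any_cov:
        raise ValueError("all regions uncovered")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts
    values[counts == 0] = np.nan
    grid = np.arange(-n_flank, n_bins + n_flank)
    return Profile(grid=grid, values=values, kind="composite")
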
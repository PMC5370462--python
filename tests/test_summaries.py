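import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrscan.meth_io import FeatureSet
from dmrscan.summaries import (
    collapse_dyads,
    global_methylation,
    heatmap_matrix,
    pca_samples,
    region_mean_methylation,
)

from conftest import make_table


class TestCollapseDyads:
    def test_pairs_sum_counts(self, strand_table):
        c = collapse_dyads(strand_table)
        rec = c.data[c.data["pos"] == 100].iloc[0]
        assert (rec["n_meth"], rec["n_unmeth"]) == (7, 7)

    def test_orphan_plus_kept(self, strand_table):
        c = collapse_dyads(strand_table)
        rec = c.data[c.data["pos"] == 200].iloc[0]
        assert (rec["n_meth"], rec["n_unmeth"]) == (1, 1)

    def test_orphan_minus_anchor_shift(self, strand_table):
        c = collapse_dyads(strand_table)
        rec = c.data[c.data["pos"] == 300].iloc[0]
        assert (rec["n_meth"], rec["n_unmeth"]) == (2, 4)

    def test_duplicate_plus_records_error(self):
        t = make_table([("chr1", 100, "+", 1, 1), ("chr1", 100, "+", 2, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            collapse_dyads(t)

    def test_collapsed_passthrough(self):
        t = make_table([("chr1", 100, "collapsed", 1, 1)])
        assert collapse_dyads(t) is t

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 50), st.sampled_from(["+", "-"]),
                st.integers(0, 9), st.integers(0, 9),
            ),
            min_size=1, max_size=30,
            unique_by=lambda r: (r[0], r[1]),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_conserves_total_reads(self, recs):
        t = make_table([("chr1", pos, strand, m, u) for pos, strand, m, u in recs])
        c = collapse_dyads(t)
        assert (
            c.data[["n_meth", "n_unmeth"]].to_numpy().sum()
            == t.data[["n_meth", "n_unmeth"]].to_numpy().sum()
        )
        assert not c.data.duplicated(["chrom", "pos"]).any()


class TestGlobalMethylation:
    def test_simple_ratio(self):
        t = make_table(
            [("chr1", 10, "collapsed", 7, 7), ("chr1", 20, "collapsed", 3, 3)]
        )
        assert global_methylation(t) == 50.0

    def test_all_unmethylated(self):
        t = make_table([("chr1", 10, "collapsed", 0, 5)])
        assert global_methylation(t) == 0.0

    def test_zero_coverage_errors(self):
        t = make_table([("chr1", 10, "collapsed", 0, 0)])
        with pytest.raises(ValueError):
            global_methylation(t)

    def test_merged_between_inputs(self):
        a = make_table([("chr1", 10, "collapsed", 9, 1)])
        b = make_table([("chr1", 20, "collapsed", 1, 9)])
        merged = make_table(
            [("chr1", 10, "collapsed", 9, 1), ("chr1", 20, "collapsed", 1, 9)]
        )
        lo, hi = sorted([global_methylation(a), global_methylation(b)])
        assert lo <= global_methylation(merged) <= hi


class TestRegionMeanMethylation:
    def test_unweighted_mean(self):
        # 40% at coverage 10, 60% at coverage 100: unweighted mean is 50
        t = make_table(
            [("chr1", 10, "collapsed", 4, 6), ("chr1", 20, "collapsed", 60, 40)]
        )
        fs = FeatureSet.from_intervals("r", [("chr1", 0, 100)])
        s = region_mean_methylation(t, fs)
        assert s.per_region["mean_pct"].iloc[0] == pytest.approx(50.0)
        assert s.per_region["n_covered"].iloc[0] == 2

    def test_uncovered_region_flagged(self):
        t = make_table([("chr1", 10, "collapsed", 4, 6)])
        fs = FeatureSet.from_intervals("r", [("chr1", 500, 600), ("chr1", 0, 100)])
        s = region_mean_methylation(t, fs)
        uncovered = s.per_region[s.per_region["start"] == 500]
        assert np.isnan(uncovered["mean_pct"].iloc[0])
        assert s.aggregate_pct == pytest.approx(40.0)  # excluded from aggregate

    def test_split_region_invariance(self):
        rng = np.random.default_rng(3)
        recs = [("chr1", int(p), "collapsed", int(m), int(u))
                for p, m, u in zip(rng.choice(1000, 50, replace=False),
                                   rng.integers(0, 9, 50),
                                   rng.integers(1, 9, 50))]
        t = make_table(recs)
        whole = FeatureSet.from_intervals("w", [("chr1", 0, 1000)])
        halves = FeatureSet.from_intervals(
            "h", [("chr1", 0, 500), ("chr1", 500, 1000)]
        )
        sw = region_mean_methylation(t, whole)
        sh = region_mean_methylation(t, halves)
        # pooled covered-dyad aggregate identical under the split
        assert sw.aggregate_pct == pytest.approx(sh.aggregate_pct)
        assert (
            sw.per_region["n_covered"].sum() == sh.per_region["n_covered"].sum()
        )


class TestHeatmapMatrix:
    def _samples(self):
        a = make_table([("chr1", 10, "collapsed", 4, 6)], sample_id="a")
        b = make_table([("chr1", 10, "collapsed", 6, 4)], sample_id="b")
        return [a, b]

    def test_column_z(self):
        fs = FeatureSet.from_intervals("r", [("chr1", 0, 100)])
        z = heatmap_matrix(self._samples(), fs, scale="column_z")
        assert z.iloc[:, 0].to_numpy() == pytest.approx(
            [-0.7071067811865476, 0.7071067811865476]
        )

    def test_constant_column_zeros(self):
        a = make_table([("chr1", 10, "collapsed", 1, 1)], sample_id="a")
        b = make_table([("chr1", 10, "collapsed", 2, 2)], sample_id="b")
        fs = FeatureSet.from_intervals("r", [("chr1", 0, 100)])
        z = heatmap_matrix([a, b], fs)
        assert (z.to_numpy() == 0).all()

    def test_scale_none_raw(self):
        fs = FeatureSet.from_intervals("r", [("chr1", 0, 100)])
        raw = heatmap_matrix(self._samples(), fs, scale="none")
        assert raw.iloc[:, 0].to_numpy() == pytest.approx([40.0, 60.0])

    def test_uncovered_column_dropped(self):
        fs = FeatureSet.from_intervals(
            "r", [("chr1", 0, 100), ("chr1", 900, 950)]
        )
        z = heatmap_matrix(self._samples(), fs)
        assert z.shape[1] == 1


class TestPcaSamples:
    def test_variance_fractions_valid(self, small_sim):
        _, young, old = small_sim
        samples = young.replicates[:2] + old.replicates[:2]
        coords, var = pca_samples(samples, min_cov=1)
        assert var.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(var) <= 1e-12)

    def test_duplicate_sample_identical_coords(self, small_sim):
        _, young, _ = small_sim
        r = young.replicates[0]
        coords, _ = pca_samples([r, r, young.replicates[1]], min_cov=1)
        assert np.allclose(
            coords.iloc[0].to_numpy(), coords.iloc[1].to_numpy(), atol=1e-8
        )

    def test_cohorts_separate_on_pc1(self, small_sim):
        """Planted mean shifts put young and old on opposite PC1 sides."""
        _, young, old = small_sim
        samples = young.replicates + old.replicates
        coords, _ = pca_samples(samples, min_cov=1)
        pc1 = coords["PC1"].to_numpy()
        y, o = pc1[:4], pc1[4:]
        # silhouette > 0 on PC1: groups are on distinct sides
        assert max(y.min(), o.min()) > min(y.max(), o.max()) or (
            (y.mean() - o.mean()) ** 2
            > max(y.var(ddof=1), o.var(ddof=1))
        )

    def test_no_common_dyads_errors(self):
        a = make_table([("chr1", 10, "collapsed", 1, 1)], sample_id="a")
        b = make_table([("chr1", 20, "collapsed", 1, 1)], sample_id="b")
        c = make_table([("chr1", 30, "collapsed", 1, 1)], sample_id="c")
        with pytest.raises(ValueError):
            pca_samples([a, b, c])
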
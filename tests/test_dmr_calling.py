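import numpy as np
import pytest

from dmrscan.dmr_calling import (
    DMR,
    Cohort,
    PipelineConfig,
    call_dms_cpgs,
    call_dmrs,
    intersect_dmr_sets,
    split_by_direction,
    suppression_analysis,
)
from dmrscan.stats_core import fisher_two_tailed

from conftest import make_table


def cohort_from_counts(name, positions, per_replicate_counts):
    """per_replicate_counts: list (per replicate) of (n_meth, n_unmeth) lists."""
    reps = []
    for i, counts in enumerate(per_replicate_counts):
        recs = [
            ("chr1", pos, "collapsed", m, u)
            for pos, (m, u) in zip(positions, counts)
        ]
        reps.append(make_table(recs, sample_id=f"{name}_rep{i}", cohort=name))
    return Cohort(name=name, replicates=reps)


class TestCallDmsCpgs:
    def test_extreme_dyad_reported_hypo(self):
        pos = [100]
        a = cohort_from_counts("A", pos, [[(5, 0)]] * 4)  # pooled (20, 0)
        b = cohort_from_counts("B", pos, [[(0, 5)]] * 4)  # pooled (0, 20)
        res = call_dms_cpgs(a, b, PipelineConfig())
        assert len(res) == 1
        r = res[0]
        assert r.direction == "hypo"
        assert r.fet_p == pytest.approx(fisher_two_tailed((20, 0, 0, 20)))
        assert r.fet_q <= r.fet_p + 1e-15

    def test_low_coverage_dyad_not_tested(self):
        pos = [100]
        a = cohort_from_counts("A", pos, [[(2, 0)]] * 4)  # pooled coverage 8
        b = cohort_from_counts("B", pos, [[(0, 5)]] * 4)
        assert call_dms_cpgs(a, b, PipelineConfig(min_cov_per_cpg=10)) == []

    def test_identical_cohorts_nothing_called(self):
        rng = np.random.default_rng(0)
        pos = sorted(rng.choice(10_000, 200, replace=False).tolist())
        counts = [[(int(m), int(u)) for m, u in
                   zip(rng.integers(0, 8, 200), rng.integers(1, 8, 200))]
                  for _ in range(4)]
        a = cohort_from_counts("A", pos, counts)
        b = cohort_from_counts("B", pos, counts)
        assert call_dms_cpgs(a, b, PipelineConfig()) == []


class TestCallDmrs:
    def test_planted_window_called_hypo(self):
        """0.7 vs 0.3 over 10 dyads, coverage ~7, 4v4 -> called hypo."""
        rng = np.random.default_rng(5)
        pos = list(range(1000, 1500, 50))
        young = [[(int(m), int(c - m)) for c, m in
                  [(c, rng.binomial(c, 0.7)) for c in rng.poisson(7, 10)]]
                 for _ in range(4)]
        old = [[(int(m), int(c - m)) for c, m in
                [(c, rng.binomial(c, 0.3)) for c in rng.poisson(7, 10)]]
               for _ in range(4)]
        a = cohort_from_counts("young", pos, young)
        b = cohort_from_counts("old", pos, old)
        dmrs = call_dmrs(a, b, PipelineConfig())
        assert len(dmrs) >= 1
        assert all(d.direction == "hypo" for d in dmrs)
        assert any(d.start <= 1000 and d.end >= 1450 for d in dmrs)

    def test_heterogeneous_window_excluded(self):
        """Old replicates split 0.9/0.9/0.1/0.1 are heterogeneity-filtered."""
        pos = list(range(1000, 1500, 50))
        young = [[(12, 5)] * 10] * 4  # ~0.7 homogeneous
        old = [[(63, 7)] * 10, [(63, 7)] * 10, [(7, 63)] * 10, [(7, 63)] * 10]
        a = cohort_from_counts("young", pos, young)
        b = cohort_from_counts("old", pos, old)
        stats = {}
        dmrs = call_dmrs(a, b, PipelineConfig(), stats=stats)
        assert dmrs == []
        assert stats["n_removed_heterogeneity"] >= 1

    def test_direction_swap_flips_and_preserves_p(self):
        rng = np.random.default_rng(6)
        pos = list(range(0, 2000, 40))
        mk = lambda p: [
            [(int(m), int(c - m)) for c, m in
             [(c, rng.binomial(c, p)) for c in rng.poisson(7, len(pos))]]
            for _ in range(4)
        ]
        a = cohort_from_counts("A", pos, mk(0.7))
        b = cohort_from_counts("B", pos, mk(0.3))
        fwd = call_dmrs(a, b, PipelineConfig())
        rev = call_dmrs(b, a, PipelineConfig())
        assert len(fwd) == len(rev) and len(fwd) >= 1
        for f, r in zip(fwd, rev):
            assert f.span == r.span
            assert {f.direction, r.direction} == {"hyper", "hypo"}
            assert f.fet_p == pytest.approx(r.fet_p, rel=1e-12)
            assert f.delta_pct == pytest.approx(-r.delta_pct, rel=1e-12)

    def test_reported_dmrs_satisfy_invariants(self, small_sim):
        _, young, old = small_sim
        cfg = PipelineConfig()
        for d in call_dmrs(young, old, cfg):
            assert (d.delta_pct > 0) == (d.direction == "hyper")
            assert d.fet_q < cfg.fdr_alpha
            assert d.het_q_a >= cfg.het_alpha and d.het_q_b >= cfg.het_alpha
            assert d.start < d.end and d.n_cpgs >= cfg.min_cpgs_per_window

    def test_disjoint_tiling_merge_is_identity(self, small_sim):
        _, young, old = small_sim
        cfg = PipelineConfig(window_step=500)
        merged = call_dmrs(young, old, cfg, merge=True)
        raw = call_dmrs(young, old, cfg, merge=False)
        assert [d.span for d in merged] == [d.span for d in raw]

    def test_deterministic(self, small_sim):
        _, young, old = small_sim
        d1 = call_dmrs(young, old, PipelineConfig())
        d2 = call_dmrs(young, old, PipelineConfig())
        assert [(d.span, d.fet_p, d.delta_pct) for d in d1] == [
            (d.span, d.fet_p, d.delta_pct) for d in d2
        ]

    def test_no_testable_windows_warns_empty(self):
        a = cohort_from_counts("A", [100], [[(3, 3)]] * 4)
        b = cohort_from_counts("B", [100], [[(3, 3)]] * 4)
        stats = {}
        assert call_dmrs(a, b, PipelineConfig(), stats=stats) == []
        assert stats["n_windows_tested"] == 0


def _dmr(chrom="chr1", start=0, end=500, direction="hypo", delta=-20.0):
    return DMR(
        chrom=chrom, start=start, end=end, direction=direction, n_cpgs=5,
        meth_a=50, unmeth_a=50, meth_b=30, unmeth_b=70, delta_pct=delta,
        fet_p=1e-6, fet_q=1e-4, het_q_a=0.5, het_q_b=0.5,
    )


class TestSplitByDirection:
    def test_partition(self):
        hyper, hypo = split_by_direction(
            [_dmr(delta=5.0, direction="hyper"), _dmr(start=1000, end=1500)]
        )
        assert len(hyper) == 1 and len(hypo) == 1

    def test_empty(self):
        assert split_by_direction([]) == ([], [])

    def test_zero_delta_errors(self):
        with pytest.raises(ValueError, match="zero delta"):
            split_by_direction([_dmr(delta=0.0)])


class TestIntersectDmrSets:
    def test_identical_lists_all_shared(self):
        x = [_dmr(), _dmr(start=1000, end=1500)]
        res = intersect_dmr_sets(x, list(x))
        assert res.n_shared_x == 2 and not res.x_only

    def test_disjoint_lists(self):
        res = intersect_dmr_sets([_dmr()], [_dmr(start=5000, end=5500)])
        assert res.n_shared_x == 0 and len(res.x_only) == 1
        assert res.bp_overlap == 0

    def test_one_bp_overlap_counts(self):
        res = intersect_dmr_sets(
            [_dmr(start=0, end=500)], [_dmr(start=499, end=999)]
        )
        assert res.n_shared_x == 1 and res.bp_overlap == 1

    def test_different_chromosomes_disjoint(self):
        res = intersect_dmr_sets([_dmr()], [_dmr(chrom="chr2")])
        assert res.n_shared_x == 0


class TestSuppressionAnalysis:
    def test_direction_reversal_is_suppression(self):
        aging = [_dmr(direction="hypo", delta=-20)]
        treat = [_dmr(direction="hyper", delta=15)]
        res = suppression_analysis(aging, treat)
        assert len(res.suppressed) == 1
        assert res.suppressed_fraction == 1.0

    def test_same_direction_not_suppression(self):
        aging = [_dmr(direction="hypo", delta=-20)]
        treat = [_dmr(direction="hypo", delta=-15)]
        res = suppression_analysis(aging, treat)
        assert res.suppressed == [] and len(res.not_suppressed) == 1

    def test_hyper_aging_needs_hypo_treatment(self):
        aging = [_dmr(direction="hyper", delta=20)]
        assert suppression_analysis(
            aging, [_dmr(direction="hypo", delta=-9)]
        ).suppressed == aging

    def test_non_age_related_listed(self):
        aging = [_dmr(start=0, end=500, direction="hypo")]
        treat = [_dmr(start=9000, end=9500, direction="hyper", delta=9)]
        res = suppression_analysis(aging, treat)
        assert res.non_age_related == treat
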
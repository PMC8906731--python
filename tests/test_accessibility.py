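"""Consensus ATAC peaks, rank shifts, and leading-edge enrichment."""

import numpy as np
import pytest

from cistromix.annotation import GeneModel
from cistromix.accessibility import (
    atac_rank_metric,
    enrichment_score,
    enrichment_permutation_pvalue,
    merge_consensus,
    promoter_atac_signal,
    rank_peaks,
)
from cistromix.core import GenomicInterval, Peak, SignalTrack


def mk_peak(start, end, auc=1.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), auc=auc)


class TestMergeConsensus:
    def test_overlap_unioned(self):
        out = merge_consensus([mk_peak(100, 200)], [mk_peak(150, 250)])
        assert [(c.interval.start, c.interval.end) for c in out] == [(100, 250)]

    def test_disjoint_pass_through(self):
        out = merge_consensus([mk_peak(100, 200)], [mk_peak(300, 400)])
        assert [(c.interval.start, c.interval.end) for c in out] == [(100, 200), (300, 400)]

    def test_chained_overlaps_collapse(self):
        out = merge_consensus(
            [mk_peak(0, 100), mk_peak(150, 260)], [mk_peak(90, 160), mk_peak(400, 500)]
        )
        assert [(c.interval.start, c.interval.end) for c in out] == [(0, 260), (400, 500)]

    def test_adjacent_intervals_not_merged(self):
        out = merge_consensus([mk_peak(0, 100)], [mk_peak(100, 200)])
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_disjoint_and_covering(self, seed):
        rng = np.random.default_rng(seed)
        peaks_a = [mk_peak(int(s), int(s) + int(rng.integers(10, 200))) for s in rng.integers(0, 5000, 30)]
        peaks_b = [mk_peak(int(s), int(s) + int(rng.integers(10, 200))) for s in rng.integers(0, 5000, 30)]
        out = merge_consensus(peaks_a, peaks_b)
        spans = [(c.interval.start, c.interval.end) for c in out]
        assert spans == sorted(spans)
        assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))  # pairwise disjoint
        covered = np.zeros(6000, dtype=bool)
        for s, e in spans:
            covered[s:e] = True
        expected = np.zeros(6000, dtype=bool)
        for p in peaks_a + peaks_b:
            expected[p.interval.start : p.interval.end] = True
        assert np.array_equal(covered, expected)

    def test_track_based_auc_recomputation(self):
        track_c = SignalTrack(data={"chr1": np.full(1000, 2.0)})
        track_k = SignalTrack(data={"chr1": np.full(1000, 1.0)})
        out = merge_consensus(
            [mk_peak(100, 200)], [mk_peak(150, 250)],
            tracks_control=[track_c], tracks_ko=[track_k],
        )
        assert out[0].mean_auc_control == pytest.approx(300.0)
        assert out[0].mean_auc_ko == pytest.approx(150.0)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_consensus([], [])


class TestRankPeaks:
    def test_ascending_ranks(self):
        cons = merge_consensus(
            [mk_peak(0, 100, 5), mk_peak(200, 300, 2), mk_peak(400, 500, 9)], []
        )
        rank_peaks(cons)
        assert [c.rank_control for c in cons] == [2, 1, 3]

    def test_identical_conditions_equal_ranks(self):
        rng = np.random.default_rng(0)
        peaks = [mk_peak(int(s) * 300, int(s) * 300 + 200, float(a))
                 for s, a in zip(range(20), rng.uniform(1, 100, 20))]
        cons = merge_consensus(peaks, [Peak(p.interval, auc=p.auc) for p in peaks])
        rank_peaks(cons)
        assert all(c.rank_control == c.rank_ko for c in cons)
        assert sorted(c.rank_control for c in cons) == list(range(1, 21))

    def test_planted_ko_loss_drops_bound_ranks(self, small_bundle):
        bundle, truth = small_bundle
        cons = merge_consensus(
            bundle.atac_peaks[("control", 1)],
            bundle.atac_peaks[("ko", 1)],
            tracks_control=bundle.atac_tracks["control"],
            tracks_ko=bundle.atac_tracks["ko"],
        )
        rank_peaks(cons)
        bound_names = set(truth.atac.loc[truth.atac["bound_tf_a"], "name"])
        by_span = {
            (t.chrom, t.summit): t.name
            for t in bundle.atac_peaks[("control", 1)]
        }
        drops_bound = []
        for c in cons:
            name = by_span.get((c.interval.chrom, c.summit))
            if name in bound_names:
                drops_bound.append(c.rank_control - c.rank_ko)
        assert len(drops_bound) > 50
        assert np.median(drops_bound) > 0


class TestPromoterAtacSignal:
    def test_single_peak_in_window(self):
        gene = GeneModel("g", "chr1", "+", 10_000)
        cons = merge_consensus([mk_peak(9_800, 10_200, 8.0)], [])
        cons[0].mean_auc_control, cons[0].mean_auc_ko = 8.0, 3.0
        assert promoter_atac_signal(gene, cons) == (8.0, 3.0)

    def test_no_peaks(self):
        assert promoter_atac_signal(GeneModel("g", "chr1", "+", 0), []) == (0.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [GeneModel(f"g{i}", "chr1", "+", int(t)) for i, t in enumerate(rng.integers(0, 100_000, 20))]
        cons = merge_consensus(
            [mk_peak(int(s), int(s) + 300, float(a)) for s, a in
             zip(rng.integers(0, 100_000, 40), rng.uniform(1, 50, 40))], []
        )
        for c in cons:
            c.mean_auc_control = float(rng.uniform(0, 10))
            c.mean_auc_ko = float(rng.uniform(0, 10))
        for g in genes:
            expected_c = sum(
                c.mean_auc_control for c in cons
                if abs(c.summit - g.tss) <= 2000
            )
            expected_k = sum(
                c.mean_auc_ko for c in cons if abs(c.summit - g.tss) <= 2000
            )
            got = promoter_atac_signal(g, cons)
            assert got[0] == pytest.approx(expected_c, abs=1e-9)
            assert got[1] == pytest.approx(expected_k, abs=1e-9)


class TestAtacRankMetric:
    def test_pseudocount_arithmetic(self):
        assert atac_rank_metric(8.0, 2.0) == pytest.approx(np.log2(3))

    def test_symmetry_and_zero(self):
        assert atac_rank_metric(5.0, 5.0) == 0.0
        assert atac_rank_metric(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            atac_rank_metric(-1.0, 2.0)


def oracle_running_sum(genes, query, metric, p):
    """Direct enumeration of the weighted running sum."""
    n, hits = len(genes), [g in query for g in genes]
    nh = sum(hits)
    weights = [abs(m) ** p if h else 0.0 for m, h in zip(metric, hits)]
    total = sum(weights) or float(nh)
    run, out = 0.0, []
    for i in range(n):
        if hits[i]:
            run += (weights[i] / total) if sum(weights) else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        out.append(run)
    return out


class TestEnrichmentScore:
    def test_perfect_concordance(self):
        genes = [f"g{i}" for i in range(20)]
        res = enrichment_score(genes, set(genes[:5]), metric=np.arange(20, 0, -1))
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == set(genes[:5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        metric = rng.normal(0, 1, 20)
        query = set(rng.choice(genes, 6, replace=False))
        for p in (0.0, 1.0):
            res = enrichment_score(genes, query, metric=metric, weight_exponent=p)
            expected = oracle_running_sum(genes, query, metric, p)
            assert res.running_sum == pytest.approx(expected, abs=1e-12)
            k = int(np.argmax(np.abs(expected)))
            assert res.es == pytest.approx(expected[k])

    def test_unweighted_antisymmetry_under_reversal(self):
        genes = [f"g{i}" for i in range(30)]
        query = set(genes[:8])
        fwd = enrichment_score(genes, query, weight_exponent=0)
        rev = enrichment_score(genes[::-1], query, weight_exponent=0)
        assert rev.es == pytest.approx(-fwd.es)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            query = set(rng.choice(genes, int(rng.integers(1, 49)), replace=False))
            res = enrichment_score(genes, query, metric=rng.normal(0, 2, 50))
            assert -1.0 <= res.es <= 1.0
            assert set(res.leading_edge) <= query

    def test_error_cases(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError):
            enrichment_score(genes, set())
        with pytest.raises(ValueError):
            enrichment_score(genes, {"z"})
        with pytest.raises(ValueError):
            enrichment_score(genes, set(genes))

    def test_permutation_pvalue_detects_top_loading(self):
        genes = [f"g{i}" for i in range(60)]
        p = enrichment_permutation_pvalue(
            genes, set(genes[:10]), weight_exponent=0, n_permutations=200, seed=0
        )
        assert p < 0.05
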
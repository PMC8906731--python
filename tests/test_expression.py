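"""Occupancy-expression integration: filtering, FDR, signals, trends, matrices."""

import numpy as np
import pandas as pd
import pytest

from cistromix.annotation import GeneModel
from cistromix.core import GenomicInterval, Peak, SignalTrack
from cistromix.expression import (
    bh_fdr,
    binned_occupancy_trend,
    classify_regulation,
    filter_expressed,
    gene_distal_signal,
    gene_promoter_signal,
    gene_signals,
    log2_fold_change,
    meta_profile,
    occupancy_matrix,
    probe_average_fold_change_ranking,
    signal_by_class_test,
    zscore_matrix,
)
from conftest import random_peak


def naive_bh(p):
    """Textbook O(m^2) step-up: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    return q


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "rpkm,kept",
        [([0.5, 0.9], False), ([0.5, 1.2], True), ([0.0, 0.0], False), ([1.0, 1.0], True)],
    )
    def test_threshold_any_sample(self, rpkm, kept):
        df = pd.DataFrame({"gene_id": ["g"], "control:rep1": [rpkm[0]], "ko:rep1": [rpkm[1]]})
        out = filter_expressed(df, ["control:rep1", "ko:rep1"])
        assert (len(out) == 1) is kept

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(pd.DataFrame(columns=["gene_id", "a"]), ["a"])


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(2, 200)))
        q = bh_fdr(p)
        assert q == pytest.approx(naive_bh(p), abs=1e-12)
        assert np.all(q >= p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (-1.2, 0.01, "down"),
            (1.0, 0.04, "up"),       # fold-change gate is inclusive
            (-1.0, 0.04, "down"),
            (-0.5, 0.001, "ns"),     # fold-change gate fails
            (-2.0, 0.05, "ns"),      # FDR gate is strict
        ],
    )
    def test_threshold_rules(self, lfc, fdr, expected):
        assert classify_regulation(lfc, fdr) == expected

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(0.0, 1.5)


class TestGeneSignals:
    def test_promoter_window_example(self):
        gene = GeneModel("g", "chr1", "+", 10_000)
        a = Peak(GenomicInterval("chr1", 9_300, 9_700), summit=9_500, auc=12, background_auc=2)
        b = Peak(GenomicInterval("chr1", 12_800, 13_200), summit=13_000, auc=50, background_auc=0)
        assert gene_promoter_signal(gene, [a, b]) == pytest.approx(10.0)

    def test_no_peaks_is_zero(self):
        assert gene_promoter_signal(GeneModel("g", "chr1", "+", 0), []) == 0.0

    @pytest.mark.parametrize(
        "summit_offset,expected",
        [(500_000, 6.0), (1_500, 0.0), (1_200_000, 0.0)],
    )
    def test_distal_window_rules(self, summit_offset, expected):
        gene = GeneModel("g", "chr1", "+", 2_000_000)
        summit = 2_000_000 + summit_offset
        peak = Peak(
            GenomicInterval("chr1", summit - 100, summit + 100),
            summit=summit, auc=7, background_auc=1,
        )
        assert gene_distal_signal(gene, [peak]) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_vectorized_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", int(t))
            for i, t in enumerate(rng.integers(0, 2_000_000, 40))
        ]
        peaks = [random_peak(rng, max_pos=2_000_000, name=f"p{i}") for i in range(80)]
        table = gene_signals(genes, peaks, far_limit=500_000).set_index("gene_id")
        for g in genes:
            assert table.loc[g.gene_id, "promoter_signal"] == pytest.approx(
                gene_promoter_signal(g, peaks), abs=1e-9
            )
            assert table.loc[g.gene_id, "distal_signal"] == pytest.approx(
                gene_distal_signal(g, peaks, far_limit=500_000), abs=1e-9
            )


class TestBinnedTrend:
    def test_two_bin_medians(self):
        df = pd.DataFrame(
            {"gene_id": list("abcd"), "signal": [10, 8, 2, 1], "log2fc": [-2, -1.5, 0.1, 0.2]}
        )
        trend = binned_occupancy_trend(df, n_bins=2)
        assert trend["median_log2fc"].tolist() == pytest.approx([-1.75, 0.15])
        assert trend["n_genes"].tolist() == [2, 2]

    def test_single_bin_global_medians(self):
        df = pd.DataFrame({"gene_id": list("abc"), "signal": [3, 2, 1], "log2fc": [1.0, 0.0, -1.0]})
        trend = binned_occupancy_trend(df, n_bins=1)
        assert trend["median_log2fc"].iloc[0] == 0.0

    def test_too_many_bins_rejected(self):
        df = pd.DataFrame({"gene_id": ["a"], "signal": [1], "log2fc": [0]})
        with pytest.raises(ValueError):
            binned_occupancy_trend(df, n_bins=2)

    def test_order_invariance_and_remainder(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(103)],
                "signal": rng.uniform(0, 10, 103),
                "log2fc": rng.normal(0, 1, 103),
            }
        )
        a = binned_occupancy_trend(df, n_bins=10)
        b = binned_occupancy_trend(df.sample(frac=1.0, random_state=1), n_bins=10)
        pd.testing.assert_frame_equal(a, b)
        assert a["n_genes"].tolist() == [11, 11, 11] + [10] * 7
        assert a["n_genes"].sum() == 103


class TestZscoreMatrix:
    def test_unit_spaced_row(self):
        df = pd.DataFrame({"gene_id": ["g"], "s1": [1.0], "s2": [2.0], "s3": [3.0]})
        z = zscore_matrix(df, ["s1", "s2", "s3"], top_k=1)
        assert z.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self, caplog):
        df = pd.DataFrame({"gene_id": ["g"], "s1": [5.0], "s2": [5.0], "s3": [5.0]})
        with caplog.at_level("WARNING"):
            z = zscore_matrix(df, ["s1", "s2", "s3"], top_k=1)
        assert z.loc["g"].tolist() == [0.0, 0.0, 0.0]
        assert "zero-variance" in caplog.text

    def test_probe_average_before_zscore(self):
        probes = pd.DataFrame(
            {"gene_id": ["g", "g"], "s1": [1.0, 3.0], "s2": [2.0, 4.0], "s3": [3.0, 5.0]}
        )
        merged = pd.DataFrame({"gene_id": ["g"], "s1": [2.0], "s2": [3.0], "s3": [4.0]})
        cols = ["s1", "s2", "s3"]
        pd.testing.assert_frame_equal(
            zscore_matrix(probes, cols, top_k=1), zscore_matrix(merged, cols, top_k=1)
        )

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(1, 100, (30, 4)), columns=list("abcd"))
        df.insert(0, "gene_id", [f"g{i}" for i in range(30)])
        z = zscore_matrix(df, list("abcd"), top_k=30)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_needs_two_samples(self):
        df = pd.DataFrame({"gene_id": ["g"], "s1": [1.0]})
        with pytest.raises(ValueError):
            zscore_matrix(df, ["s1"])


class TestFoldChangeRanking:
    def test_most_down_gene_leads(self):
        df = pd.DataFrame(
            {
                "gene_id": ["flat", "down", "up"],
                "c1": [10.0, 40.0, 5.0],
                "c2": [10.0, 40.0, 5.0],
                "k1": [10.0, 2.0, 20.0],
                "k2": [10.0, 2.0, 20.0],
            }
        )
        ranked = probe_average_fold_change_ranking(df, ["c1", "c2"], ["k1", "k2"])
        assert ranked["gene_id"].tolist() == ["down", "flat", "up"]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_log2fc_pseudocount(self):
        assert log2_fold_change([0.0], [0.0])[0] == 0.0


class TestOccupancyMatrix:
    def test_constant_field(self):
        track = SignalTrack(data={"chr1": np.full(40_000, 3.0)})
        mat, _ = occupancy_matrix([("chr1", 20_000)], track, flank=5000, n_cols=10)
        assert np.allclose(mat, 3.0)
        assert np.allclose(meta_profile(mat), 3.0)

    def test_planted_peak_centres_meta_profile(self):
        vec = np.zeros(40_000)
        vec[19_800:20_200] = 5.0
        track = SignalTrack(data={"chr1": vec})
        anchors = [("chr1", 20_000), ("chr1", 20_050)]
        mat, _ = occupancy_matrix(anchors, track, flank=5000, n_cols=21)
        meta = meta_profile(mat)
        assert meta.argmax() == 10  # central column

    def test_sorted_matrix_invariant_to_anchor_order(self):
        rng = np.random.default_rng(0)
        track = SignalTrack(data={"chr1": rng.uniform(0, 2, 100_000)})
        anchors = [("chr1", int(p)) for p in rng.integers(10_000, 90_000, 20)]
        m1, _ = occupancy_matrix(anchors, track, flank=2000, n_cols=10)
        m2, _ = occupancy_matrix(anchors[::-1], track, flank=2000, n_cols=10)
        assert np.allclose(m1, m2)

    def test_offchromosome_anchor_gives_zero_row(self):
        track = SignalTrack(data={"chr1": np.ones(1000)})
        mat, _ = occupancy_matrix([("chr2", 500)], track, flank=100, n_cols=4)
        assert np.allclose(mat, 0.0)


class TestSignalByClass:
    def test_exact_small_sample(self):
        out = signal_by_class_test({"down": [1, 2], "up": [3, 4]}, pairs=[("down", "up")])
        assert out["u_statistic"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(1 / 3)

    def test_identical_groups_null(self):
        x = list(range(50))
        out = signal_by_class_test({"down": x, "ns": x}, pairs=[("down", "ns")])
        assert out["p_value"].iloc[0] > 0.9

    def test_planted_separation_detected(self):
        rng = np.random.default_rng(0)
        out = signal_by_class_test(
            {"down": rng.lognormal(3, 0.5, 500), "up": rng.lognormal(1, 0.5, 500)},
            pairs=[("down", "up")],
        )
        assert out["p_value"].iloc[0] < 1e-6

    def test_empty_group_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = signal_by_class_test({"down": [1.0], "up": []})
        assert ("down", "up") not in list(zip(out.get("group_a", []), out.get("group_b", [])))
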
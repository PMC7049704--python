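"""Site clustering: replicate consensus, spike normalization, 50-nt chaining,
decap-ratio filter, prominence and distal selection."""

import numpy as np
import pandas as pd
import pytest

from leakyscan import clustering as cl


def positions(rows, columns=("chrom", "pos", "strand", "replicate", "count")):
    return pd.DataFrame(rows, columns=list(columns))


class TestReplicateConsensus:
    def test_position_missing_in_one_replicate_dropped(self):
        df = positions([("c", 10, "+", r, c) for r, c in [(1, 3), (2, 0), (3, 5)]])
        assert cl.replicate_consensus(df, 3).empty

    def test_position_in_all_replicates_kept_with_summed_weight(self):
        df = positions([("c", 10, "+", r, 1) for r in (1, 2, 3)])
        out = cl.replicate_consensus(df, 3)
        assert len(out) == 1
        assert out.loc[0, "weight"] == 3

    def test_single_replicate_is_identity(self):
        df = positions([("c", 5, "+", 1, 2), ("c", 9, "-", 1, 4)])
        out = cl.replicate_consensus(df, 1)
        assert len(out) == 2
        assert out["weight"].tolist() == [2, 4]


class TestSpikeNormalize:
    def test_equal_spike_totals_factor_one(self):
        assert cl.spike_normalize(np.array([4.0]), 100, 100)[0] == 4.0

    def test_double_spike_halves_weights(self):
        assert cl.spike_normalize(np.array([4.0]), 200, 100)[0] == 2.0

    def test_equal_signal_at_double_depth_normalizes_equal(self):
        # sample B sequenced 2x deeper: 2x counts, 2x spike total
        a = cl.spike_normalize(np.array([10.0]), 100, 100)
        b = cl.spike_normalize(np.array([20.0]), 200, 100)
        assert a[0] == b[0]

    def test_zero_spike_total_errors(self):
        with pytest.raises(ValueError):
            cl.spike_normalize(np.array([1.0]), 0, 100)


def sites(pos_list, weight=1.0, chrom="c", strand="+"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos_list, "strand": strand,
         "weight": [weight] * len(pos_list)}
    )


class TestClusterSites:
    def test_gap_above_max_splits(self):
        clusters, _ = cl.cluster_sites(sites([100, 130, 190]), max_gap=50)
        assert len(clusters) == 2
        assert clusters["start"].tolist() == [100, 190]

    def test_gap_of_exactly_max_gap_joins(self):
        clusters, _ = cl.cluster_sites(sites([0, 50, 100]), max_gap=50)
        assert len(clusters) == 1
        assert clusters.loc[0, ["start", "end"]].tolist() == [0, 101]

    def test_single_position_single_cluster(self):
        clusters, _ = cl.cluster_sites(sites([42]), max_gap=50)
        assert len(clusters) == 1
        assert clusters.loc[0, "peak"] == 42

    def test_strands_and_chroms_never_merge(self):
        df = pd.concat([sites([10]), sites([12], strand="-"), sites([14], chrom="d")])
        clusters, _ = cl.cluster_sites(df, max_gap=50)
        assert len(clusters) == 3

    def test_partition_and_weight_conservation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "chrom": "c", "strand": "+",
            "pos": np.sort(rng.choice(5000, 300, replace=False)),
            "weight": rng.uniform(0.5, 5, 300),
        })
        clusters, assigned = cl.cluster_sites(df, max_gap=30)
        assert assigned["cluster_id"].notna().all()
        assert clusters["n_positions"].sum() == len(df)
        assert np.isclose(clusters["weight"].sum(), df["weight"].sum())

    def test_order_and_translation_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.choice(2000, 80, replace=False)
        df = sites(pos)
        base, _ = cl.cluster_sites(df, max_gap=25)
        shuffled, _ = cl.cluster_sites(df.sample(frac=1, random_state=2), max_gap=25)
        pd.testing.assert_frame_equal(base, shuffled)
        moved, _ = cl.cluster_sites(sites(pos + 1000), max_gap=25)
        assert (moved["start"].to_numpy() - base["start"].to_numpy() == 1000).all()


def cluster_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "weight", "peak"]
    )


class TestDecapFilter:
    def test_ratio_arithmetic_from_the_weight_fractions(self):
        # cluster holds 50 of 500 total; overlapping control cluster 1 of 100
        clusters = cluster_frame([("c", "+", 0, 10, 50.0, 5),
                                  ("c", "+", 100, 110, 450.0, 105)])
        nodecap = cluster_frame([("c", "+", 0, 10, 1.0, 5),
                                 ("c", "+", 100, 110, 99.0, 105)])
        out = cl.decap_filter(clusters, nodecap)
        assert np.isclose(out.loc[0, "R"], 10.0)
        assert bool(out.loc[0, "kept"])

    def test_equal_fractions_removed_at_strict_boundary(self):
        clusters = cluster_frame([("c", "+", 0, 10, 50.0, 5),
                                  ("c", "+", 100, 110, 50.0, 105)])
        nodecap = cluster_frame([("c", "+", 0, 10, 5.0, 5),
                                 ("c", "+", 100, 110, 5.0, 105)])
        out = cl.decap_filter(clusters, nodecap)
        assert np.allclose(out["R"], 1.0)
        assert not out["kept"].any()

    def test_cluster_without_control_overlap_kept(self):
        clusters = cluster_frame([("c", "+", 0, 10, 5.0, 5),
                                  ("c", "+", 500, 510, 5.0, 505)])
        nodecap = cluster_frame([("c", "+", 500, 510, 100.0, 505)])
        out = cl.decap_filter(clusters, nodecap)
        assert np.isinf(out.loc[0, "R"]) and bool(out.loc[0, "kept"])

    def test_empty_control_keeps_everything(self):
        clusters = cluster_frame([("c", "+", 0, 10, 5.0, 5)])
        out = cl.decap_filter(clusters, clusters.iloc[0:0])
        assert out["kept"].all()

    def test_kept_iff_fraction_exceeds_control_fraction(self):
        # algebraic restatement of R > 1
        rng = np.random.default_rng(3)
        starts = np.arange(0, 4000, 200)
        clusters = cluster_frame(
            [("c", "+", s, s + 10, w, s) for s, w in
             zip(starts, rng.uniform(1, 50, starts.size))]
        )
        nodecap = cluster_frame(
            [("c", "+", s, s + 10, w, s) for s, w in
             zip(starts, rng.uniform(1, 50, starts.size))]
        )
        out = cl.decap_filter(clusters, nodecap)
        frac = clusters["weight"] / clusters["weight"].sum()
        nd_frac = nodecap["weight"] / nodecap["weight"].sum()
        assert (out["kept"] == (frac > nd_frac)).all()


class TestProminenceAndDistal:
    def test_below_threshold_cluster_dropped(self):
        df = cluster_frame([("c", "+", s, s + 5, w, s) for s, w in
                            [(0, 80.0), (100, 15.0), (200, 5.0)]])
        df["gene_id"] = "g1"
        kept = cl.prominence_filter(df, 0.10)
        assert kept["weight"].tolist() == [80.0, 15.0]

    def test_exactly_ten_percent_kept(self):
        df = cluster_frame([("c", "+", 0, 5, 90.0, 0), ("c", "+", 100, 105, 10.0, 100)])
        df["gene_id"] = "g1"
        assert len(cl.prominence_filter(df, 0.10)) == 2

    def test_prominent_in_any_one_condition_suffices(self):
        df = cluster_frame([("c", "+", 0, 5, 0.0, 0), ("c", "+", 100, 105, 0.0, 100)])
        df["gene_id"] = "g1"
        df["weight_a"] = [95.0, 5.0]
        df["weight_b"] = [88.0, 12.0]
        kept = cl.prominence_filter(df, 0.10, ("weight_a", "weight_b"))
        assert len(kept) == 2

    @staticmethod
    def gene_table():
        return pd.DataFrame(
            [
                {"gene_id": "gp", "chrom": "c", "strand": "+", "tx_start": 900,
                 "tx_end": 3000, "cds_start": 1100, "cds_end": 2900},
                {"gene_id": "gm", "chrom": "c", "strand": "-", "tx_start": 5000,
                 "tx_end": 7100, "cds_start": 5100, "cds_end": 6900},
            ]
        )

    def test_distal_tss_plus_strand_is_upstream_most_peak(self):
        clusters = cluster_frame([("c", "+", 1000, 1010, 5.0, 1000),
                                  ("c", "+", 1050, 1060, 9.0, 1050)])
        clusters["gene_id"] = "gp"
        distal = cl.select_distal(clusters, self.gene_table(), "tss")
        assert distal["gp"] == 1000

    def test_distal_tss_minus_strand_is_highest_coordinate(self):
        clusters = cluster_frame([("c", "-", 2000, 2010, 5.0, 2000),
                                  ("c", "-", 2050, 2060, 9.0, 2050)])
        clusters["gene_id"] = "gm"
        distal = cl.select_distal(clusters, self.gene_table(), "tss")
        assert distal["gm"] == 2050

    def test_single_cluster_is_its_own_distal(self):
        clusters = cluster_frame([("c", "+", 1000, 1010, 5.0, 1003)])
        clusters["gene_id"] = "gp"
        assert cl.select_distal(clusters, self.gene_table(), "tss")["gp"] == 1003

    def test_assign_to_genes_by_upstream_window(self):
        clusters = cluster_frame([
            ("c", "+", 1000, 1010, 5.0, 1005),   # in gp's TL
            ("c", "-", 6950, 6960, 5.0, 6955),   # in gm's TL (minus strand)
            ("c", "+", 4000, 4010, 5.0, 4005),   # intergenic, wrong strand side
        ])
        out = cl.assign_to_genes(clusters, self.gene_table(), "tss")
        assert out["gene_id"].tolist() == ["gp", "gm", None]
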
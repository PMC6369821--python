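"""Cluster finding, isoform counting, independence expectation, ordering."""

import numpy as np
import pytest

from editscape import (
    IsoformCounts,
    LinkageSpec,
    SiteCluster,
    SiteKey,
    cluster_reads_to_sam,
    expected_independent,
    find_clusters,
    gen_cluster_reads,
    isoform_counts,
    isoform_counts_from_alignments,
    isoform_labels,
    linkage_stats,
    ordering_inference,
    population_vs_others,
)
from editscape.io_model import SampleSheet


def cluster_at(*positions, strand="+"):
    return SiteCluster(tuple(SiteKey("chr2L", p, strand) for p in positions))


class TestFindClusters:
    def test_window_rule_and_singleton_exclusion(self):
        sites = [SiteKey("chr2L", p) for p in (10, 45, 120)]
        clusters = find_clusters(sites, cluster_window=40)
        assert [c.positions for c in clusters] == [(10, 45)]

    def test_chaining(self):
        sites = [SiteKey("chr2L", p) for p in (10, 49, 88)]
        clusters = find_clusters(sites, cluster_window=40)
        assert [c.positions for c in clusters] == [(10, 49, 88)]

    def test_matches_graph_components_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        for _ in range(10):
            positions = sorted(set(map(int, rng.integers(1, 2000, size=60))))
            sites = [SiteKey("chr2L", p) for p in positions]
            clusters = find_clusters(sites, cluster_window=40)
            graph = nx.Graph()
            graph.add_nodes_from(positions)
            for p in positions:
                for q in positions:
                    if p < q and q - p < 40:
                        graph.add_edge(p, q)
            expected = sorted(
                tuple(sorted(c)) for c in nx.connected_components(graph) if len(c) >= 2
            )
            assert sorted(c.positions for c in clusters) == expected


class TestIsoformCounts:
    def test_counting_and_marginals(self):
        calls = ["AA"] * 6 + ["AG", "GA"] + ["GG"] * 2
        ic = isoform_counts(calls, cluster_at(10, 30))
        assert ic.total == 10
        assert ic.marginals() == pytest.approx([0.3, 0.3])

    def test_non_spanning_and_ambiguous_reads_discarded(self):
        calls = ["AA", "A", "AN", "GG", "AGG"]
        ic = isoform_counts(calls, cluster_at(10, 30))
        assert ic.total == 2

    def test_marginal_consistency_invariant(self):
        """Levels recomputed from isoform counts equal per-site counts exactly."""
        spec = LinkageSpec((0.3, 0.5, 0.2), "fully_linked")
        ic = gen_cluster_reads(spec, 5000, seed=4)
        for i, m in enumerate(ic.marginals()):
            g_i = sum(n for iso, n in ic.counts.items() if iso[i] == "G")
            assert m == g_i / ic.total

    def test_multinomial_consistency_with_truth(self):
        spec = LinkageSpec.from_table({"AA": 0.5, "AG": 0.1, "GA": 0.15, "GG": 0.25})
        ic = gen_cluster_reads(spec, 20_000, seed=6)
        fr = ic.fractions()
        for iso, p in spec.joint_table().items():
            se = np.sqrt(p * (1 - p) / 20_000)
            assert abs(fr[iso] - p) < 4 * se


class TestReadBackedExtraction:
    def test_sam_round_trip(self, tmp_path):
        cluster = cluster_at(100, 130)
        spec = LinkageSpec((0.3, 0.4), "fully_linked")
        drawn = gen_cluster_reads(spec, 500, seed=9, cluster=cluster)
        sam = tmp_path / "cluster.sam"
        cluster_reads_to_sam(sam, cluster, drawn)
        back = isoform_counts_from_alignments(sam, cluster)
        assert back.counts == drawn.counts

    def test_minus_strand_round_trip(self, tmp_path):
        cluster = cluster_at(100, 130, strand="-")
        spec = LinkageSpec((0.5, 0.5), "independent")
        drawn = gen_cluster_reads(spec, 300, seed=10, cluster=cluster)
        sam = tmp_path / "minus.sam"
        cluster_reads_to_sam(sam, cluster, drawn)
        back = isoform_counts_from_alignments(sam, cluster)
        assert back.counts == drawn.counts


class TestExpectedIndependent:
    def test_uniform(self):
        exp = expected_independent([0.5, 0.5])
        assert all(v == pytest.approx(0.25) for v in exp.values())

    def test_degenerate_marginal(self):
        exp = expected_independent([0.0, 0.3])
        assert exp["GA"] == 0 and exp["GG"] == 0
        assert exp["AA"] == pytest.approx(0.7) and exp["AG"] == pytest.approx(0.3)

    def test_sli_like_marginals(self):
        exp = expected_independent([0.29, 0.34])
        assert exp["AA"] == pytest.approx(0.4686)
        assert exp["GG"] == pytest.approx(0.0986)

    def test_sums_to_one_and_reproduces_marginals(self):
        rng = np.random.default_rng(12)
        for k in (2, 3, 4):
            p = rng.uniform(0, 1, size=k)
            exp = expected_independent(p)
            assert sum(exp.values()) == pytest.approx(1.0, abs=1e-12)
            for i in range(k):
                m = sum(v for iso, v in exp.items() if iso[i] == "G")
                assert m == pytest.approx(p[i], abs=1e-12)

    def test_equals_independence_mle(self):
        """Product of marginals maximizes the independence-model likelihood."""
        counts = {"AA": 40, "AG": 25, "GA": 20, "GG": 15}
        total = sum(counts.values())
        p_hat = [
            sum(n for iso, n in counts.items() if iso[i] == "G") / total
            for i in range(2)
        ]
        mle = expected_independent(p_hat)

        def loglik(p):
            exp = expected_independent(p)
            return sum(n * np.log(exp[iso]) for iso, n in counts.items())

        best = loglik(p_hat)
        for q1 in np.linspace(0.05, 0.95, 19):
            for q2 in np.linspace(0.05, 0.95, 19):
                assert loglik([q1, q2]) <= best + 1e-9
        assert sum(mle.values()) == pytest.approx(1.0)


class TestLinkageStats:
    def test_observed_equals_expected(self):
        # independent draws: diffs hover near zero, t-test not significant
        spec = LinkageSpec((0.3, 0.4), "independent")
        reps = [gen_cluster_reads(spec, 20_000, seed=s) for s in (31, 32, 33)]
        stats = linkage_stats(reps)
        assert stats["diff"].abs().max() < 0.02
        assert (stats["p_value"] > 0.01).all()

    def test_full_linkage_closed_form(self):
        # only AA/GG reads with marginal 0.3: diff(GG) = 0.3 - 0.09 = +0.21
        cluster = cluster_at(10, 30)
        ic = IsoformCounts(cluster, "s", {"AA": 700, "GG": 300})
        stats = linkage_stats([ic]).set_index("isoform")
        assert stats.loc["GG", "diff"] == pytest.approx(0.21)
        assert stats.loc["AA", "diff"] == pytest.approx(0.21)
        assert stats.loc["AG", "diff"] == pytest.approx(-0.21)

    def test_coregulation_sign_signature(self):
        """Full linkage: all-A and all-G isoforms over-, mixed under-represented."""
        spec = LinkageSpec((0.25, 0.4, 0.3), "fully_linked")
        reps = [gen_cluster_reads(spec, 10_000, seed=s) for s in (41, 42, 43)]
        stats = linkage_stats(reps).set_index("isoform")
        assert stats.loc["AAA", "diff"] > 0
        assert stats.loc["GGG", "diff"] > 0
        mixed = [iso for iso in isoform_labels(3) if iso not in ("AAA", "GGG")]
        assert (stats.loc[mixed, "diff"] < 0.005).all()

    def test_diff_sums_to_zero(self):
        spec = LinkageSpec((0.3, 0.5), "fully_linked")
        reps = [gen_cluster_reads(spec, 2_000, seed=s) for s in (51, 52)]
        stats = linkage_stats(reps)
        assert stats["observed"].sum() == pytest.approx(1.0, abs=1e-12)
        assert stats["expected"].sum() == pytest.approx(1.0, abs=1e-12)
        assert stats["diff"].sum() == pytest.approx(0.0, abs=1e-12)


class TestPopulationVsOthers:
    def test_focal_population_detected(self):
        sheet = SampleSheet(
            [(f"{p}_r{r}", p, r) for p in ("fru", "oth1", "oth2") for r in (1, 2, 3)]
        )
        cluster = cluster_at(10, 30)
        linked = LinkageSpec((0.3, 0.3), "fully_linked")
        indep = LinkageSpec((0.1, 0.1), "independent")
        by_sample = {}
        for i, s in enumerate(sheet.samples):
            spec = linked if s.startswith("fru") else indep
            by_sample[s] = gen_cluster_reads(spec, 5_000, seed=60 + i, cluster=cluster)
        res = population_vs_others(by_sample, sheet, "fru").set_index("isoform")
        assert res.loc["GG", "significant"]
        assert res.loc["GG", "mean_diff"] > 0.10


class TestOrdering:
    def test_prerequisite_first_site(self):
        # isoforms observed only with G at site 1 -> site 1 precedes 2 and 3
        ic = IsoformCounts(
            cluster_at(10, 30, 50), "s",
            {"AAA": 400, "GAA": 200, "GGA": 150, "GAG": 100, "GGG": 150},
        )
        assert set(ordering_inference(ic)) == {(0, 1), (0, 2)}

    def test_symmetric_counts_no_order(self):
        ic = IsoformCounts(cluster_at(10, 30), "s", {"AA": 50, "AG": 25, "GA": 25})
        assert ordering_inference(ic) == []

    def test_full_linkage_no_order(self):
        ic = IsoformCounts(cluster_at(10, 30), "s", {"AA": 70, "GG": 30})
        assert ordering_inference(ic) == []

    def test_sequential_generator_recovered(self):
        spec = LinkageSpec((0.5, 0.25), "sequential")
        ic = gen_cluster_reads(spec, 10_000, seed=71)
        assert ordering_inference(ic) == [(0, 1)]
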
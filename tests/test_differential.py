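"""Fisher exact comparisons, significance gating, population summaries."""

from math import comb

import numpy as np
import pytest

from editscape import (
    CountMatrix,
    SampleSheet,
    SiteKey,
    fisher_site,
    gen_counts,
    make_truth,
    pairwise_differential,
    population_summary,
)


def fisher_enumeration(g1, a1, g2, a2):
    """Independent oracle: exact two-sided p by enumerating 2×2 tables."""
    n1, n2 = g1 + a1, g2 + a2
    G, N = g1 + g2, g1 + a1 + g2 + a2

    def prob(x):
        return comb(n1, x) * comb(n2, G - x) / comb(N, G)

    p_obs = prob(g1)
    lo, hi = max(0, G - n2), min(G, n1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestFisherSite:
    def test_identical_proportions(self):
        assert fisher_site(50, 50, 50, 50) == 1.0

    def test_strong_difference(self):
        assert fisher_site(90, 10, 50, 50) < 1e-8

    def test_small_table_exact_enumeration(self):
        # [[0,5],[5,0]]: only the two extreme tables are as improbable -> 2/252
        assert fisher_site(5, 0, 0, 5) == pytest.approx(2 / 252)

    @pytest.mark.parametrize(
        "table", [(5, 0, 0, 5), (10, 3, 4, 9), (20, 5, 12, 13), (7, 7, 2, 12), (0, 4, 4, 0)]
    )
    def test_agrees_with_enumeration_oracle(self, table):
        a1, g1, a2, g2 = table
        assert fisher_site(a1, g1, a2, g2) == pytest.approx(
            fisher_enumeration(g1, a1, g2, a2), rel=1e-9
        )

    def test_symmetry(self):
        assert fisher_site(10, 3, 4, 9) == pytest.approx(fisher_site(4, 9, 10, 3))

    def test_all_zero_table_warns(self):
        with pytest.warns(UserWarning):
            assert fisher_site(0, 0, 0, 0) == 1.0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fisher_site(-1, 2, 3, 4)


def planted_matrix(n_null=30, n_diff=10, depth=500, delta=0.3, seed=0):
    """Two populations × 3 replicates; the first n_diff sites differ by delta."""
    rng = np.random.default_rng(seed)
    sheet = SampleSheet([(f"{p}_r{r}", p, r) for p in ("A", "B") for r in (1, 2, 3)])
    n = n_null + n_diff
    levels_a = np.full(n, 0.2)
    levels_b = np.full(n, 0.2)
    levels_b[:n_diff] += delta
    a = np.zeros((n, 6), dtype=int)
    g = np.zeros((n, 6), dtype=int)
    for j, smp in enumerate(sheet.samples):
        lv = levels_a if smp.startswith("A") else levels_b
        g[:, j] = rng.binomial(depth, lv)
        a[:, j] = depth - g[:, j]
    sites = [SiteKey("chr2L", 100 + 10 * i) for i in range(n)]
    return CountMatrix(sites, sheet.samples, a, g), sheet


class TestPairwiseDifferential:
    def test_effect_size_gate(self):
        # huge counts, tiny p, but delta below the 20% gate -> not significant
        sheet = SampleSheet([("A_r1", "A", 1), ("B_r1", "B", 1)])
        mat = CountMatrix(
            [SiteKey("chr2L", 1)], ["A_r1", "B_r1"],
            np.array([[8100, 9000]]), np.array([[1900, 1000]]),
        )
        res = pairwise_differential(mat, sheet, correction="none")
        assert res.iloc[0]["p_adjusted"] < 1e-10
        assert abs(res.iloc[0]["delta"]) < 0.20
        assert not res.iloc[0]["significant"]

    def test_planted_sites_recovered(self):
        mat, sheet = planted_matrix(seed=1)
        res = pairwise_differential(mat, sheet)
        sig_pos = set(res[res["significant"]]["pos"])
        planted = {100 + 10 * i for i in range(10)}
        assert sig_pos == planted
        # every flagged record satisfies the printed 20% gate by construction
        assert (res[res["significant"]]["delta"].abs() > 0.20).all()

    def test_low_coverage_pair_skipped(self):
        sheet = SampleSheet([("A_r1", "A", 1), ("B_r1", "B", 1), ("C_r1", "C", 1)])
        mat = CountMatrix(
            [SiteKey("chr2L", 1)], sheet.samples,
            np.array([[50, 5, 40]]), np.array([[50, 5, 10]]),
        )
        res = pairwise_differential(mat, sheet, min_coverage=20)
        assert set(zip(res["pop_a"], res["pop_b"])) == {("A", "C")}

    def test_delta_antisymmetry(self):
        sheet_ab = SampleSheet([("x", "A", 1), ("y", "B", 1)])
        sheet_ba = SampleSheet([("y", "B", 1), ("x", "A", 1)])
        mat = CountMatrix(
            [SiteKey("chr2L", 1)], ["x", "y"], np.array([[60, 30]]), np.array([[40, 70]])
        )
        r1 = pairwise_differential(mat, sheet_ab, correction="none").iloc[0]
        r2 = pairwise_differential(mat, sheet_ba, correction="none").iloc[0]
        assert r1["delta"] == pytest.approx(-r2["delta"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_null_false_flag_rate_controlled(self):
        """Equal-editing populations at coverage 200: BH keeps flags ≤ alpha."""
        rng = np.random.default_rng(9)
        n_sites, depth = 1000, 200
        sheet = SampleSheet([("A_r1", "A", 1), ("B_r1", "B", 1)])
        g = rng.binomial(depth, 0.3, size=(n_sites, 2))
        mat = CountMatrix(
            [SiteKey("chr2L", i + 1) for i in range(n_sites)],
            ["A_r1", "B_r1"], depth - g, g,
        )
        res = pairwise_differential(mat, sheet, alpha=0.05, correction="bh")
        false_rate = res["significant"].mean()
        assert false_rate <= 0.05

    def test_correction_modes_ordering(self):
        mat, sheet = planted_matrix(seed=2)
        raw = pairwise_differential(mat, sheet, correction="none")
        bh = pairwise_differential(mat, sheet, correction="bh")
        bonf = pairwise_differential(mat, sheet, correction="bonferroni")
        assert (raw["p_adjusted"] <= bh["p_adjusted"] + 1e-15).all()
        assert (bh["p_adjusted"] <= bonf["p_adjusted"] + 1e-15).all()


class TestPopulationSummary:
    def test_counting_and_antisymmetry(self):
        truth = make_truth(
            n_sites=30, n_populations=4, mean_depth=400, snp_rate=0,
            conversion_noise_rate=0, n_repeat_loci=0, sites_per_repeat_locus=0,
            shift_values=[0.4] * 6, seed=21,
        )
        counts, sheet = gen_counts(truth)
        res = pairwise_differential(counts, sheet)
        summary, bins = population_summary(res)
        sig = res[res["significant"]]
        # each significant record contributes one higher and one lower side
        assert summary["n_higher"].sum() >= 0
        total_bins = bins["n_populations_differing"].sum()
        assert total_bins == 2 * len(sig)

    def test_no_significant_results(self):
        sheet = SampleSheet([("x", "A", 1), ("y", "B", 1)])
        mat = CountMatrix(
            [SiteKey("chr2L", 1)], ["x", "y"], np.array([[50, 50]]), np.array([[50, 50]])
        )
        summary, bins = population_summary(pairwise_differential(mat, sheet))
        assert (summary["n_higher"] == 0).all() and (summary["n_lower"] == 0).all()
        assert bins.empty

    def test_site_higher_in_one_population_binned_correctly(self):
        import pandas as pd

        res = pd.DataFrame(
            [
                {"chrom": "chr2L", "pos": 1, "strand": "+", "pop_a": "Fru",
                 "pop_b": q, "level_a": 0.6, "level_b": 0.1, "delta": 0.5,
                 "p_value": 1e-9, "p_adjusted": 1e-8, "significant": True}
                for q in ("P1", "P2", "P3")
            ]
        )
        summary, bins = population_summary(res)
        fru = summary.set_index("population").loc["Fru"]
        assert fru["n_higher"] == 1 and fru["n_lower"] == 0
        fru_bin = bins[(bins["population"] == "Fru") & (bins["direction"] == "higher")]
        assert list(fru_bin["n_populations_differing"]) == [3]
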
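import numpy as np
import pandas as pd
import pytest

from melcoev import integration as ig
from melcoev.selection import SiteSelectionCall


def scan_df(gene_a, gene_b, rows):
    """rows: (col_a, col_b, delta_aic [, s, d, profile])"""
    recs = []
    for r in rows:
        col_a, col_b, da = r[:3]
        s, d = (r[3], r[4]) if len(r) > 3 else (1.0, 0.5)
        prof = r[5] if len(r) > 5 else "AA/CC"
        recs.append({"site_a_gene": gene_a, "site_b_gene": gene_b,
                     "col_a": col_a, "col_b": col_b,
                     "orig_col_a": col_a, "orig_col_b": col_b,
                     "profile": prof, "s": s, "d": d,
                     "loglik_coev": 0.0, "loglik_indep": -da / 2 - 2,
                     "delta_aic": da})
    columns = ["site_a_gene", "site_b_gene", "col_a", "col_b", "orig_col_a",
               "orig_col_b", "profile", "s", "d", "loglik_coev",
               "loglik_indep", "delta_aic"]
    return pd.DataFrame(recs, columns=columns)


def call(codon, category="positive", branches=frozenset()):
    return SiteSelectionCall(codon, category=category, n_usable=10,
                             n_substitutions=2, branches_selected=branches)


class TestCountPairs:
    def test_no_pair_passes(self):
        scans = {("g1", "g2"): scan_df("g1", "g2", [(0, 0, 1.0), (1, 2, 0.5)])}
        out = ig.count_coevolving_pairs(scans, {("g1", "g2"): 5.0})
        assert out.loc["g1", "g2"] == 0

    def test_counts_and_averages_by_hand(self):
        scans = {
            ("g1", "g2"): scan_df("g1", "g2",
                                  [(0, 0, 10.0), (1, 1, 8.0), (2, 2, 1.0)]),
            ("g1", "g3"): scan_df("g1", "g3", [(0, 0, 10.0)]),
            ("g2", "g3"): scan_df("g2", "g3", [(0, 1, -3.0)]),
        }
        thr = {k: 5.0 for k in scans}
        out = ig.count_coevolving_pairs(scans, thr)
        assert out.loc["g1", "g2"] == 2
        assert out.loc["g2", "g1"] == 2
        assert out.loc["g1", "g3"] == 1
        assert out.loc["g2", "g3"] == 0
        assert out.loc["g1", "average"] == pytest.approx((2 + 1) / 2)
        assert out.loc["g3", "average"] == pytest.approx((1 + 0) / 2)

    def test_threshold_monotonicity(self):
        scans = {("g1", "g2"): scan_df(
            "g1", "g2", [(i, i, float(i)) for i in range(10)])}
        counts = [ig.count_coevolving_pairs(
            scans, {("g1", "g2"): t}).loc["g1", "g2"] for t in (2.0, 5.0, 8.0)]
        assert counts[0] >= counts[1] >= counts[2]


class TestResponsePairs:
    def test_no_positive_codons_gives_empty(self):
        scans = {("g1", "g2"): scan_df("g1", "g2", [(0, 0, 10.0)])}
        selection = {"g1": [call(0, "neutral")], "g2": [call(0, "purifying")]}
        out = ig.select_response_pairs(scans, selection, {("g1", "g2"): 5.0})
        assert out.empty

    def test_codon_attribution_rule(self):
        # column 7 of gene A belongs to codon floor(7/3) = 2
        scans = {("gA", "gB"): scan_df("gA", "gB", [(7, 3, 10.0)])}
        selection = {"gA": [call(2, "positive")], "gB": [call(1, "neutral")]}
        out = ig.select_response_pairs(scans, selection, {("gA", "gB"): 5.0})
        assert len(out) == 1
        assert bool(out.iloc[0]["target_a"]) is True
        assert bool(out.iloc[0]["target_b"]) is False

    def test_pair_can_count_for_both_genes(self):
        scans = {("gA", "gB"): scan_df("gA", "gB", [(0, 0, 10.0)])}
        selection = {"gA": [call(0)], "gB": [call(0)]}
        out = ig.select_response_pairs(scans, selection, {("gA", "gB"): 5.0})
        assert bool(out.iloc[0]["target_a"]) and bool(out.iloc[0]["target_b"])

    def test_missing_provenance_is_hard_error(self):
        df = scan_df("g1", "g2", [(0, 0, 10.0)]).drop(
            columns=["orig_col_a", "orig_col_b"])
        with pytest.raises(ig.IntegrationError):
            ig.select_response_pairs({("g1", "g2"): df},
                                     {"g1": [call(0)], "g2": [call(0)]},
                                     {("g1", "g2"): 5.0})

    def test_frame_offset_shifts_codons(self):
        scans = {("gA", "gB"): scan_df("gA", "gB", [(2, 0, 10.0)])}
        selection = {"gA": [call(0, "positive")], "gB": [call(0, "neutral")]}
        # offset 2: column 2 -> codon (2-2)//3 = 0
        out = ig.select_response_pairs(scans, selection, {("gA", "gB"): 5.0},
                                       frame_offsets={"gA": 2})
        assert len(out) == 1


class TestSiteStats:
    def test_distinct_site_dedup(self):
        scans = {("gA", "gB"): scan_df("gA", "gB",
                                       [(3, 0, 10.0), (3, 1, 9.0)])}
        selection = {"gA": [call(1, "positive")], "gB": [call(0, "neutral")]}
        resp = ig.select_response_pairs(scans, selection, {("gA", "gB"): 5.0})
        stats = ig.distinct_site_stats(resp, {"gA": 30, "gB": 30})
        assert stats.loc["gA", "n_pairs"] == 2
        assert stats.loc["gA", "n_distinct_sites"] == 1
        assert stats.loc["gA", "n_distinct_sites"] <= stats.loc["gA", "n_pairs"]

    @pytest.mark.parametrize("n_sites, length, expected", [
        (22, 396, 5.6), (34, 951, 3.6)])
    def test_percentage_to_one_decimal(self, n_sites, length, expected):
        scans = {("gA", "gB"): scan_df(
            "gA", "gB", [(3 * i, 0, 10.0) for i in range(n_sites)])}
        selection = {"gA": [call(i, "positive") for i in range(n_sites)],
                     "gB": [call(0, "neutral")]}
        resp = ig.select_response_pairs(scans, selection, {("gA", "gB"): 5.0})
        stats = ig.distinct_site_stats(resp, {"gA": length, "gB": length})
        assert stats.loc["gA", "pct_distinct_sites"] == expected

    def test_zero_length_rejected(self):
        resp = pd.DataFrame(columns=["gene_a", "gene_b", "col_a", "col_b",
                                     "target_a", "target_b"])
        with pytest.raises(ig.IntegrationError):
            ig.distinct_site_stats(resp, {"gA": 0})

    def test_partner_counts_row_sum_equals_pair_total(self):
        scans = {
            ("gA", "gB"): scan_df("gA", "gB", [(0, 0, 10.0), (3, 1, 9.0)]),
            ("gA", "gC"): scan_df("gA", "gC", [(0, 2, 12.0)]),
            ("gB", "gC"): scan_df("gB", "gC", []),
        }
        selection = {"gA": [call(0, "positive"), call(1, "positive")],
                     "gB": [call(0, "neutral")], "gC": [call(0, "neutral")]}
        resp = ig.select_response_pairs(scans, selection,
                                        {k: 5.0 for k in scans})
        partner = ig.partner_pair_counts(resp, ["gA", "gB", "gC"])
        stats = ig.distinct_site_stats(resp, {"gA": 30, "gB": 30, "gC": 30})
        for g in ("gA", "gB", "gC"):
            assert partner.loc[g].sum() == stats.loc[g, "n_pairs"]


class TestChisq:
    def test_equal_rates_not_significant(self):
        counts = {"g1": 50, "g2": 50, "g3": 50}
        expos = {"g1": 1000, "g2": 1000, "g3": 1000}
        out = ig.gene_vs_rest_chisq(counts, expos)
        assert (out["label"] == "ns").all()
        assert (out["p"] > 0.9).all()

    def test_chisq_statistic_matches_closed_form(self):
        # 2x2 table (30, 70 / 10, 190): chi2 = n (ad-bc)^2 / (r1 r2 c1 c2)
        from scipy.stats import chi2_contingency
        table = np.array([[30.0, 70.0], [10.0, 190.0]])
        stat, _, _, _ = chi2_contingency(table, correction=False)
        n = table.sum()
        a, b, c, d = table.ravel()
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(expected, rel=1e-12)
        out = ig.gene_vs_rest_chisq({"g1": 30, "g2": 10},
                                    {"g1": 100, "g2": 200})
        assert out.loc["g1", "p"] == pytest.approx(
            1 - __import__("scipy").stats.chi2.cdf(expected, 1), rel=1e-9)
        assert out.loc["g1", "direction"] == "above"

    def test_fisher_fallback_on_tiny_expected(self):
        out = ig.gene_vs_rest_chisq({"g1": 0, "g2": 1}, {"g1": 3, "g2": 2000})
        assert out.loc["g1", "method"] == "fisher"

    def test_count_exceeding_exposure_rejected(self):
        with pytest.raises(ig.IntegrationError):
            ig.gene_vs_rest_chisq({"g1": 10, "g2": 0}, {"g1": 5, "g2": 10})


class TestPCA:
    def test_single_varying_variable(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0] * 4,
                           "c": [2.0] * 4}, index=list("wxyz"))
        with pytest.warns(UserWarning):
            res = ig.pca_influence(df)
        assert res.variables == ["a"]
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_rank_one_three_correlated_variables(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": 3 * x + 1},
                          index=list("wxyz"))
        res = ig.pca_influence(df)
        assert res.eigenvalues[0] == pytest.approx(3.0, abs=1e-9)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)
        assert res.retained.tolist() == [True, False, False]

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 3))
        df = pd.DataFrame(X, columns=list("abc"),
                          index=[f"g{i}" for i in range(10)])
        res = ig.pca_influence(df)
        vals = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert np.allclose(res.eigenvalues, vals, atol=1e-8)
        assert np.allclose(res.explained_pct, 100 * vals / vals.sum(),
                           atol=1e-8)

    def test_pc1_loadings_oriented_non_negative_for_influence_metrics(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 10, 8)
        df = pd.DataFrame({
            "n_pairs": base * 3 + rng.normal(0, 0.3, 8),
            "n_sites": base + rng.normal(0, 0.2, 8),
            "pct_branches": base * 0.5 + rng.normal(0, 0.1, 8),
        }, index=[f"g{i}" for i in range(8)])
        res = ig.pca_influence(df)
        assert (res.loadings[:, 0] >= 0).all()
        # the gene with the largest underlying influence scores highest
        assert res.scores["PC1"].idxmax() == df["n_pairs"].idxmax()

    def test_too_few_genes_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ig.IntegrationError):
            ig.pca_influence(df)
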
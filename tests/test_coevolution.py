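import numpy as np
import pytest
from scipy.linalg import expm

from melcoev import coevolution as cv
from melcoev.synthetic_data import generate_tree, simulate_coev_pair
from melcoev.trees import Tree


def cols(*pairs):
    """Build two columns from dinucleotide strings."""
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    return a, b


class TestSelectProfile:
    def test_most_frequent_pair(self):
        a, b = cols(*(["AT"] * 5 + ["GC"] * 4 + ["AC"]))
        prof = cv.select_profile(a, b)
        assert (prof.state1, prof.state2) == ("AT", "GC")

    def test_single_position_variation_infeasible(self):
        a, b = cols(*(["AT"] * 5 + ["AC"] * 4))
        assert cv.select_profile(a, b) is None

    def test_tie_break_lexicographic(self):
        a, b = cols(*(["AT"] * 3 + ["GC"] * 3 + ["CG"] * 3))
        prof = cv.select_profile(a, b)
        # all three mutually valid pairs tie at 6; (AT, CG) < (AT, GC) < (CG, GC)
        assert (prof.state1, prof.state2) == ("AT", "CG")

    def test_gaps_do_not_define_states(self):
        a, b = cols("AT", "AT", "GC", "-C", "AN")
        prof = cv.select_profile(a, b)
        assert (prof.state1, prof.state2) == ("AT", "GC")

    def test_invalid_profile_rejected(self):
        with pytest.raises(cv.CoevError):
            cv.CoevProfile("AT", "AC")
        with pytest.raises(cv.CoevError):
            cv.CoevProfile("GC", "AT")  # wrong order


class TestRateMatrix:
    def test_equal_rates_reduce_to_uniform_single_changes(self):
        Q = cv.coev_rate_matrix(cv.CoevProfile("AA", "CC"), 0.7, 0.7)
        off = Q[~np.eye(16, dtype=bool)]
        nz = off[off > 0]
        assert np.allclose(nz, 0.7)
        assert len(nz) == 16 * 6  # six single-position neighbours per state

    def test_structure(self):
        Q = cv.coev_rate_matrix(cv.CoevProfile("AA", "CC"), 2.0, 1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for x in range(16):
            for y in range(16):
                if x == y:
                    continue
                x1, x2, y1, y2 = x // 4, x % 4, y // 4, y % 4
                if (x1 != y1) and (x2 != y2):
                    assert Q[x, y] == 0.0

    def test_rule_application(self):
        # profile {AA, CC}; AC -> CC completes the profile (rate s),
        # AC -> AG leaves it (rate d)
        Q = cv.coev_rate_matrix(cv.CoevProfile("AA", "CC"), 2.0, 1.0)
        AC, CC, AG, AA = 1, 5, 2, 0
        assert Q[AC, CC] == 2.0
        assert Q[AC, AG] == 1.0
        assert Q[AC, AA] == 2.0

    def test_negative_rates_rejected(self):
        with pytest.raises(cv.CoevError):
            cv.coev_rate_matrix(cv.CoevProfile("AA", "CC"), -1.0, 0.5)


class TestReductionIdentity:
    def test_equal_rates_match_independent_jc(self, quartet_tree):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACGT"))
        for _ in range(10):
            a = letters[rng.integers(0, 4, 4)]
            b = letters[rng.integers(0, 4, 4)]
            prof = cv.select_profile(a, b)
            if prof is None:
                continue
            ll16 = cv.coev_pair_loglik(a, b, quartet_tree, prof, 1 / 3, 1 / 3)
            ll_ind, k, _ = cv.fit_independent_pair(a, b, quartet_tree)
            assert ll16 == pytest.approx(ll_ind, abs=1e-6)
            assert k == 0

    def test_holds_with_missing_data(self, quartet_tree):
        a = np.array(list("AC-G"))
        b = np.array(list("TNAC"))
        prof = cv.select_profile(a, b)
        ll16 = cv.coev_pair_loglik(a, b, quartet_tree, prof, 1 / 3, 1 / 3)
        ll_ind, _, _ = cv.fit_independent_pair(a, b, quartet_tree)
        assert ll16 == pytest.approx(ll_ind, abs=1e-6)


class TestIndependentModel:
    def test_three_leaf_enumeration(self, triplet_tree):
        a = np.array(list("ACG"))
        ll = cv.jc_site_logliks(triplet_tree,
                                cv.column_partials(a[:, None]))[0]
        Ps = [cv.jc_transition(t) for t in triplet_tree.blen]
        states = [0, 1, 2]
        total = sum(0.25 * np.prod([Ps[i][r, states[i]] for i in range(3)])
                    for r in range(4))
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_invariant_pair_is_finite(self, quartet_tree):
        a = np.array(list("AAAA"))
        b = np.array(list("CCCC"))
        ll, k, aic = cv.fit_independent_pair(a, b, quartet_tree)
        assert np.isfinite(ll)
        assert aic == pytest.approx(-2 * ll)


class TestGridFit:
    def test_grid_matches_exact_evaluator_at_argmax(self, quartet_tree):
        rng = np.random.default_rng(1)
        letters = np.array(list("ACGT"))
        eng = cv.CoevEngine(quartet_tree)
        for _ in range(5):
            a = letters[rng.integers(0, 4, 4)]
            b = letters[rng.integers(0, 4, 4)]
            fit = cv.fit_coev_pair(a, b, quartet_tree, eng)
            if fit is None:
                continue
            exact = cv.coev_pair_loglik(a, b, quartet_tree, fit.profile,
                                        fit.s, fit.d)
            assert fit.loglik == pytest.approx(exact, abs=1e-4)
            assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_fit_not_below_fixed_grid_points(self, quartet_tree):
        eng = cv.CoevEngine(quartet_tree)
        a = np.array(list("ATAT"))
        b = np.array(list("GCGC"))
        fit = cv.fit_coev_pair(a, b, quartet_tree, eng)
        for s, d in [(1 / 3, 1 / 3), (1.0, 1.0), (2.0, 0.25)]:
            ll = cv.coev_pair_loglik(a, b, quartet_tree, fit.profile, s, d)
            assert fit.loglik >= ll - 1e-4

    def test_rate_ratio_recovery_on_strong_pairs(self):
        tree = generate_tree(20, seed=9, height=0.5)
        rng = np.random.default_rng(10)
        eng = cv.CoevEngine(tree)
        prof = cv.CoevProfile("AT", "GC")
        ratios = []
        for _ in range(20):
            a, b = simulate_coev_pair(tree, prof, 10.0, 1.0, rng)
            fit = cv.fit_coev_pair(a, b, tree, eng)
            if fit is not None:
                ratios.append(fit.s / fit.d)
        assert len(ratios) >= 18
        assert np.mean(np.array(ratios) > 1) >= 0.9


class TestPairResult:
    def test_delta_aic_and_threshold_rule(self):
        fit = cv.CoevFit(cv.CoevProfile("AA", "CC"), 2.0, 1.0, loglik=-10.0)
        res = cv.CoevPairResult(("gA", 1), ("gB", 2), fit, loglik_indep=-12.0)
        # AIC_indep - AIC_coev = (0 + 24) - (4 + 20) = 0
        assert res.delta_aic == pytest.approx(0.0)
        assert not res.is_coevolving(0.0)
        assert res.is_coevolving(-0.5)

    def test_infeasible_pair_never_coevolving(self):
        res = cv.CoevPairResult(("gA", 1), ("gB", 2), None, loglik_indep=-12.0)
        assert res.delta_aic == -np.inf
        assert not res.is_coevolving(-1e12)


class TestScan:
    @pytest.fixture
    def paired(self):
        from melcoev.seq_io import GeneAlignment, pair_genes
        rng = np.random.default_rng(12)
        letters = np.array(list("ACGT"))
        species = [f"s{i}" for i in range(6)]
        a = GeneAlignment("ga", species, letters[rng.integers(0, 4, (6, 10))])
        b = GeneAlignment("gb", species, letters[rng.integers(0, 4, (6, 7))])
        return pair_genes(a, b)

    @pytest.fixture
    def scan_tree(self):
        return Tree.from_newick(
            "((s0:0.2,s1:0.2):0.1,((s2:0.2,s3:0.2):0.1,(s4:0.2,s5:0.2):0.1):0.05);")

    def test_pair_count(self, paired, scan_tree):
        res = cv.scan_gene_pair(paired, scan_tree)
        assert len(res) == 70
        assert set(res["site_a_gene"]) == {"ga"}
        assert set(res["site_b_gene"]) == {"gb"}

    def test_deterministic(self, paired, scan_tree):
        eng = cv.CoevEngine(scan_tree)
        r1 = cv.scan_gene_pair(paired, scan_tree, eng)
        r2 = cv.scan_gene_pair(paired, scan_tree, eng)
        assert r1.equals(r2)

    def test_delta_aic_consistency(self, paired, scan_tree):
        res = cv.scan_gene_pair(paired, scan_tree)
        ok = np.isfinite(res["delta_aic"])
        expected = 2 * (res["loglik_coev"] - res["loglik_indep"]) - 4
        assert np.allclose(res.loc[ok, "delta_aic"], expected[ok], atol=1e-9)


@pytest.fixture(scope="module")
def calib():
    tree = generate_tree(12, seed=30, height=0.6)
    return cv.calibrate_null(tree, nsites=60, seed=13)


class TestCalibration:
    def test_threshold_ordering(self, calib):
        assert (calib.threshold(90) <= calib.threshold(95)
                <= calib.threshold(97.5))

    def test_percentile_by_construction(self, calib):
        n = len(calib.sample)
        frac = (calib.sample > calib.threshold(95)).mean()
        assert abs(frac - 0.05) <= 1.0 / np.sqrt(n) + 1e-9

    def test_sample_size(self, calib):
        assert len(calib.sample) == 60 * 59 // 2

    def test_json_round_trip(self, calib, tmp_path):
        import json
        path = tmp_path / "cal.json"
        calib.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["thresholds"] == calib.thresholds
        assert payload["k_coev"] == 2 and payload["k_indep"] == 0


class TestAncestralSubstitutions:
    def test_clade_split_substitution_on_connecting_branches(self):
        tree = Tree.from_newick("((A:0.05,B:0.05):0.2,(C:0.05,D:0.05):0.2);")
        a = np.array(list("AAGG"))
        b = np.array(list("TTCC"))
        prof = cv.CoevProfile("AT", "GC")
        changed = cv.pair_substitution_branches(a, b, tree, prof, 5.0, 0.5)
        # the AT->GC switch happens along the two deep branches; no terminal
        # branch shows a change
        assert changed[:4].sum() == 0
        assert changed[4:].any()
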
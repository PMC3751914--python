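import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pwfrank as pw
from pwfrank.simulate import GeneSetCatalog


def _ranking(n, rng=None):
    """A uniform-random (or identity) ranking frame over n genes."""
    ranks = np.arange(1, n + 1, dtype=float)
    if rng is not None:
        rng.shuffle(ranks)
    return pd.DataFrame(
        {"pwf": 1.0 / ranks, "rank": ranks, "quantile": ranks / n},
        index=[f"g{i:05d}" for i in range(n)],
    )


def _bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestCernoStatistic:
    def test_members_at_worst_rank_give_zero_statistic(self):
        ranking = _ranking(10)
        catalog = GeneSetCatalog(sets={"worst": ["g00009"]})  # rank 10 of 10
        res = pw.cerno_test(ranking, catalog)
        assert res.loc["worst", "S"] == pytest.approx(0.0)
        assert res.loc["worst", "p"] == pytest.approx(1.0)

    def test_extreme_ranks_match_closed_form(self):
        ranking = _ranking(10)
        catalog = GeneSetCatalog(sets={"top2": ["g00000", "g00001"]})
        res = pw.cerno_test(ranking, catalog)
        s_expected = -2 * (np.log(0.1) + np.log(0.2))
        assert res.loc["top2", "S"] == pytest.approx(s_expected, rel=1e-12)
        assert res.loc["top2", "S"] == pytest.approx(7.824, abs=5e-4)
        assert res.loc["top2", "df"] == 4
        assert res.loc["top2", "p"] == pytest.approx(
            sps.chi2.sf(s_expected, 4), rel=1e-12)

    def test_improving_a_member_rank_increases_s(self):
        base = _ranking(100)
        catalog = GeneSetCatalog(sets={"s": ["g00049"]})
        s_vals = []
        for target in ("g00049", "g00010", "g00000"):
            res = pw.cerno_test(base, GeneSetCatalog(sets={"s": [target]}))
            s_vals.append(res.loc["s", "S"])
        assert s_vals[0] < s_vals[1] < s_vals[2]
        p_vals = [sps.chi2.sf(s, 2) for s in s_vals]
        assert p_vals[0] > p_vals[1] > p_vals[2]

    def test_null_statistic_is_chi_square(self):
        rng = np.random.default_rng(71)
        ranking = _ranking(2000, rng)
        k = 10
        sets = {
            f"s{i}": list(rng.choice(ranking.index, k, replace=False))
            for i in range(500)
        }
        res = pw.cerno_test(ranking, GeneSetCatalog(sets=sets))
        ks = sps.kstest(res["S"], sps.chi2(2 * k).cdf)
        assert ks.pvalue > 0.01

    def test_chi_square_tail_against_exact_permutation_distribution(self):
        """chi2 tail vs exhaustive distinct-rank subsets.

        For k = 1 the chi-square tail is exact at every support point of
        any N.  For k > 1 the exact null samples ranks without
        replacement, so the chi-square approximation carries an O(k/N)
        discreteness error -- large for tiny N (up to ~0.14 at N = 12)
        and below 0.02 by N = 100, which is what the test pins down.
        """
        from itertools import combinations

        n = 12
        all_s1 = np.array([-2 * np.log(r / n) for r in range(1, n + 1)])
        for r in range(1, n + 1):
            s = -2 * np.log(r / n)
            exact = (all_s1 >= s - 1e-12).mean()
            assert abs(exact - sps.chi2.sf(s, 2)) < 1e-12

        n = 100
        for k in (2, 3):
            all_s = np.array([
                -2 * np.log(np.array(c) / n).sum()
                for c in combinations(range(1, n + 1), k)
            ])
            for s in np.quantile(all_s, np.linspace(0.01, 0.999, 25)):
                exact = (all_s >= s - 1e-12).mean()
                assert abs(exact - sps.chi2.sf(s, 2 * k)) < 0.02

    def test_empty_intersection_flagged_untestable(self):
        ranking = _ranking(10)
        catalog = GeneSetCatalog(sets={"ghost": ["nope"], "ok": ["g00000"]})
        res = pw.cerno_test(ranking, catalog)
        assert not res.loc["ghost", "testable"]
        assert np.isnan(res.loc["ghost", "q"])
        assert res.loc["ok", "q"] == pytest.approx(res.loc["ok", "p"])


class TestBhFdr:
    def test_hand_step_up_example(self):
        q = pw.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated_families(self):
        assert pw.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(pw.bh_fdr(np.ones(5)), np.ones(5))

    def test_against_brute_force_oracle_on_random_families(self):
        rng = np.random.default_rng(73)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            np.testing.assert_allclose(pw.bh_fdr(p), _bh_oracle(p), rtol=1e-12)

    def test_invalid_p_values_rejected(self):
        with pytest.raises(ValueError):
            pw.bh_fdr(np.array([0.1, 1.2]))


@pytest.fixture(scope="module")
def planted():
    cfg = pw.SimulationConfig(
        n_genes=1000, proportions=(0.10, 0, 0),
        effect_mean=3.0, effect_sd=0.25, noise_sd=0.2, seed=77,
    )
    expr, design, truth = pw.simulate_expression(cfg)
    catalog = pw.simulate_gene_sets(truth, n_sets=100, set_size=20,
                                    n_enriched=3, seed=78)
    stats = pw.fit_all_transcripts(expr, design, method="blocked")
    ranking = pw.compute_pwf(stats)["sorted"]
    results = pw.cerno_test(ranking, catalog)
    return truth, catalog, ranking, results


class TestSelectForDsm:
    def test_planted_sets_have_smallest_q(self, planted):
        truth, _, _, results = planted
        smallest = results.sort_values("q").index[:3]
        assert set(smallest) == set(truth.sets.index[truth.sets["enriched"]])

    def test_stricter_gene_quantile_only_shrinks_selection(self, planted):
        _, catalog, ranking, results = planted
        _, loose = pw.select_for_dsm(results, ranking, catalog,
                                     set_q_max=1e-2, gene_quantile_max=0.01)
        _, strict = pw.select_for_dsm(results, ranking, catalog,
                                      set_q_max=1e-2, gene_quantile_max=0.001)
        assert set(strict) <= set(loose)

    def test_boundary_q_excluded_under_strict_comparison(self, planted):
        _, catalog, ranking, results = planted
        results = results.copy()
        results["q"] = 1e-4
        sets, _ = pw.select_for_dsm(results, ranking, catalog, set_q_max=1e-4,
                                    gene_quantile_max=0.5)
        assert sets == []

    def test_empty_selection_warns_not_raises(self, planted):
        _, catalog, ranking, results = planted
        results = results.copy()
        results["q"] = 1.0
        with pytest.warns(UserWarning):
            sets, genes = pw.select_for_dsm(results, ranking, catalog)
        assert sets == [] and genes == []
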
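import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pwfrank as pw
from pwfrank.model import TERMS


def _stats_frame(f_rows, gene_ids=None, degenerate=None):
    n = len(f_rows)
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n)]
    f = np.asarray(f_rows, dtype=float)
    frame = pd.DataFrame(
        {f"F_{t}": f[:, j] for j, t in enumerate(TERMS)}, index=gene_ids
    )
    frame["fit_method"] = "blocked"
    frame["degenerate"] = degenerate if degenerate is not None else False
    frame["residual_df"] = 6
    return frame


class TestPwfFormula:
    def test_single_term_gene_keeps_its_full_f(self):
        assert pw.pwf_from_f(np.array([5.0, 0.0, 0.0])).tolist() == [5.0, 0.0, 0.0]

    def test_worked_triple(self):
        np.testing.assert_allclose(
            pw.pwf_from_f(np.array([9.0, 1.0, 0.0])), [8.1, 0.1, 0.0]
        )

    def test_all_zero_triple_gives_zero(self):
        assert pw.pwf_from_f(np.zeros(3)).tolist() == [0.0, 0.0, 0.0]

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=3, max_size=3))
    def test_pwf_bounded_by_f_and_total_by_max(self, f):
        f = np.array(f)
        pwf = pw.pwf_from_f(f)
        assert np.all(pwf <= f + 1e-9)
        assert pwf.sum() <= f.max() + 1e-9
        if f.sum() > 0:
            assert np.argmax(pwf) == np.argmax(f)


class TestComputePwf:
    def test_ranks_are_a_permutation_and_quantiles_scale(self, small_ranking):
        for term, frame in small_ranking.items():
            ranks = frame["rank"].dropna().to_numpy()
            assert sorted(ranks) == list(range(1, len(ranks) + 1))
            assert np.all(np.diff(frame["pwf"].dropna().to_numpy()) <= 1e-12)
            q = frame["quantile"].dropna()
            assert q.iloc[0] == pytest.approx(1 / len(ranks))
            assert q.iloc[-1] == pytest.approx(1.0)

    def test_tie_break_is_lexicographic_on_gene_id(self):
        stats = _stats_frame([[2, 0, 0]] * 3, gene_ids=["b", "a", "c"])
        ranking = pw.compute_pwf(stats)["sorted"]
        assert list(ranking.index[:3]) == ["a", "b", "c"]

    def test_degenerate_genes_ranked_last_and_excluded_from_n(self):
        stats = _stats_frame(
            [[4, 0, 0], [0, 0, 0], [9, 0, 0]],
            gene_ids=["a", "dead", "c"],
            degenerate=[False, True, False],
        )
        stats.loc["dead", [f"F_{t}" for t in TERMS]] = np.nan
        ranking = pw.compute_pwf(stats)["sorted"]
        assert list(ranking.index) == ["c", "a", "dead"]
        assert ranking.loc["c", "quantile"] == pytest.approx(0.5)
        assert np.isnan(ranking.loc["dead", "rank"])

    def test_argmax_term_preserved_between_f_and_pwf(self, small_ranking, small_dataset):
        expr, design, _ = small_dataset
        stats = pw.fit_all_transcripts(expr, design, method="blocked").sort_index()
        pwf = np.column_stack(
            [small_ranking[t].sort_index()["pwf"].to_numpy() for t in TERMS]
        )
        ok = ~stats["degenerate"].to_numpy()
        f = stats[[f"F_{t}" for t in TERMS]].to_numpy()
        assert np.all(np.argmax(f[ok], axis=1) == np.argmax(pwf[ok], axis=1))


class TestTopGenes:
    def test_boundaries(self, small_ranking):
        frame = small_ranking["sorted"]
        n = int(frame["rank"].notna().sum())
        assert pw.top_genes(frame, 0) == []
        assert len(pw.top_genes(frame, n)) == n
        with pytest.raises(IndexError):
            pw.top_genes(frame, n + 1)

    def test_top_k_recovers_planted_sorted_genes(self):
        cfg = pw.SimulationConfig(
            n_genes=1500, proportions=(0.10, 0, 0),
            effect_mean=2.0, effect_sd=0.25, noise_sd=0.25, seed=31,
        )
        expr, design, truth = pw.simulate_expression(cfg)
        stats = pw.fit_all_transcripts(expr, design, method="blocked")
        ranking = pw.compute_pwf(stats)["sorted"]
        top = pw.top_genes(ranking, 100)
        hits = (truth.genes.loc[top, "effect_class"] == "sorted").sum()
        assert hits >= 80

    def test_planted_mean_rank_below_20th_percentile(self):
        cfg = pw.SimulationConfig(
            n_genes=1000, proportions=(0.10, 0, 0),
            effect_mean=2.0, effect_sd=0.25, noise_sd=0.25, seed=37,
        )
        expr, design, truth = pw.simulate_expression(cfg)
        stats = pw.fit_all_transcripts(expr, design, method="blocked")
        ranking = pw.compute_pwf(stats)["sorted"]
        planted = truth.genes_of_class("sorted")
        mean_rank = ranking.loc[planted, "rank"].mean()
        assert mean_rank < 0.20 * len(expr)


class TestZscoreMatrix:
    def test_rows_standardized(self, design12):
        expr = pd.DataFrame([[1.0, 2.0, 3.0] * 4], index=["g"],
                            columns=design12.index)
        z = pw.zscore_matrix(expr, ["g"])
        assert z.loc["g"].mean() == pytest.approx(0.0)
        assert z.loc["g"].std(ddof=0) == pytest.approx(1.0)

    def test_shift_invariance_and_antisymmetry(self, design12, rng):
        values = rng.normal(7, 1, (3, 12))
        expr = pd.DataFrame(values, index=list("abc"), columns=design12.index)
        z = pw.zscore_matrix(expr, ["a", "b"])
        z_shift = pw.zscore_matrix(expr + 10, ["a", "b"])
        pd.testing.assert_frame_equal(z, z_shift)
        z_neg = pw.zscore_matrix(-expr, ["a", "b"])
        pd.testing.assert_frame_equal(z_neg, -z)

    def test_zero_variance_row_names_gene(self, design12):
        expr = pd.DataFrame(np.ones((1, 12)) * 5, index=["flat"],
                            columns=design12.index)
        with pytest.raises(ValueError, match="flat"):
            pw.zscore_matrix(expr, ["flat"])


class TestDifferentialMirna:
    def test_boundary_fold_change_fails_strict_filter(self, design12):
        pos = design12["sorted"] == "pos"
        base = np.where(pos, 0.5, -0.5)  # exact +1 log2 difference
        expr = pd.DataFrame(
            [7.0 + base + 1e-6 * np.arange(12)], index=["m"],
            columns=design12.index,
        )
        result = pw.differential_mirna(expr, design12)
        assert result.loc["m", "fold_change"] == pytest.approx(2.0, abs=1e-4)
        assert not bool(result.loc["m", "pass_flag"])

    def test_planted_mirna_passes(self, design12, rng):
        pos = design12["sorted"] == "pos"
        delta = np.where(pos, -2.27 / 2, 2.27 / 2)
        expr = pd.DataFrame([7.0 + delta + rng.normal(0, 0.01, 12)],
                            index=["mir146a"], columns=design12.index)
        result = pw.differential_mirna(expr, design12)
        assert result.loc["mir146a", "fold_change"] == pytest.approx(-4.82, abs=0.1)
        assert bool(result.loc["mir146a", "pass_flag"])

    def test_null_mirnas_essentially_never_pass(self, design12):
        rng = np.random.default_rng(41)
        expr = pd.DataFrame(rng.normal(7, 0.3, (10_000, 12)),
                            index=[f"m{i}" for i in range(10_000)],
                            columns=design12.index)
        result = pw.differential_mirna(expr, design12)
        assert result["pass_flag"].sum() == 0

    def test_insufficient_replication_rejected(self, design12, rng):
        sub = design12.iloc[[0, 1, 2, 3, 4]]  # one pos sample only? build explicit
        sub = design12[design12["sorted"] == "neg"].iloc[:4]
        one_pos = design12[design12["sorted"] == "pos"].iloc[:1]
        design = pd.concat([sub, one_pos])
        expr = pd.DataFrame(rng.normal(7, 1, (3, len(design))),
                            index=list("abc"), columns=design.index)
        with pytest.raises(ValueError, match="2 samples"):
            pw.differential_mirna(expr, design)
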
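"""Z-scores, gene-set statistics, rank tests and FDR utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from txfeedback import (bh_adjust, compute_zscores, gene_correlation_profile,
                        gene_set_statistic, pearson_test, resolve_gene_sets,
                        tf_association, wilcoxon_rank_sum)
from txfeedback.errors import InputError
from txfeedback.factorization import FactorizationResult


def _result_from_draws(draws):
    """Minimal FactorizationResult carrying only amplitude draws."""
    draws = [np.asarray(a, dtype=float) for a in draws]
    g, k = draws[0].shape
    A = pd.DataFrame(draws[0], index=[f"g{i}" for i in range(g)],
                     columns=[f"pattern_{j+1}" for j in range(k)])
    P = pd.DataFrame(np.full((k, 2), 0.5), index=A.columns, columns=["c1", "c2"])
    return FactorizationResult(A=A, P=P, samples=[(d, P.to_numpy()) for d in draws],
                               k=k, chi2=0.0, seed=0, n_iter=1)


class TestZscores:
    def test_mean_over_sd(self):
        res = _result_from_draws([[[1.0]], [[2.0]], [[3.0]]])
        assert compute_zscores(res).iloc[0, 0] == pytest.approx(2.0)

    def test_constant_draws_large_finite(self):
        res = _result_from_draws([[[2.0]], [[2.0]], [[2.0]]])
        z = compute_zscores(res).iloc[0, 0]
        assert np.isfinite(z) and z > 1e6

    def test_all_zero_draws_give_zero(self):
        res = _result_from_draws([[[0.0]], [[0.0]]])
        assert compute_zscores(res).iloc[0, 0] == 0.0

    def test_requires_two_draws(self):
        res = _result_from_draws([[[1.0]]])
        with pytest.raises(InputError):
            compute_zscores(res)


@pytest.fixture(scope="module")
def Z():
    rng = np.random.default_rng(4)
    return pd.DataFrame({"p1": rng.normal(size=10)},
                        index=[f"g{i}" for i in range(10)])


class TestGeneSetStatistic:

    def test_top_gene_singleton_matches_enumeration(self, Z):
        top = Z["p1"].idxmax()
        res = gene_set_statistic(Z, {top}, "p1", n_perm=10_000, seed=1)
        # exact: 1 of 10 singletons reaches the maximum
        assert res.p_value == pytest.approx(0.1, abs=0.02)

    def test_whole_universe_is_null(self, Z):
        res = gene_set_statistic(Z, set(Z.index), "p1", n_perm=500, seed=1)
        assert res.p_value == 1.0

    def test_invariant_to_nonmember_relabeling(self, Z):
        members = {"g0", "g3"}
        res1 = gene_set_statistic(Z, members, "p1", n_perm=2000, seed=5)
        relabeled = Z.rename(index={g: g + "_x" for g in Z.index if g not in members})
        res2 = gene_set_statistic(relabeled, members, "p1", n_perm=2000, seed=5)
        assert res1.p_value == res2.p_value
        assert res1.statistic == res2.statistic

    def test_empty_intersection_rejected(self, Z):
        with pytest.raises(InputError):
            gene_set_statistic(Z, {"absent"}, "p1")

    def test_few_permutations_flagged(self, Z):
        res = gene_set_statistic(Z, {"g0"}, "p1", n_perm=50, seed=0)
        assert "few_permutations" in res.flags


class TestCorrelationProfile:
    def test_identical_and_scaled_rows(self):
        Z = pd.DataFrame([[1.0, 2, 3], [1, 2, 3], [2, 4, 6], [3, 2, 1]],
                         index=["q", "same", "scaled", "reversed"])
        r = gene_correlation_profile(Z, "q")
        assert r["same"] == pytest.approx(1.0)
        assert r["scaled"] == pytest.approx(1.0)
        assert r["reversed"] == pytest.approx(-1.0)
        assert "q" not in r.index

    def test_zero_variance_row_missing(self):
        Z = pd.DataFrame([[1.0, 2, 3], [5, 5, 5]], index=["q", "flat"])
        assert np.isnan(gene_correlation_profile(Z, "q")["flat"])

    def test_unknown_query_rejected(self):
        Z = pd.DataFrame([[1.0, 2.0]], index=["g"])
        with pytest.raises(InputError):
            gene_correlation_profile(Z, "nope")


class TestTfAssociation:
    def test_top_targets_exact_p(self):
        corr = pd.Series([0.9, 0.8, 0.3, 0.2, 0.1],
                         index=["a", "b", "c", "d", "e"])
        sets = {"TF": {"a", "b", "q"}}
        table = tf_association(corr, sets, "q")
        assert table.loc[0, "p_value"] == pytest.approx(0.1)  # 1 / C(5,2)

    def test_all_tied_gives_p_one(self):
        corr = pd.Series([0.5] * 6, index=list("abcdef"))
        table = tf_association(corr, {"TF": {"a", "b", "q"}}, "q")
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_value_irrelevant(self):
        corr = pd.Series([0.9, 0.8, 0.3, 0.2, 0.1, -5.0],
                         index=["a", "b", "c", "d", "e", "q"])
        t1 = tf_association(corr, {"TF": {"a", "b", "q"}}, "q")
        corr2 = corr.copy()
        corr2["q"] = 99.0
        t2 = tf_association(corr2, {"TF": {"a", "b", "q"}}, "q")
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_annotating_tf_returns_empty(self):
        corr = pd.Series([0.1], index=["a"])
        table = tf_association(corr, {"TF": {"a"}}, "q")
        assert table.empty

    def test_planted_tf_ranks_first(self, fit_result, truth):
        Z = compute_zscores(fit_result)
        ref = truth.signature_truth["reference"]
        sets = resolve_gene_sets(truth.tf_targets, set(Z.index) | {ref})
        table = tf_association(gene_correlation_profile(Z, ref), sets, ref)
        assert len(table) >= 2          # decoy TF also annotates the reference
        assert table.loc[0, "tf"] == "AP2A"
        assert table.loc[0, "p_value"] < 0.05


class TestWilcoxon:
    def test_exact_examples(self):
        assert wilcoxon_rank_sum([0.9, 0.8], [0.1, 0.2, 0.3], "greater")[1] \
            == pytest.approx(0.1)
        assert wilcoxon_rank_sum([5], [1, 2, 3], "greater")[1] == pytest.approx(0.25)

    def test_identical_samples_tied_two_sided(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two-sided")
        assert p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10_000),
           st.sampled_from(["greater", "less", "two-sided"]))
    def test_exact_path_matches_reference_distribution(self, nx, ny, seed, alt):
        rng = np.random.default_rng(seed)
        pooled = rng.normal(size=nx + ny)
        x, y = pooled[:nx], pooled[nx:]
        u, p = wilcoxon_rank_sum(x, y, alt)
        ref = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_boundary(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pooled = rng.normal(size=12)
            x, y = pooled[:6], pooled[6:]
            _, p_exact = wilcoxon_rank_sum(x, y, "greater")
            p_asym = stats.mannwhitneyu(x, y, alternative="greater",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_rank_sum([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_test([1, 2, 3, 4], [3, 5, 7, 9], "greater")
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        r, _ = pearson_test([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            pearson_test([1, 2], [3, 4])


class TestBH:
    def test_worked_example(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_dominates_raw_and_monotone(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
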
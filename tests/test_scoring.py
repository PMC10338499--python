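"""Filtering, rank transform, interaction strength and permutation p-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lrcomm as lc


def scalar_is(r1: float, r2: float) -> float:
    """Independent scalar oracle for the interaction strength."""
    return (r1 + r2) * (10.0 - abs(r1 - r2))


def scalar_rank_scores(values) -> list[float]:
    """Independent rank-score oracle: descending positions with average
    ties, scaled so the top gene scores 10 and the bottom 10/G."""
    vals = list(values)
    G = len(vals)
    order = sorted(range(G), key=lambda i: -vals[i])
    pos = [0.0] * G
    i = 0
    while i < G:
        j = i
        while j + 1 < G and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average position of the tie block
        for k in range(i, j + 1):
            pos[order[k]] = avg
        i = j + 1
    return [10.0 * (G - p + 1.0) / G for p in pos]


class TestFilterGenes:
    def test_gene_above_threshold_removed(self):
        x = pd.DataFrame(np.ones((10, 10)), index=[f"g{i}" for i in range(10)])
        x.iloc[0, :4] = 0.0  # 40% zeros
        out = lc.filter_genes(x)
        assert out.shape[0] == 9 and "g0" not in out.index

    def test_exact_boundary_retained(self):
        x = pd.DataFrame(np.ones((5, 10)), index=[f"g{i}" for i in range(5)])
        x.iloc[0, :3] = 0.0  # exactly 30%
        assert "g0" in lc.filter_genes(x).index

    def test_no_zeros_identity(self, small_expr):
        pd.testing.assert_frame_equal(lc.filter_genes(small_expr), small_expr)

    def test_all_removed_is_error(self):
        x = pd.DataFrame(np.zeros((3, 10)))
        with pytest.raises(ValueError, match="all 3 genes removed"):
            lc.filter_genes(x)


class TestRankTransform:
    def test_five_distinct_values(self):
        df = pd.DataFrame({"s": [50.0, 40, 30, 20, 10]}, index=list("abcde"))
        assert lc.rank_transform(df)["s"].tolist() == [10.0, 8.0, 6.0, 4.0, 2.0]

    def test_tie_at_top_gets_average_position(self):
        df = pd.DataFrame({"s": [9.0, 9.0, 3, 2, 1]}, index=list("abcde"))
        r = lc.rank_transform(df)["s"]
        assert r.iloc[0] == r.iloc[1] == 9.0

    def test_constant_sample_all_average(self):
        df = pd.DataFrame({"s": [7.0, 7, 7, 7]}, index=list("abcd"))
        assert (lc.rank_transform(df)["s"] == 6.25).all()

    def test_single_gene_degenerate(self):
        with pytest.raises(ValueError, match="at least 2 genes"):
            lc.rank_transform(pd.DataFrame({"s": [1.0]}, index=["a"]))

    def test_monotone_nondecreasing_in_expression_and_bounds(self, small_expr):
        r = lc.rank_transform(small_expr)
        G = small_expr.shape[0]
        for col in small_expr:
            order = small_expr[col].sort_values().index
            assert r[col].loc[order].is_monotonic_increasing
            assert r[col].max() == 10.0
            assert r[col].min() == pytest.approx(10.0 / G)

    def test_matches_scalar_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=(12, 4)).astype(float)  # many ties
        df = pd.DataFrame(x)
        r = lc.rank_transform(df).to_numpy()
        for j in range(4):
            assert r[:, j] == pytest.approx(scalar_rank_scores(x[:, j]))


class TestInteractionStrength:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [(10, 10, 200.0), (5, 5, 100.0), (10, 1e-9, pytest.approx(0.0, abs=1e-6))],
    )
    def test_analytic_values(self, r1, r2, expected):
        assert lc.interaction_strength(r1, r2) == expected

    @given(
        st.floats(min_value=0.001, max_value=10.0),
        st.floats(min_value=0.001, max_value=10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_bounds(self, r1, r2):
        a = lc.interaction_strength(r1, r2)
        assert a == lc.interaction_strength(r2, r1)
        assert 0.0 <= a <= 200.0
        assert a == pytest.approx(scalar_is(r1, r2))

    def test_maximum_only_at_double_top(self):
        assert lc.interaction_strength(10, 10) == 200.0
        for r1, r2 in [(10, 9.99), (9.99, 9.99), (10, 5)]:
            assert lc.interaction_strength(r1, r2) < 200.0

    def test_strictly_increasing_on_diagonal(self):
        rs = np.linspace(0.5, 10, 20)
        vals = [lc.interaction_strength(r, r) for r in rs]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals == pytest.approx([20.0 * r for r in rs])  # closed form 2r*10

    def test_out_of_range_rejected(self):
        for bad in [(0.0, 5.0), (11.0, 5.0), (-1.0, 5.0), (5.0, 10.5)]:
            with pytest.raises(ValueError, match=r"\(0, 10\]"):
                lc.interaction_strength(*bad)

    def test_vectorized_equals_scalar_loop(self):
        """Vectorized IS over all gene pairs of random 20x5 matrices equals
        a per-element scalar loop exactly."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            x = rng.lognormal(1, 1, size=(20, 5))
            r = lc.rank_transform(pd.DataFrame(x)).to_numpy()
            for i in range(20):
                for j in range(i + 1, 20):
                    vec = lc.interaction_strength(r[i], r[j])
                    for n in range(5):
                        assert vec[n] == scalar_is(r[i, n], r[j, n])


class TestScorePairs:
    def test_requires_seed_and_positive_nperm(self, small_expr):
        with pytest.raises(ValueError, match="seed"):
            lc.score_pairs(small_expr, [("g0", "g1")], n_perm=10, seed=None)
        with pytest.raises(ValueError, match="n_perm"):
            lc.score_pairs(small_expr, [("g0", "g1")], n_perm=0, seed=1)

    def test_minimum_cohort_size_enforced(self, small_expr):
        with pytest.raises(ValueError, match="at least 6"):
            lc.score_pairs(small_expr.iloc[:, :5], [("g0", "g1")], n_perm=10, seed=1)

    def test_absent_gene_skipped_with_reason(self, small_expr):
        run = lc.score_pairs(small_expr, [("g0", "nope")], n_perm=10, seed=1)
        assert not run.scores
        assert run.skipped[0][0] == ("g0", "nope")
        assert "nope" in run.skipped[0][1]

    def test_extreme_p_has_add_one_correction(self):
        """A pair outscoring all 200 null draws gets p = 1/201."""
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.2, size=(50, 10))
        x[0], x[1] = 1e4, 1e4  # tied top pair in every sample
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
        run = lc.score_pairs(df, [("g0", "g1")], n_perm=200, seed=2)
        assert run.scores[0].p_value == pytest.approx(1 / 201)

    def test_double_top_pair_attains_tied_maximum(self):
        """Two genes tied at the top of every sample attain the maximal
        summary strength for a tied pair, 200*(G-0.5)/G."""
        rng = np.random.default_rng(6)
        G = 50
        x = rng.lognormal(0, 0.2, size=(G, 8))
        x[0], x[1] = 1e4, 1e4
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(G)])
        run = lc.score_pairs(df, [("g0", "g1")], n_perm=10, seed=2)
        r_tied = 10.0 * (G - 1.5 + 1.0) / G
        assert run.scores[0].summary_is == pytest.approx(2 * r_tied * 10.0)

    def test_p_value_matches_scalar_brute_force(self):
        """Fixed-seed 50-gene x 10-sample fixture: p-values equal an
        independent scalar recomputation using the documented null
        protocol (default_rng([seed, k]) per pair)."""
        rng = np.random.default_rng(9)
        x = rng.lognormal(1, 1, size=(50, 10))
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
        pairs = [("g0", "g1"), ("g5", "g40"), ("g12", "g12")]
        seed, n_perm = 123, 200
        run = lc.score_pairs(df, pairs, n_perm=n_perm, seed=seed)

        ranks = [scalar_rank_scores(x[:, n]) for n in range(10)]  # per sample
        idx = {f"g{i}": i for i in range(50)}
        for k, (g1, g2) in enumerate(pairs):
            i, j = idx[g1], idx[g2]
            obs = sum(scalar_is(ranks[n][i], ranks[n][j]) for n in range(10)) / 10
            prng = np.random.default_rng([seed, k])
            a = prng.integers(0, 50, size=n_perm)
            b = prng.integers(0, 50, size=n_perm)
            bad = (a == b) | ((a == i) & (b == j))
            while bad.any():
                nb = int(bad.sum())
                a[bad] = prng.integers(0, 50, size=nb)
                b[bad] = prng.integers(0, 50, size=nb)
                bad = (a == b) | ((a == i) & (b == j))
            hits = 0
            for t in range(n_perm):
                null = sum(
                    scalar_is(ranks[n][a[t]], ranks[n][b[t]]) for n in range(10)
                ) / 10
                hits += null >= obs
            expected_p = (1 + hits) / (n_perm + 1)
            assert run.scores[k].summary_is == pytest.approx(obs)
            assert run.scores[k].p_value == pytest.approx(expected_p)

    def test_p_independent_of_pair_list_context(self, planted_fixture):
        expr, manifest = planted_fixture
        solo = lc.score_pairs(expr, manifest[:1], n_perm=50, seed=4)
        batch = lc.score_pairs(expr, manifest[:5], n_perm=50, seed=4)
        assert solo.scores[0].p_value == batch.scores[0].p_value

    def test_rank_invariance_under_monotone_transform(self, planted_fixture):
        """Scoring on FPKM and on log2(FPKM+0.05) gives identical results."""
        expr, manifest = planted_fixture
        runs = [
            lc.score_pairs(m, manifest[:5], n_perm=50, seed=8)
            for m in (expr, lc.normalize_log2(expr))
        ]
        for s_raw, s_log in zip(runs[0].scores, runs[1].scores):
            assert s_raw.summary_is == s_log.summary_is
            assert s_raw.p_value == s_log.p_value

    def test_lower_tail_alternative_flips(self, planted_fixture):
        expr, manifest = planted_fixture
        hi = lc.score_pairs(expr, manifest[:1], n_perm=100, seed=3)
        lo = lc.score_pairs(expr, manifest[:1], n_perm=100, seed=3, alternative="less")
        assert hi.scores[0].p_value < 0.05
        assert lo.scores[0].p_value > 0.9


class TestScoreReferenceSets:
    def _expr(self):
        spec = lc.FixtureSpec(seed=21, n_genes=80, n_samples=10, n_planted_pairs=5)
        return lc.make_expression(spec)

    def test_alpha_one_accepts_all_and_zero_none(self):
        expr, manifest = self._expr()
        for alpha, expected in [(1.0, 5), (0.0, 0)]:
            out = lc.score_reference_sets(
                expr, manifest, manifest, alpha=alpha, n_perm=30, seed=2
            )
            assert out["curated"]["n_significant"] == expected

    def test_significant_count_matches_direct_recount(self):
        expr, manifest = self._expr()
        out = lc.score_reference_sets(
            expr, manifest, manifest, alpha=0.05, n_perm=200, seed=2
        )
        table = out["lr"]["table"]
        assert out["lr"]["n_significant"] == int((table["p_value"] <= 0.05).sum())

    def test_empty_reference_rejected(self):
        expr, manifest = self._expr()
        with pytest.raises(ValueError, match="empty"):
            lc.score_reference_sets(expr, [], manifest, n_perm=10, seed=1)
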
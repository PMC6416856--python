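import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wormlife import fecundity
from wormlife.fecundity import (
    brood_fraction_table,
    brood_fractions,
    brood_summary,
    fisher_exact,
    lifetime_broods,
    rank_sum_test,
)


def brute_force_ranksum_p(x, y):
    """Exact permutation two-sided p for the rank-sum test, by enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = np.delete(pooled, list(first_idx))
        gt = (first[:, None] > rest[None, :]).sum()
        eq = (first[:, None] == rest[None, :]).sum()
        return gt + eq / 2.0

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in itertools.combinations(range(n), n1)])
    mu = n1 * (n - n1) / 2.0
    if u_obs >= mu:
        p = 2.0 * np.mean(us >= u_obs - 1e-9)
    else:
        p = 2.0 * np.mean(us <= u_obs + 1e-9)
    return min(1.0, p)


class TestRankSum:
    def test_small_example_exact(self):
        res = rank_sum_test([3, 4], [1, 2])
        assert res.u_first == 4
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_complete_ties(self):
        res = rank_sum_test([1, 1], [1, 1])
        assert res.u_first == 2
        assert res.p_value == 1.0

    def test_u_statistics_are_complementary(self, rng):
        x = rng.integers(0, 50, 23)
        y = rng.integers(0, 50, 17)
        fwd = rank_sum_test(x, y)
        rev = rank_sum_test(y, x)
        assert fwd.u_first + rev.u_first == 23 * 17

    @given(
        x=st.lists(st.integers(0, 40), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 40), min_size=1, max_size=5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, x, y):
        res = rank_sum_test(x, y)
        expected = brute_force_ranksum_p(x, y)
        n1, n2 = len(x), len(y)
        u_pairs = sum(
            1.0 if xv > yv else 0.5 if xv == yv else 0.0
            for xv in x for yv in y
        )
        assert res.u_first == pytest.approx(u_pairs)
        assert 0 <= res.u_first <= n1 * n2
        if res.method == "exact":
            assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_exact_agrees_with_scipy(self, rng):
        vals = rng.choice(10000, 27, replace=False).astype(float)
        x, y = vals[:12], vals[12:]
        res = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u_first == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approx_close_to_scipy_with_ties(self, rng):
        x = rng.integers(0, 10, 60)
        y = rng.integers(2, 12, 55)
        res = rank_sum_test(x, y)
        assert res.method == "normal_approx"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])


class TestFisherExact:
    def test_published_cross_failure_table(self):
        res = fisher_exact([[10, 20], [5, 25]])
        assert round(res.odds_ratio_cmle, 2) == 2.46
        assert round(res.p_two_sided, 2) == 0.23

    def test_proportional_table_is_null(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.odds_ratio_cmle == pytest.approx(1.0, abs=1e-9)
        assert res.p_two_sided == 1.0

    def test_diagonal_table_enumeration(self):
        res = fisher_exact([[3, 0], [0, 3]])
        assert res.p_two_sided == pytest.approx(2 / 20)
        assert np.isinf(res.odds_ratio_cmle) and res.or_undefined

    def test_zero_margin_flagged(self):
        res = fisher_exact([[0, 0], [3, 5]])
        assert res.p_two_sided == 1.0
        assert res.or_undefined

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_p_matches_hypergeometric_enumeration(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        res = fisher_exact([[a, b], [c, d]])
        n, r1, c1 = a + b + c + d, a + b, a + c
        support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
        probs = stats.hypergeom.pmf(support, n, r1, c1)
        p_obs = probs[support == a][0]
        expected = probs[probs <= p_obs * (1 + 1e-7)].sum()
        assert res.p_two_sided == pytest.approx(min(1.0, expected), abs=1e-10)

    @given(
        a=st.integers(1, 15), b=st.integers(1, 15),
        c=st.integers(1, 15), d=st.integers(1, 15),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_or_cmle_matches_scipy_conditional(self, a, b, c, d):
        res = fisher_exact([[a, b], [c, d]])
        from scipy.stats.contingency import odds_ratio

        ref = odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        if np.isfinite(ref) and not res.or_undefined:
            assert res.odds_ratio_cmle == pytest.approx(ref, rel=1e-6)

    def test_cmle_solves_conditional_score_equation(self):
        from wormlife.fecundity import _conditional_mean, _support_logw

        tab = np.array([[10, 20], [5, 25]])
        res = fisher_exact(tab)
        support, logw = _support_logw(tab)
        mean = _conditional_mean(support, logw, np.log(res.odds_ratio_cmle))
        assert mean == pytest.approx(10.0, abs=1e-8)


class TestBroodSchedules:
    def test_single_day_layer(self):
        assert brood_fractions([40, 0, 0]).tolist() == [1.0, 0.0, 0.0]

    def test_even_split(self):
        assert brood_fractions([10, 10]).tolist() == [0.5, 0.5]

    def test_fractions_sum_to_one(self, rng):
        counts = rng.integers(0, 30, 8)
        counts[0] += 1
        assert brood_fractions(counts).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_brood_rejected(self):
        with pytest.raises(ValueError):
            brood_fractions([0, 0])

    def _frame(self):
        rows = []
        for fid, sp, counts in [
            ("f1", "A", [5, 5]),
            ("f2", "A", [0, 0]),
            ("f3", "B", [10, 2, 2]),
        ]:
            for d, c in enumerate(counts, start=1):
                rows.append((fid, sp, d, c))
        return pd.DataFrame(rows,
                            columns=["female_id", "species", "day", "count"])

    def test_lifetime_broods(self):
        broods = lifetime_broods(self._frame())
        assert broods.set_index("female_id")["lifetime_brood"].to_dict() == {
            "f1": 10, "f2": 0, "f3": 14,
        }

    def test_summary_with_and_without_failed(self):
        df = self._frame()
        all_in = brood_summary(df, drop_failed=False)
        assert all_in.set_index("species")["median_brood"]["A"] == 5.0
        dropped = brood_summary(df, drop_failed=True)
        assert dropped.set_index("species")["median_brood"]["A"] == 10.0
        assert dropped.set_index("species")["n"]["A"] == 1

    def test_fraction_table_excludes_zero_brood_females(self):
        frac = brood_fraction_table(self._frame())
        assert "f2" not in set(frac["female_id"])
        sums = frac.groupby("female_id")["fraction"].sum()
        assert np.allclose(sums, 1.0)
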
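"""Exact-mode tests against brute-force enumeration, plus calibration."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from rmscape.stats import (bh_adjust, binomial_test, chi_square,
                           co_occurrence_test, mann_whitney_u,
                           rank_correlation)


def brute_spearman_p(x, y, sidedness="two"):
    def rho(a, b):
        ra, rb = rankdata(a), rankdata(b)
        ra, rb = ra - ra.mean(), rb - rb.mean()
        return float((ra * rb).sum()
                     / np.sqrt((ra ** 2).sum() * (rb ** 2).sum()))
    obs = rho(x, y)
    vals = [rho(x, p) for p in itertools.permutations(y)]
    eps = 1e-12
    if sidedness == "two":
        return np.mean([abs(v) >= abs(obs) - eps for v in vals])
    return np.mean([v >= obs - eps for v in vals])


def brute_mww_p(a, b, sidedness="two"):
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u1(sel):
        ranks = rankdata(pooled)
        mask = np.zeros(len(pooled), bool)
        mask[list(sel)] = True
        return ranks[mask].sum() - n1 * (n1 + 1) / 2

    obs = u1(range(n1))
    us = [u1(sel) for sel in
          itertools.combinations(range(len(pooled)), n1)]
    eps = 1e-9
    p_ge = np.mean([u >= obs - eps for u in us])
    p_le = np.mean([u <= obs + eps for u in us])
    if sidedness == "two":
        return min(1.0, 2 * min(p_ge, p_le))
    return p_ge if sidedness == "greater" else p_le


class TestSpearman:
    def test_perfect_monotone(self):
        assert rank_correlation([1, 2, 3], [10, 20, 30]).statistic == 1.0
        assert rank_correlation([1, 2, 3], [30, 20, 10]).statistic == -1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_equals_full_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = rank_correlation(x, y)
        assert res.method == "spearman_exact"
        assert res.p_value == pytest.approx(brute_spearman_p(x, y))

    def test_exact_handles_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 1.0, 3.0, 5.0]
        res = rank_correlation(x, y)
        assert res.p_value == pytest.approx(brute_spearman_p(x, y))

    def test_constant_vector_is_undefined(self):
        res = rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=5, max_size=7,
                    unique=True))
    def test_invariant_under_monotone_transform(self, x):
        y = list(range(len(x)))
        r1 = rank_correlation(x, y)
        r2 = rank_correlation(np.exp(np.array(x) / 100), y)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestMannWhitney:
    def test_two_vs_two_exact_third(self):
        # U is extreme in 2 of the 6 label assignments: two-sided p = 1/3
        assert mann_whitney_u([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed,sidedness",
                             [(0, "two"), (1, "greater"), (2, "less")])
    def test_exact_equals_enumeration_no_ties(self, seed, sidedness):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=6)
        res = mann_whitney_u(a, b, sidedness)
        assert res.method == "mww_exact"
        assert res.p_value == pytest.approx(brute_mww_p(a, b, sidedness))

    def test_exact_equals_enumeration_with_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 3.0]
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(brute_mww_p(a, b))

    def test_power_under_shift_alternative(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(500):
            a = rng.normal(1.0, 1.0, size=30)
            b = rng.normal(0.0, 1.0, size=30)
            hits += mann_whitney_u(a, b).p_value < 0.05
        assert hits / 500 > 0.8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=6, unique=True),
           st.lists(st.integers(-50, 50), min_size=3, max_size=6, unique=True))
    def test_invariant_under_monotone_transform(self, a, b):
        r1 = mann_whitney_u(a, b)
        f = lambda v: np.arctan(np.array(v) / 50)
        r2 = mann_whitney_u(f(a), f(b))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestChiSquare:
    def test_textbook_statistic(self):
        res = chi_square([10, 10], [5, 15])
        assert res.statistic == pytest.approx(25 / 5 + 25 / 15)

    def test_observed_equals_expected(self):
        res = chi_square([7, 7, 7], [7, 7, 7])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(ValueError, match="merge"):
            chi_square([1, 2], [0, 3])

    @pytest.mark.parametrize("table", [[[16, 4], [6, 14]],
                                       [[15, 5], [7, 13]],
                                       [[14, 6], [5, 15]]])
    def test_independence_tail_p_tracks_fixed_margin_enumeration(self, table):
        """In the rejection tail the asymptotic 2x2 independence p agrees
        with full enumeration of tables with fixed margins at n = 40 (near
        the null the discreteness of the conditional distribution dominates
        and no continuous approximation can track it)."""
        from scipy.stats import hypergeom
        t = np.array(table)
        res = chi_square(contingency=t)
        r1, r2 = t.sum(1)
        c1 = t.sum(0)[0]
        n = t.sum()

        def stat(a):
            tt = np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]], float)
            e = np.outer(tt.sum(1), tt.sum(0)) / n
            return ((tt - e) ** 2 / e).sum()

        p_exact = sum(hypergeom.pmf(a, n, r1, c1)
                      for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                      if stat(a) >= res.statistic - 1e-9)
        assert res.p_value < 0.1  # tail case by construction
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_independence_null_calibration_2x2(self):
        rng = np.random.default_rng(56)
        rej = n_ok = 0
        for _ in range(500):
            t = rng.multinomial(40, [0.25] * 4).reshape(2, 2)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            n_ok += 1
            rej += chi_square(contingency=t).p_value <= 0.05
        assert 0.02 <= rej / n_ok <= 0.08


class TestBinomial:
    def test_ten_of_ten_one_sided(self):
        res = binomial_test(10, 10, 0.5, "greater")
        assert res.p_value == pytest.approx(0.5 ** 10)

    def test_k_at_expectation_one_sided_above_half(self):
        assert binomial_test(5, 10, 0.5, "greater").p_value > 0.5

    @pytest.mark.parametrize("k,n,p0", [(3, 12, 0.25), (7, 9, 0.5),
                                        (0, 6, 0.4)])
    def test_matches_direct_pmf_summation(self, k, n, p0):
        res = binomial_test(k, n, p0, "greater")
        direct = sum(comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
                     for i in range(k, n + 1))
        assert res.p_value == pytest.approx(direct)

    def test_p0_outside_unit_interval_is_error(self):
        with pytest.raises(ValueError):
            binomial_test(1, 2, 1.5)


class TestTypeIError:
    """Rejection rate at nominal 0.05 stays within [0.03, 0.07]."""

    N_SIMS = 1000

    def test_spearman(self):
        rng = np.random.default_rng(101)
        rej = sum(rank_correlation(rng.normal(size=30),
                                   rng.normal(size=30)).p_value <= 0.05
                  for _ in range(self.N_SIMS))
        assert 0.03 <= rej / self.N_SIMS <= 0.07

    def test_mann_whitney_exact(self):
        rng = np.random.default_rng(102)
        rej = sum(mann_whitney_u(rng.normal(size=8),
                                 rng.normal(size=8)).p_value <= 0.05
                  for _ in range(self.N_SIMS))
        assert 0.03 <= rej / self.N_SIMS <= 0.07

    def test_chi_square(self):
        rng = np.random.default_rng(103)
        rej = sum(chi_square(rng.multinomial(200, [0.25] * 4),
                             [50.0] * 4).p_value <= 0.05
                  for _ in range(self.N_SIMS))
        assert 0.03 <= rej / self.N_SIMS <= 0.07

    def test_binomial(self):
        # n = 250: the exact test's achievable size is 0.0497, essentially
        # nominal (discreteness pushes smaller n below the band)
        rng = np.random.default_rng(104)
        rej = sum(binomial_test(int(k), 250, 0.5).p_value <= 0.05
                  for k in rng.binomial(250, 0.5, size=self.N_SIMS))
        assert 0.03 <= rej / self.N_SIMS <= 0.07


class TestCoOccurrence:
    def _data(self, rng, shift=0.0, n=50):
        counts, flag, sizes = {}, {}, {}
        for i in range(2 * n):
            g = f"g{i:03d}"
            flag[g] = i < n
            counts[g] = rng.poisson(3) + (shift if flag[g] else 0)
            sizes[g] = 1.0 if i % 2 else 3.0
        return counts, flag, sizes

    def test_boundary_genome_goes_to_large_stratum(self):
        counts = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0}
        flag = {"a": True, "b": False, "c": True, "d": False}
        sizes = {"a": 2.0, "b": 2.5, "c": 1.0, "d": 1.9}
        df = co_occurrence_test(counts, flag, sizes)
        large = df[df.stratum == "large"].iloc[0]
        assert large["n_flagged"] + large["n_unflagged"] == 2  # a and b

    def test_shifted_counts_detected(self):
        rng = np.random.default_rng(7)
        counts, flag, sizes = self._data(rng, shift=2.0)
        df = co_occurrence_test(counts, flag, sizes)
        assert (df["p_value"] < 0.01).all()

    def test_null_p_uniformity_ks(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            counts, flag, sizes = self._data(rng, n=25)
            # continuity: add jitter so the discrete MWW p is ~uniform
            counts = {g: c + rng.normal(0, 0.01) for g, c in counts.items()}
            df = co_occurrence_test(counts, flag, sizes)
            pvals.extend(df["p_value"].dropna().tolist())
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_reported_without_test(self):
        counts = {"a": 1.0, "b": 2.0}
        flag = {"a": True, "b": True}
        sizes = {"a": 1.0, "b": 1.0}
        df = co_occurrence_test(counts, flag, sizes)
        assert df["method"].eq("none").all()


def test_bh_adjustment_is_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    adj = bh_adjust(p)
    assert (adj >= p).all()
    assert (adj <= 1).all()
    assert list(adj[np.argsort(p)]) == sorted(adj)
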
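"""Nonparametric tests used by the association analyses.

Small samples get exact p-values (full enumeration of the permutation /
combination null); larger samples use the standard approximations
(t-approximation for Spearman, tie-corrected normal approximation for
Mann-Whitney, the chi-square distribution, exact binomial tail sums at
any n).  Two-sided is the default everywhere except where a directional
claim is being tested (the per-species region-size comparison).

No multiple-testing correction is applied to the reported p-values; a
Benjamini-Hochberg column can be attached to result tables for
transparency but never gates any result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_N_MAX = 8          # exact Spearman enumeration bound (n!)
EXACT_COMB_MAX = 20000   # exact Mann-Whitney enumeration bound (C(n, n1))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    sidedness: str = "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def rank_correlation(x, y, sidedness: str = "two") -> TestResult:
    """Spearman's rho with average ranks for ties.

    Exact permutation p for n <= 8 (all n! orderings of y); the
    t-approximation otherwise.  A constant input vector yields an
    undefined (NaN) rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    n = len(x)
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return TestResult(rho, float("nan"), "spearman", (n,), sidedness)
    if n <= EXACT_N_MAX:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(ry)))
        cx = rx - rx.mean()
        cp = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((cx ** 2).sum() * (cp ** 2).sum(axis=1))
        rhos = (cp @ cx) / denom
        eps = 1e-12
        if sidedness == "two":
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
        elif sidedness == "greater":
            p = float(np.mean(rhos >= rho - eps))
        else:
            p = float(np.mean(rhos <= rho + eps))
        return TestResult(rho, p, "spearman_exact", (n,), sidedness)
    t = rho * sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
    if sidedness == "two":
        p = 2 * sps.t.sf(abs(t), n - 2)
    elif sidedness == "greater":
        p = sps.t.sf(t, n - 2)
    else:
        p = sps.t.cdf(t, n - 2)
    return TestResult(rho, min(1.0, float(p)), "spearman_t", (n,), sidedness)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=64)
def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U1 (no ties).

    Counts rank interleavings by dynamic programming: placing the pooled
    ranks in ascending order, a sample-2 value placed while ``n1 - ax``
    sample-1 values remain contributes that many (x > y) pairs to U1.
    """
    umax = n1 * n2
    dp = np.zeros((n1 + 1, umax + 1))
    dp[0, 0] = 1.0
    for pos in range(n1 + n2):
        new = np.zeros_like(dp)
        for ax in range(min(pos, n1) + 1):
            row = dp[ax]
            if not row.any():
                continue
            if ax < n1:
                new[ax + 1] += row
            if pos - ax < n2:
                add = n1 - ax
                if add:
                    new[ax, add:] += row[:umax + 1 - add]
                else:
                    new[ax] += row
        dp = new
    pmf = dp[n1]
    return pmf / pmf.sum()


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:len(a)].sum()
    u1 = r1 - len(a) * (len(a) + 1) / 2
    return float(u1), float(len(a) * len(b) - u1)


def mann_whitney_u(a, b, sidedness: str = "two") -> TestResult:
    """Mann-Whitney-Wilcoxon U test.

    Exact when the label-assignment space is enumerable (C(n1+n2, n1) <=
    20000, with ties handled by full enumeration); tie-corrected normal
    approximation otherwise.  ``greater`` means a tends larger than b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u1, u2 = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if comb(n1 + n2, n1) <= EXACT_COMB_MAX:
        if not has_ties:
            pmf = _u_null_pmf(n1, n2)
            u_vals = np.arange(len(pmf))
            eps = 1e-9
            p_ge = pmf[u_vals >= u1 - eps].sum()
            p_le = pmf[u_vals <= u1 + eps].sum()
        else:
            us = []
            idx = np.arange(n1 + n2)
            for pick in itertools.combinations(idx, n1):
                mask = np.zeros(n1 + n2, dtype=bool)
                mask[list(pick)] = True
                us.append(_u_statistic(pooled[mask], pooled[~mask])[0])
            us = np.array(us)
            eps = 1e-9
            p_ge = float(np.mean(us >= u1 - eps))
            p_le = float(np.mean(us <= u1 + eps))
        if sidedness == "two":
            p = min(1.0, 2 * min(p_ge, p_le))
        elif sidedness == "greater":
            p = p_ge
        else:
            p = p_le
        return TestResult(u1, float(p), "mww_exact", (n1, n2), sidedness)
    mu = n1 * n2 / 2
    tie_counts = np.array([np.sum(pooled == v) for v in np.unique(pooled)])
    tie_term = (tie_counts ** 3 - tie_counts).sum() / ((n1 + n2) * (n1 + n2 - 1))
    sigma = sqrt(n1 * n2 / 12 * ((n1 + n2 + 1) - tie_term))
    if sigma == 0:
        return TestResult(u1, 1.0, "mww_normal", (n1, n2), sidedness)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma
    if sidedness == "two":
        p = 2 * sps.norm.sf(abs(z))
    elif sidedness == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return TestResult(u1, min(1.0, float(p)), "mww_normal", (n1, n2), sidedness)


# ---------------------------------------------------------------------------
# chi-square


def chi_square(observed=None, expected=None, contingency=None) -> TestResult:
    """Pearson chi-square: goodness-of-fit (observed vs expected) or
    independence on a contingency table (expected from margins)."""
    if contingency is not None:
        table = np.asarray(contingency, dtype=float)
        stat, p, dof, exp = sps.chi2_contingency(table, correction=False)
        if (exp <= 0).any():
            raise ValueError("zero expected cell; merge categories")
        return TestResult(float(stat), float(p), "chi2_independence",
                          tuple(table.shape))
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if (expected <= 0).any():
        raise ValueError("zero expected cell; merge categories")
    stat = float(((observed - expected) ** 2 / expected).sum())
    dof = len(observed) - 1
    p = float(sps.chi2.sf(stat, dof))
    return TestResult(stat, p, "chi2_gof", (len(observed),))


# ---------------------------------------------------------------------------
# binomial


def binomial_test(k: int, n: int, p0: float = 0.5,
                  sidedness: str = "two") -> TestResult:
    """Exact binomial tail-sum test."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    res = sps.binomtest(k, n, p0, alternative=alt)
    return TestResult(float(k), float(res.pvalue), "binomial", (n,), sidedness)


# ---------------------------------------------------------------------------
# stratified co-occurrence


def co_occurrence_test(counts: dict[str, float], flag: dict[str, bool],
                       sizes_mb: dict[str, float],
                       boundary_mb: float = 2.0) -> pd.DataFrame:
    """Per-stratum Mann-Whitney comparison of per-genome R-M counts
    between flag-true and flag-false genomes.

    Genomes split into small (< boundary) and large (>= boundary) strata;
    a genome of exactly the boundary size is large.  Strata with an empty
    group are reported without a test.
    """
    rows = []
    for stratum in ("small", "large"):
        if stratum == "small":
            ids = [g for g in sorted(counts) if sizes_mb[g] < boundary_mb]
        else:
            ids = [g for g in sorted(counts) if sizes_mb[g] >= boundary_mb]
        yes = [counts[g] for g in ids if flag[g]]
        no = [counts[g] for g in ids if not flag[g]]
        row = {"stratum": stratum, "n_flagged": len(yes),
               "n_unflagged": len(no),
               "mean_flagged": float(np.mean(yes)) if yes else float("nan"),
               "mean_unflagged": float(np.mean(no)) if no else float("nan")}
        if yes and no:
            res = mann_whitney_u(yes, no)
            row.update(statistic=res.statistic, p_value=res.p_value,
                       method=res.method)
        else:
            row.update(statistic=float("nan"), p_value=float("nan"),
                       method="none")
        rows.append(row)
    return pd.DataFrame(rows)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never gating)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
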
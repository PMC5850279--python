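"""Nonparametric and permutation tests used throughout the analysis.

Wilcoxon signed-rank for paired data, Wilcoxon/Mann-Whitney rank-sum for
unpaired data, a Monte Carlo (label permutation) Welch t-test run in parallel
with the nonparametric tests, and a simple 2-SD separation rule for
regression slopes. Exact null distributions are used whenever the sample
sizes permit (no ties, n <= 25 for the signed-rank; C(n1+n2, n1) <= 1e6 for
the rank-sum); otherwise the normal approximation with continuity/tie
correction applies. All p-values are two-sided unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

from .metrics import DecayRegressionFit

#: reporting default for significance, configurable by callers
DEFAULT_ALPHA = 0.01

#: scipy's exact signed-rank path is used up to this n (without ties)
SIGNED_RANK_EXACT_MAX_N = 25

#: exact rank-sum enumeration cap on C(n1+n2, n1)
RANK_SUM_EXACT_MAX_COMB = 10**6


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    method: str = "exact"
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def wilcoxon_signed_rank(differences, *, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute values receive average ranks. The exact distribution is used for
    n <= 25 when there are no ties; otherwise the normal approximation with
    continuity correction. Requires n >= 5 after zero-dropping.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    has_ties = len(np.unique(np.abs(d))) < n
    exact = n <= SIGNED_RANK_EXACT_MAX_N and not has_ties
    res = sps.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative=alternative,
        method="exact" if exact else "approx",
    )
    return TestResult(
        test_name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        method="exact" if exact else "normal_approx",
    )


def rank_sum(x, y, *, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon/Mann-Whitney rank-sum test for two independent samples.

    Exact enumeration when C(n1+n2, n1) <= 1e6 and there are no cross-sample
    ties; otherwise the normal approximation with tie correction and
    continuity correction. Requires n1, n2 >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"need n1, n2 >= 3, got {n1}, {n2}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = comb(n1 + n2, n1) <= RANK_SUM_EXACT_MAX_COMB and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        test_name="rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=n1,
        n2=n2,
        method="exact" if exact else "normal_approx",
    )


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def monte_carlo_t(x, y, n_permutations: int = 10000, seed: int = 0) -> TestResult:
    """Two-sided permutation test on the Welch t statistic.

    Labels of the pooled sample are permuted; the p-value uses the
    add-one convention (1 + #{|t*| >= |t|}) / (1 + n_permutations), which is
    exactly valid under exchangeability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"need n1, n2 >= 3, got {n1}, {n2}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t statistic undefined")
    observed = abs(_welch_t(x, y))
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    # one vectorized pass: each row of perms is a permuted pooled sample
    perms = np.empty((n_permutations, n1 + n2))
    for i in range(n_permutations):
        perms[i] = rng.permutation(pooled)
    px, py = perms[:, :n1], perms[:, n1:]
    v1 = px.var(axis=1, ddof=1)
    v2 = py.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(
            denom > 0, (px.mean(axis=1) - py.mean(axis=1)) / denom, 0.0
        )
    exceed = int(np.sum(np.abs(tstats) >= observed))
    p = (1 + exceed) / (1 + n_permutations)
    return TestResult(
        test_name="monte_carlo_t",
        statistic=observed,
        p_value=p,
        n1=n1,
        n2=n2,
        method="monte_carlo",
        n_permutations=n_permutations,
        seed=seed,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; no correction is
    applied by default anywhere in the package)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def slope_separation(fit_a: DecayRegressionFit, fit_b: DecayRegressionFit) -> bool:
    """True iff the closed intervals slope +/- 2*SD of the two fits are disjoint."""
    lo_a, hi_a = fit_a.slope - 2 * fit_a.slope_sd, fit_a.slope + 2 * fit_a.slope_sd
    lo_b, hi_b = fit_b.slope - 2 * fit_b.slope_sd, fit_b.slope + 2 * fit_b.slope_sd
    return hi_a < lo_b or hi_b < lo_a
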
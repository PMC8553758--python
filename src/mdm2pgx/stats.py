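"""Statistical primitives shared by every screen.

Each kernel returns a :class:`TestResult` whose ``method`` tag records the
exact variant that ran (exact vs. approximate Wilcoxon, Welch t, ...), so
downstream tables are self-describing.  Standard tests are fronted by
scipy/statsmodels; the empirical-Bayes moderated t — the limma-style arm of
the triple differential-expression test — is implemented here because no
installed Python package provides it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_chisquare

EXACT_WILCOXON_MAX_N = 8  # per-group size bound for exact enumeration


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str

    def __post_init__(self) -> None:
        # p lives in (0, 1]; underflowing p-values are clamped to the
        # smallest positive float rather than reported as exactly zero.
        if self.p == 0.0:
            self.p = float(np.finfo(float).tiny)
        if np.isfinite(self.p) and not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")


# ---------------------------------------------------------------------------
# Rank and count tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact null distribution when both groups have at most
    8 observations and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(len(x) * len(y) / 2.0, 1.0, "wilcoxon-degenerate")
    ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_WILCOXON_MAX_N and len(y) <= EXACT_WILCOXON_MAX_N and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon-exact")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon-normal-cc")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities of tables no more likely
    than the observed one.  A zero margin gives p = 1 by convention.
    """
    counts = np.array([[a, b], [c, d]])
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return TestResult(np.nan, 1.0, "fisher-degenerate-margin")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t-distribution approximation on
    t = rho * sqrt((n - 2) / (1 - rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, 1.0, "spearman-zero-variance")
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman-t-approx")


def two_sample_t(x, y) -> TestResult:
    """Welch two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, "welch-t-degenerate")
        return TestResult(np.inf, float(np.finfo(float).tiny), "welch-t-degenerate")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "welch-t")


def proportion_test(successes, totals) -> TestResult:
    """Chi-square test of homogeneity of proportions across k groups.

    df = k - 1, no continuity correction for k > 2.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if len(successes) < 2:
        raise ValueError("need at least 2 groups")
    if (totals <= 0).any():
        raise ValueError("all group totals must be positive")
    if (successes > totals).any() or (successes < 0).any():
        raise ValueError("successes must lie in [0, total] per group")
    pooled = successes.sum() / totals.sum()
    if pooled in (0.0, 1.0) or np.ptp(successes / totals) == 0:
        return TestResult(0.0, 1.0, "prop-chisq")
    chi2, p, _ = proportions_chisquare(successes.astype(int), totals.astype(int))
    return TestResult(float(chi2), float(p), "prop-chisq")


def hypergeom_enrichment(hits, universe, query) -> TestResult:
    """Upper-tail hypergeometric over-representation test.

    p = P(overlap >= observed) when drawing |query| genes from the
    universe, of which |hits| belong to the set.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    overlap = len(hits & query)
    p = stats.hypergeom.sf(overlap - 1, len(universe), len(hits), len(query))
    return TestResult(float(overlap), float(min(p, 1.0)), "hypergeom-upper")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t (limma-style)
# ---------------------------------------------------------------------------

def trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Models s2 ~ s0^2 * F(df, d0) via the moments of log(s2) (digamma /
    trigamma identities); returns (d0, s0^2), with d0 = inf when the
    observed log-variances are under-dispersed relative to pure chi-square
    noise (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * float(trigamma_inverse(np.array([evar]))[0])
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # Under-dispersed log-variances: infinite prior df (complete
        # pooling); the pooled value is the arithmetic mean variance.
        d0 = np.inf
        s0_2 = float(s2.mean())
    return d0, s0_2


def moderated_t(
    matrix, groups, d0_override: float | None = None
) -> tuple[list[TestResult], float, float]:
    """Per-feature moderated t-test between two groups of samples.

    ``matrix`` is features x samples; ``groups`` is a binary label per
    sample (group 1 minus group 0 is the reported effect direction).  The
    per-feature pooled residual variance s_g^2 (df d_g = n - 2) is shrunk
    toward an empirical prior s0^2 with d0 prior df, both estimated by
    method of moments on log s_g^2:

        s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
        t_g    = (mean1 - mean0) / (s~_g * sqrt(1/n0 + 1/n1))

    with p from a t-distribution on d0 + d_g df (capped at the total
    residual df, normal when d0 is infinite).  ``d0_override`` forces the
    prior df: 0 recovers the ordinary t per feature, inf complete pooling.

    Returns (per-feature results, d0, s0^2).  If the prior cannot be
    estimated (a single feature), falls back to ordinary Welch t per
    feature, flagged in the method tag.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(groups)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValueError("matrix must be features x samples matching groups")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("groups must contain exactly two labels")
    g1 = labels == uniq[1]
    g0 = labels == uniq[0]
    n1, n0 = int(g1.sum()), int(g0.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")

    m1 = X[:, g1].mean(axis=1)
    m0 = X[:, g0].mean(axis=1)
    effect = m1 - m0
    dg = n1 + n0 - 2
    ss = ((X[:, g1] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, g0] - m0[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / dg
    scale = np.sqrt(1.0 / n1 + 1.0 / n0)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = fit_f_dist(s2, dg)[1] if len(s2) > 1 else float(s2[0])
        method = "moderated-t-d0fixed"
    elif X.shape[0] < 2:
        res = [two_sample_t(X[i, g1], X[i, g0]) for i in range(X.shape[0])]
        return (
            [TestResult(r.statistic, r.p, "moderated-t-fallback-ordinary") for r in res],
            0.0,
            float(s2[0]) if len(s2) else np.nan,
        )
    else:
        d0, s0_2 = fit_f_dist(s2, dg)
        method = "moderated-t-eb"

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = dg
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = min(d0 + dg, dg * len(s2))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2_post) * scale)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    results = [TestResult(float(ti), float(min(pi, 1.0)) if pi > 0 else float(pi), method)
               for ti, pi in zip(t, p)]
    return results, float(d0), float(s0_2)
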
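"""Univariate and population statistics used throughout the analysis.

Exact two-tailed sign test, pooled-SD Cohen's d, one-way ANOVA across the
four phase bins, Kruskal-Wallis, chi-square goodness of fit against
uniformity, rank-sum, and Spearman/Pearson correlations.  No
multiple-comparison correction is applied anywhere (the analyses are
exploratory by design).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def sign_test_two_tailed(n_pos: int, n_neg: int) -> float:
    """Exact two-tailed sign test against a zero median.

    Ties (zero differences) are dropped before counting.  Uses the
    double-the-larger-tail exact binomial:
    ``p = min(1, 2 P(X >= max(n_pos, n_neg) | n, 1/2))``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("no non-zero differences")
    k = max(n_pos, n_neg)
    return float(min(1.0, 2.0 * sps.binom.sf(k - 1, n, 0.5)))


def cohens_d(group_a, group_b) -> float:
    """Pooled-SD standardized mean difference, positive when A > B."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("degenerate groups: zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def oneway_anova_phase(values, bin_labels) -> tuple[float, float]:
    """One-way ANOVA of a feature across the phase bins present.

    Bins with fewer than 2 values are dropped; at least two usable bins
    are required.  With exactly two bins this reduces to a t-test
    (``F = t^2``).
    """
    values = np.asarray(values, float)
    labels = np.asarray(bin_labels)
    groups = [values[labels == b] for b in np.unique(labels)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two bins with >= 2 values")
    if all(np.all(g == groups[0][0]) for g in groups):
        raise ValueError("all values identical: F undefined")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def distribution_tests(data, kind: str) -> tuple[float, float]:
    """Standard distributional tests with midrank tie handling.

    ``kruskal_wallis``: ``data`` is a sequence of groups.
    ``chi2_gof_uniform``: ``data`` is a vector of bin counts, tested
    against equal expected counts.
    ``ranksum``: ``data`` is a pair of samples (two-sided Wilcoxon
    rank-sum via the tie-corrected Mann-Whitney U normal approximation).
    """
    if kind == "kruskal_wallis":
        groups = [np.asarray(g, float) for g in data]
        if any(len(g) == 0 for g in groups) or len(groups) < 2:
            raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
        stat, p = sps.kruskal(*groups)
    elif kind == "chi2_gof_uniform":
        counts = np.asarray(data, float)
        if counts.size == 0 or counts.sum() == 0:
            raise ValueError("empty counts")
        stat, p = sps.chisquare(counts)
    elif kind == "ranksum":
        a, b = (np.asarray(g, float) for g in data)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("empty group")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test kind: {kind}")
    return float(stat), float(p)


def correlation(x, y, kind: str = "spearman") -> tuple[float, float]:
    """Spearman (midrank ties) or Pearson correlation with t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    if kind == "spearman":
        r, p = sps.spearmanr(x, y)
    elif kind == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation kind: {kind}")
    return float(r), float(p)
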
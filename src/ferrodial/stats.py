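"""Group statistics with a normality-gated test choice.

Groups of per-replicate bioaccessibility values are summarized by mean,
median, min, max, interquartile range and sample SD.  Comparisons follow
the two-branch convention common in this literature: Shapiro-Wilk on every
group at alpha = 0.05; when all groups look normal, one-way ANOVA with
Tukey's HSD post hoc; otherwise Kruskal-Wallis with Dunn's post hoc.
P-values are additionally mapped to the reporting tiers
p < 0.05 / p < 0.01 / p < 0.001.

Omnibus and post hoc machinery is standard and delegated to scipy
(``f_oneway``, ``kruskal``, ``tukey_hsd``, ``shapiro``); Dunn's mean-rank
z test with tie correction is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary", "PairwiseComparison", "ComparisonResult", "TestChoice",
    "descriptive", "shapiro_wilk", "one_way_anova", "tukey_hsd",
    "kruskal_wallis", "dunn_test", "compare_groups", "significance_tier",
    "levene",
]

ALPHA_DEFAULT = 0.05


class TestChoice(str, Enum):
    ANOVA_TUKEY = "anova_tukey"
    KRUSKAL_DUNN = "kruskal_dunn"


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    median: float
    minimum: float
    maximum: float
    iqr: float
    sd: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: object
    group_b: object
    p: float
    tier: str


@dataclass(frozen=True)
class ComparisonResult:
    test_used: TestChoice
    statistic: float          # F or H
    p_omnibus: float
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float = ALPHA_DEFAULT
    shapiro_p: tuple[float, ...] = ()


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


def descriptive(values: Sequence[float]) -> GroupSummary:
    """Seven-number summary; SD uses the n-1 denominator and quantiles use
    linear interpolation, so ``sd`` is NaN for a single observation."""
    arr = _clean(values)
    if arr.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(med),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        iqr=float(q3 - q1),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation, 3 <= n <= 5000)."""
    arr = _clean(values)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("W is undefined for a constant sample")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def _check_groups(groups: Sequence[Sequence[float]], min_n: int
                  ) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cleaned = [_clean(g) for g in groups]
    for i, g in enumerate(cleaned):
        if g.size < min_n:
            raise ValueError(f"group {i} has n={g.size} < {min_n}")
    return cleaned


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """F = MSB/MSW and its p from F(k-1, N-k)."""
    cleaned = _check_groups(groups, min_n=2)
    f, p = sps.f_oneway(*cleaned)
    return float(f), float(p)


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence] = None
              ) -> list[PairwiseComparison]:
    """Tukey(-Kramer) studentized-range pairwise p-values."""
    cleaned = _check_groups(groups, min_n=2)
    labels = list(labels) if labels is not None else list(range(len(cleaned)))
    res = sps.tukey_hsd(*cleaned)
    out = []
    for i, j in combinations(range(len(cleaned)), 2):
        p = float(res.pvalue[i, j])
        out.append(PairwiseComparison(labels[i], labels[j], p,
                                      significance_tier(p)))
    return out


def _kw_statistic(cleaned: list[np.ndarray]) -> float:
    pooled = np.concatenate(cleaned)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start, rank_sums = 0, []
    for g in cleaned:
        rank_sums.append(ranks[start:start + g.size].sum())
        start += g.size
    h = (12.0 / (n * (n + 1))
         * sum(rs ** 2 / g.size for rs, g in zip(rank_sums, cleaned))
         - 3.0 * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if correction == 0:
        raise ValueError("H is undefined: all values are identical")
    return h / correction


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   p_method: Literal["asymptotic", "exact"] = "asymptotic",
                   ) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H.

    ``p_method="asymptotic"`` takes p from chi-square with k-1 df;
    ``"exact"`` enumerates every assignment of the pooled values to groups
    of the observed sizes (only feasible for tiny samples) and reports
    P(H* >= H) over that permutation distribution.
    """
    cleaned = _check_groups(groups, min_n=1)
    if sum(g.size for g in cleaned) < 3:
        raise ValueError("need at least 3 observations in total")
    h = _kw_statistic(cleaned)
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(h, df=len(cleaned) - 1))
    elif p_method == "exact":
        p = _kw_exact_p(cleaned, h)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return float(h), p


def _kw_exact_p(cleaned: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p by enumerating group assignments."""
    pooled = np.concatenate(cleaned)
    sizes = [g.size for g in cleaned]
    n_total = pooled.size
    if n_total > 12:
        raise ValueError("exact enumeration is limited to N <= 12")
    count = total = 0
    idx = frozenset(range(n_total))

    def recurse(remaining: frozenset, gi: int, assigned: list) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            groups_ = assigned + [sorted(remaining)]
            h = _kw_statistic([pooled[list(g)] for g in groups_])
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - frozenset(combo), gi + 1,
                    assigned + [list(combo)])

    recurse(idx, 0, [])
    return count / total


def dunn_test(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence] = None,
              adjust: Literal["bonferroni", "holm", "none"] = "bonferroni",
              ) -> list[PairwiseComparison]:
    """Dunn's post hoc test on mean ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S2 * (1/n_i + 1/n_j)) with
    S2 = N(N+1)/12 - sum(t^3 - t)/(12(N-1)); two-sided normal p, adjusted
    over all k(k-1)/2 comparisons (Bonferroni by default).
    """
    cleaned = _check_groups(groups, min_n=1)
    pooled = np.concatenate(cleaned)
    n = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("Dunn test undefined: all values are identical")
    ranks = sps.rankdata(pooled)
    start, mean_ranks = 0, []
    for g in cleaned:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    s2 = n * (n + 1) / 12.0 - tie_term
    labels = list(labels) if labels is not None else list(range(len(cleaned)))
    pairs = list(combinations(range(len(cleaned)), 2))
    raw = []
    for i, j in pairs:
        se = np.sqrt(s2 * (1.0 / cleaned[i].size + 1.0 / cleaned[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adjusted = _adjust_pvalues(raw, adjust)
    return [PairwiseComparison(labels[i], labels[j], p, significance_tier(p))
            for (i, j), p in zip(pairs, adjusted)]


def _adjust_pvalues(pvalues: Sequence[float], method: str) -> list[float]:
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if method == "none":
        return p.tolist()
    if method == "bonferroni":
        return np.minimum(1.0, p * m).tolist()
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * p[k])
            adj[k] = min(1.0, running)
        return adj.tolist()
    raise ValueError(f"unknown adjustment {method!r}")


def significance_tier(p: float, alpha: float = ALPHA_DEFAULT) -> str:
    """Map a p-value to the reporting tiers used for these tables."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < alpha:
        return "p<0.05"
    return "ns"


def levene(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Optional variance-homogeneity diagnostic (Brown-Forsythe variant);
    not part of the test-selection gate."""
    cleaned = _check_groups(groups, min_n=2)
    stat, p = sps.levene(*cleaned, center="median")
    return float(stat), float(p)


def compare_groups(groups: Sequence[Sequence[float]],
                   labels: Optional[Sequence] = None,
                   alpha: float = ALPHA_DEFAULT,
                   dunn_adjust: Literal["bonferroni", "holm", "none"] = "bonferroni",
                   ) -> ComparisonResult:
    """Normality-gated omnibus + post hoc comparison.

    Shapiro-Wilk is run per group; the parametric branch is taken only
    when every group passes (p >= alpha).  Constant groups cannot pass a
    normality check and route to the rank-based branch.
    """
    cleaned = _check_groups(groups, min_n=3)
    sw_p = []
    all_normal = True
    for g in cleaned:
        if np.ptp(g) == 0:
            sw_p.append(0.0)
            all_normal = False
            continue
        _, p = shapiro_wilk(g)
        sw_p.append(p)
        if p < alpha:
            all_normal = False
    if all_normal:
        stat, p_omni = one_way_anova(cleaned)
        pairwise = tukey_hsd(cleaned, labels)
        choice = TestChoice.ANOVA_TUKEY
    else:
        stat, p_omni = kruskal_wallis(cleaned)
        pairwise = dunn_test(cleaned, labels, adjust=dunn_adjust)
        choice = TestChoice.KRUSKAL_DUNN
    return ComparisonResult(
        test_used=choice,
        statistic=stat,
        p_omnibus=p_omni,
        pairwise=tuple(pairwise),
        alpha=alpha,
        shapiro_p=tuple(sw_p),
    )
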
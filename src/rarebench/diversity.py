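"""Alpha-diversity metrics and the hypothesis tests used on the simulations.

Richness and Shannon diversity are compared between treatment groups with
the two-sample Wilcoxon rank-sum test; distance matrices are tested with
PERMANOVA (permutational multivariate ANOVA on the pseudo-F statistic).
Aggregating each test's rejection fraction over replicate simulations gives
the empirical type-I error rate (at effect size 1.00) and power (above it).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import DistanceMatrix


@dataclass
class HypothesisResult:
    statistic: float
    p_value: float
    test: str                  # "permanova" | "wilcoxon"
    metric: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def richness(row: np.ndarray) -> int:
    """Number of OTUs observed (count > 0) in one sample."""
    row = np.asarray(row)
    return int((row > 0).sum())


def shannon(row: np.ndarray) -> float:
    """Shannon diversity -sum(p log p) in nats, from any abundance scale."""
    row = np.asarray(row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("Shannon diversity needs positive total abundance")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def expected_rarefied_richness(counts_row: np.ndarray, n: int) -> float:
    """Closed form E[S] = sum_g 1 - C(N - c_g, n)/C(N, n) for a draw of n reads."""
    c = np.asarray(counts_row, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    if n > total:
        raise ValueError("subsample larger than the sample")
    # log-space hypergeometric zero-probability: C(N-c, n)/C(N, n)
    from scipy.special import gammaln

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_p0 = np.where(total - c >= n,
                      logc(total - c, n) - logc(total, n), -np.inf)
    return float((1.0 - np.exp(log_p0)).sum())


def wilcoxon_two_sample(a: np.ndarray, b: np.ndarray,
                        metric: str = "") -> HypothesisResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact null distribution when both groups have at most 10 values and the
    pooled data are tie-free; otherwise the normal approximation with
    continuity correction.  Constant pooled data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return HypothesisResult(statistic=len(a) * len(b) / 2, p_value=1.0,
                                test="wilcoxon", metric=metric,
                                note="constant data")
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 10) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return HypothesisResult(statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            test="wilcoxon", metric=metric)


def _permanova_f(d2: np.ndarray, masks: list[np.ndarray], n: int) -> float:
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for m in masks:
        ss_within += d2[np.ix_(m, m)].sum() / (2 * int(m.sum()))
    a = len(masks)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, groups: np.ndarray, n_perm: int = 999,
              seed: int = 0, exact: bool = False) -> HypothesisResult:
    """PERMANOVA pseudo-F test for different group centroids.

    ``SS_total = sum_{i<j} d_ij^2 / n``; within-group sums use each group's
    size; ``F = (SS_between/(a-1)) / (SS_within/(n-a))``.  The p-value
    permutes group labels: ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``,
    or enumerates every distinct label arrangement when ``exact``.
    """
    groups = np.asarray(groups)
    n = dm.n
    if len(groups) != n:
        raise ValueError("groups must align with the distance matrix")
    levels = np.unique(groups)
    if len(levels) < 2 or any((groups == g).sum() < 2 for g in levels):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = dm.values ** 2
    if not d2.any():
        return HypothesisResult(statistic=np.nan, p_value=1.0,
                                test="permanova", note="degenerate all-zero matrix")
    masks = [groups == g for g in levels]
    f_obs = _permanova_f(d2, masks, n)

    if exact:
        if len(levels) != 2:
            raise ValueError("exact enumeration implemented for two groups")
        n_a = int(masks[0].sum())
        ge = total = 0
        for combo in combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            f = _permanova_f(d2, [m, ~m], n)
            total += 1
            ge += f >= f_obs - 1e-12
        return HypothesisResult(statistic=f_obs, p_value=ge / total,
                                test="permanova")

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = [np.zeros(n, dtype=bool) for _ in levels]
        for k, m in enumerate(masks):
            pm[k][perm[m]] = True
        ge += _permanova_f(d2, pm, n) >= f_obs - 1e-12
    p = (1 + ge) / (n_perm + 1)
    return HypothesisResult(statistic=f_obs, p_value=p, test="permanova")


def aggregate_error_power(records: pd.DataFrame, alpha: float = 0.05,
                          p_col: str = "p_value",
                          effect_col: str = "effect_size") -> pd.DataFrame:
    """Rejection fraction per condition: type-I error at effect 1.00, power above.

    Groups by every column other than the p-value and replicate/seed
    bookkeeping and reports ``fraction_significant`` with the replicate count.
    """
    drop = {p_col, "replicate", "seed", "accuracy"}
    key_cols = [c for c in records.columns if c not in drop]
    grouped = records.groupby(key_cols, dropna=False)[p_col]
    out = grouped.agg(fraction_significant=lambda p: float((p <= alpha).mean()),
                      n_replicates="size").reset_index()
    out["kind"] = np.where(np.isclose(out[effect_col], 1.0),
                           "type_I_error", "power")
    return out
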
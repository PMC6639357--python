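"""Shared small-sample statistics.

The rank-sum test used throughout (sense vs antisense expression, proximity
shift) is exact by enumeration for small samples and switches to the
tie-corrected normal approximation for larger ones.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 20


def rank_sum_test(x, y, exact_n_max: int = EXACT_N_MAX) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(statistic, p_value)`` where the statistic is the rank sum of
    ``x`` (midranks under ties). For combined sample size <= ``exact_n_max``
    the null distribution is enumerated over all assignments of the observed
    (possibly tied) values to the two groups, so ties are handled exactly;
    otherwise the continuity- and tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()

    if n1 + n2 <= exact_n_max:
        idx = np.fromiter(
            (i for comb in combinations(range(n1 + n2), n1) for i in comb),
            dtype=np.intp,
        ).reshape(-1, n1)
        w_all = ranks[idx].sum(axis=1)
        mean_w = ranks.sum() * n1 / (n1 + n2)
        # two-sided: as or more extreme in distance from the mean rank sum
        p = np.mean(np.abs(w_all - mean_w) >= np.abs(w_obs - mean_w) - 1e-12)
        return float(w_obs), float(min(1.0, p))

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(w_obs), float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are passed through and
    excluded from the denominator."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
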
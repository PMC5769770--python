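"""Rank-based statistics used by matrix comparison and boundary filtering."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import stats as _sps

#: largest pooled sample size for which the exact null distribution is used
EXACT_MAX_POOLED_N = 12


def rank_sum_test(x, y, *, exact_max_pooled_n: int = EXACT_MAX_POOLED_N) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small, tie-free samples and the
    normal approximation with continuity correction otherwise (the behaviour
    of R's ``wilcox.test`` with ``correct = TRUE``).

    Returns
    -------
    (statistic, p_value)
        ``statistic`` is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every value tied; no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= exact_max_pooled_n:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = _sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)
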
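import numpy as np
import pytest

from tadbound.hic import ContactMatrix, RestrictionMap
from tadbound.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_rmap():
    """Two 1-kb fragments on a 2-kb chromosome."""
    return RestrictionMap("chr1", [0, 1000, 2000])


def symmetric_matrix(rng, n, low=1, high=50):
    """Random symmetric integer count matrix."""
    upper = np.triu(rng.integers(low, high, size=(n, n)))
    return (upper + np.triu(upper, 1).T).astype(float)


@pytest.fixture
def random_matrix(rng):
    counts = symmetric_matrix(rng, 12)
    return ContactMatrix("chrT", 0, 10_000, counts)


def brute_force_insulation(counts, mask, w):
    """Independent double-loop diamond mean (oracle for insulation_signal)."""
    n = counts.shape[0]
    sig = np.full(n, np.nan)
    for i in range(n):
        if i - w + 1 < 0 or i + w > n - 1 or mask[i]:
            continue
        vals = []
        for u in range(i - w + 1, i + 1):
            for d in range(i + 1, i + w + 1):
                if not mask[u] and not mask[d]:
                    vals.append(counts[u, d])
        if vals:
            sig[i] = float(np.mean(vals))
    return sig


def exact_two_sided_ranksum_p(x, y):
    """Exhaustive-permutation two-sided rank-sum p-value (tie-free samples)."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    nx = len(x)
    sums = [sum(c) for c in combinations(range(1, len(pooled) + 1), nx)]
    n_total = len(sums)
    le = sum(1 for s in sums if s <= obs)
    ge = sum(1 for s in sums if s >= obs)
    return min(1.0, 2.0 * min(le, ge) / n_total)
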
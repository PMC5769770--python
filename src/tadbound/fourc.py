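"""4C-seq viewpoint profile quantification.

Fragment-level profiles are smoothed with a running window, normalized to a
fixed read mass within +/- span of the viewpoint, and summarized as
inter-domain contact percentages, per-region sums, cumulative contact
curves, and Euclidean/Ward clustering of curves across genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .intervals import GenomicInterval

DEFAULT_SMOOTH_WINDOW = 11
DEFAULT_NORM_SPAN = 5_000_000
DEFAULT_NORM_TARGET = 1e6
DEFAULT_CURVE_STEP = 10_000


@dataclass
class FourCProfile:
    """Restriction-fragment-level signal around one viewpoint."""

    chrom: str
    viewpoint: GenomicInterval
    name: str
    starts: np.ndarray
    ends: np.ndarray
    signal: np.ndarray
    smoothed_window: Optional[int] = None
    normalized_span: Optional[int] = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.signal = np.asarray(self.signal, dtype=float)
        if not (self.starts.shape == self.ends.shape == self.signal.shape):
            raise ValueError("starts, ends and signal must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragments must have positive length")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("fragments must be sorted and non-overlapping")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")

    @property
    def n_fragments(self) -> int:
        return int(self.signal.size)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def fragment(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.starts[i]), int(self.ends[i]))


@dataclass(frozen=True)
class DomainRatio:
    """Percentages of signal in two disjoint domains (sum to 100)."""

    domain_a: GenomicInterval
    domain_b: GenomicInterval
    excluded: Optional[GenomicInterval]
    sum_a: float
    sum_b: float
    pct_a: float
    pct_b: float

    def __post_init__(self) -> None:
        if abs(self.pct_a + self.pct_b - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


@dataclass
class CumulativeCurve:
    """Running sum of signal against offset from the viewpoint (at 0)."""

    name: str
    offsets: np.ndarray
    values: np.ndarray
    bounds: Tuple[int, int]

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("cumulative values must be non-decreasing")


def smooth_profile(p: FourCProfile, window: int = DEFAULT_SMOOTH_WINDOW) -> FourCProfile:
    """Running mean over ``window`` fragments centered on each fragment.

    Near the profile edges the window is truncated to the available
    fragments (e.g. index 0 with window 11 averages 6 fragments).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    h = window // 2
    n = p.n_fragments
    csum = np.concatenate([[0.0], np.cumsum(p.signal)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(p, signal=smoothed, smoothed_window=window)


def normalize_profile(
    p: FourCProfile,
    span: int = DEFAULT_NORM_SPAN,
    target: float = DEFAULT_NORM_TARGET,
) -> FourCProfile:
    """Scale so the signal within viewpoint +/- span totals ``target``.

    Fragments outside the span are scaled by the same factor; the operation
    is idempotent and removes sequencing-depth differences between
    replicates.
    """
    lo = p.viewpoint.start - span
    hi = p.viewpoint.end + span
    mids = p.midpoints
    in_window = (mids >= lo) & (mids < hi)
    total = float(p.signal[in_window].sum())
    if total <= 0:
        raise ValueError("no signal within the normalization span")
    factor = target / total
    return replace(p, signal=p.signal * factor, normalized_span=span)


def domain_ratio(
    p: FourCProfile,
    a: GenomicInterval,
    b: GenomicInterval,
    exclude: Optional[GenomicInterval] = None,
) -> DomainRatio:
    """Signal percentages in two disjoint domains, by fragment midpoint.

    Fragments whose midpoint falls in ``exclude`` contribute nothing; the
    result is ``100 * S_a / (S_a + S_b)`` and its complement.
    """
    if a.overlaps(b):
        raise ValueError("domains must be disjoint")
    mids = p.midpoints
    keep = np.ones(p.n_fragments, dtype=bool)
    if exclude is not None and exclude.chrom == p.chrom:
        keep &= ~((mids >= exclude.start) & (mids < exclude.end))
    in_a = keep & (mids >= a.start) & (mids < a.end) if a.chrom == p.chrom else np.zeros_like(keep)
    in_b = keep & (mids >= b.start) & (mids < b.end) if b.chrom == p.chrom else np.zeros_like(keep)
    s_a = float(p.signal[in_a].sum())
    s_b = float(p.signal[in_b].sum())
    if s_a + s_b <= 0:
        raise ValueError("no signal in either domain")
    pct_a = 100.0 * s_a / (s_a + s_b)
    return DomainRatio(a, b, exclude, s_a, s_b, pct_a, 100.0 - pct_a)


def region_quant(p: FourCProfile, panel: "RegionPanel") -> pd.DataFrame:
    """Per-region signal sum and fragment count, any-overlap rule.

    Half-open intervals: a fragment exactly abutting a region does not
    count. Returns a DataFrame indexed by region name.
    """
    rows = []
    for name, region in panel.items():
        if region.chrom != p.chrom:
            rows.append((name, 0.0, 0))
            continue
        hit = (p.starts < region.end) & (p.ends > region.start)
        rows.append((name, float(p.signal[hit].sum()), int(hit.sum())))
    return pd.DataFrame(rows, columns=["region", "signal_sum", "n_fragments"]).set_index(
        "region"
    )


def cumulative_curve(
    p: FourCProfile, bounds: Tuple[int, int]
) -> CumulativeCurve:
    """Prefix-sum curve of signal vs. offset from the viewpoint midpoint."""
    lo, hi = bounds
    if not lo <= 0 <= hi:
        raise ValueError("bounds must contain offset 0")
    offsets = p.midpoints - p.viewpoint.midpoint
    sel = (offsets >= lo) & (offsets <= hi)
    if not sel.any():
        raise ValueError("no fragments within bounds")
    return CumulativeCurve(
        name=p.name,
        offsets=offsets[sel],
        values=np.cumsum(p.signal[sel]),
        bounds=(lo, hi),
    )


def curve_distance_cluster(
    curves: Sequence[CumulativeCurve], step: int = DEFAULT_CURVE_STEP
) -> Tuple[np.ndarray, np.ndarray]:
    """Euclidean distances between curves and a Ward merge tree.

    Curves are linearly interpolated onto a shared offset grid (the
    intersection of their ranges, at ``step`` spacing) before computing
    pairwise distances; ties in the linkage resolve by input order.
    Returns (square distance matrix, scipy linkage matrix).
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    lo = max(int(c.offsets.min()) for c in curves)
    hi = min(int(c.offsets.max()) for c in curves)
    if lo >= hi:
        raise ValueError("curves have non-overlapping offset ranges")
    grid = np.arange(lo, hi + 1, step)
    X = np.vstack([np.interp(grid, c.offsets, c.values) for c in curves])
    dist = squareform(pdist(X, metric="euclidean"))
    Z = linkage(X, method="ward")
    return dist, Z


def merge_tree_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick text for a scipy linkage matrix (branch lengths = heights)."""
    tree = to_tree(Z)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return fmt(tree, tree.dist) + ";"


class RegionPanel:
    """Named genomic regions used for per-region 4C quantification."""

    def __init__(self, regions: Dict[str, GenomicInterval]):
        self._regions = dict(regions)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self._regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def __len__(self) -> int:
        return len(self._regions)

    def items(self):
        return self._regions.items()

    def names(self) -> List[str]:
        return list(self._regions)
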
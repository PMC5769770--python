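"""Insulation-diamond boundary calling and multi-window consensus TADs.

The caller follows the three-step TopDom scheme: (i) per-bin diamond-mean
insulation signal, (ii) turning-point detection of strict local minima,
(iii) a rank-sum filter comparing within-diamond contacts against the
flanking intra-domain triangles. Domains called at many window sizes are
aggregated into consensus TADs kept only when the exact same coordinates
recur in a sufficient fraction of window sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hic import ContactMatrix
from .intervals import GenomicInterval
from .stats import rank_sum_test

DEFAULT_WINDOW_RANGE: Tuple[int, ...] = tuple(range(3, 16))
DEFAULT_CONSENSUS_THRESHOLD = 0.40
DEFAULT_P_THRESHOLD = 0.05


@dataclass
class InsulationTrack:
    """Per-bin diamond-mean insulation signal at one window size.

    ``signal`` is NaN where the full diamond does not fit inside the matrix
    or where a side of the diamond is fully masked.
    """

    chrom: str
    start: int
    bin_size: int
    window_w: int
    signal: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.signal)

    @property
    def halfwidth(self) -> int:
        """Genomic half-width of the diamond in bases (w * bin_size)."""
        return self.window_w * self.bin_size

    def bin_interval(self, i: int) -> GenomicInterval:
        s = self.start + i * self.bin_size
        return GenomicInterval(self.chrom, s, s + self.bin_size)


@dataclass(frozen=True)
class DomainCallSet:
    """Domain/gap/boundary-bin intervals tiling the analyzed extent."""

    window_w: int
    calls: Tuple[Tuple[GenomicInterval, str], ...]

    def domains(self) -> List[GenomicInterval]:
        return [iv for iv, kind in self.calls if kind == "domain"]

    def boundary_bins(self) -> List[GenomicInterval]:
        return [iv for iv, kind in self.calls if kind == "boundary_bin"]


@dataclass(frozen=True)
class ConsensusTADSet:
    """Domains retained across window sizes, with per-interval support."""

    window_range: Tuple[int, ...]
    threshold: float
    tads: Tuple[Tuple[GenomicInterval, int], ...]

    def boundaries(self) -> List[int]:
        """Sorted unique edge coordinates of the retained TADs."""
        edges = set()
        for iv, _ in self.tads:
            edges.add(iv.start)
            edges.add(iv.end)
        return sorted(edges)


def insulation_signal(m: ContactMatrix, w: int) -> InsulationTrack:
    """Mean of the w x w diamond upstream x downstream of each bin.

    The diamond at bin ``i`` covers rows ``i-w+1..i`` and columns
    ``i+1..i+w``; the mean is taken over entries whose bins are both
    unmasked. Bins where the diamond does not fit, masked bins, and bins
    with a fully masked side are NaN.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    n = m.n_bins
    if w > n // 2:
        raise ValueError(f"window {w} larger than half the extent ({n} bins)")
    sig = np.full(n, np.nan)
    unmasked = ~m.mask
    for i in range(w - 1, n - w):
        if m.mask[i]:
            continue
        rows = np.arange(i - w + 1, i + 1)
        cols = np.arange(i + 1, i + w + 1)
        rows_u = rows[unmasked[rows]]
        cols_u = cols[unmasked[cols]]
        if rows_u.size == 0 or cols_u.size == 0:
            continue
        sig[i] = m.counts[np.ix_(rows_u, cols_u)].mean()
    return InsulationTrack(m.chrom, m.start, m.bin_size, w, sig)


def _distance_expected(m: ContactMatrix) -> np.ndarray:
    """Mean unmasked contact value per bin-distance (zeros become 1)."""
    n = m.n_bins
    active = ~m.mask
    exp = np.ones(n)
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        ok = active[i] & active[j]
        if ok.any():
            v = m.counts[i[ok], j[ok]].mean()
            exp[d] = v if v > 0 else 1.0
    return exp


def _local_minima(signal: np.ndarray, eligible: np.ndarray, radius: int = 1) -> List[int]:
    """Strict local minima of the defined bins within +/- ``radius`` neighbors.

    A bin is a turning point when its value is strictly below every other
    defined value within ``radius`` positions on both sides (and at least
    one defined neighbor exists on each side). Plateaus (runs of equal
    values) count as a single minimum when the values flanking the run are
    strictly greater; the leftmost bin of the run is reported.
    """
    idx = np.where(eligible)[0]
    v = signal[idx]
    minima: List[int] = []
    k = 1
    while k < v.size - 1:
        if v[k] < v[k - 1]:
            j = k
            while j + 1 < v.size and v[j + 1] == v[k]:
                j += 1
            if j + 1 < v.size and v[j + 1] > v[k]:
                left = v[max(0, k - radius):k]
                right = v[j + 1:j + 1 + radius]
                if np.all(left > v[k]) and np.all(right > v[k]):
                    minima.append(int(idx[k]))
            k = j + 1
        else:
            k += 1
    return minima


def _diamond_and_flanks(
    m: ContactMatrix, i: int, w: int, values: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    unmasked = ~m.mask
    rows = np.arange(i - w + 1, i + 1)
    cols = np.arange(i + 1, i + w + 1)
    rows_u = rows[unmasked[rows]]
    cols_u = cols[unmasked[cols]]
    diamond = values[np.ix_(rows_u, cols_u)].ravel()
    flanks = []
    for side in (rows_u, cols_u):
        if side.size >= 2:
            iu, ju = np.triu_indices(side.size, k=1)
            flanks.append(values[side[iu], side[ju]])
    flank = np.concatenate(flanks) if flanks else np.array([])
    return diamond, flank


def call_domains(
    m: ContactMatrix,
    w: int,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    distance_normalize: bool = True,
) -> DomainCallSet:
    """Call domains, gaps, and boundary bins at one window size.

    Strict local minima of the insulation signal become boundary bins when
    the within-diamond contacts are significantly depleted relative to the
    flanking intra-domain triangles (two-sided rank-sum, ``p <
    p_threshold``). With ``distance_normalize`` the test is run on
    observed/expected-at-distance values so the genome-wide distance decay
    does not bias it. Runs of masked or all-zero bins become gaps; the
    remaining stretches are domains.
    """
    n = m.n_bins
    gap = m.mask | (m.counts.sum(axis=1) == 0)
    if gap.all():
        warnings.warn("all bins masked or empty; returning empty call set")
        return DomainCallSet(window_w=w, calls=())
    track = insulation_signal(m, w)
    eligible = track.defined & ~gap
    candidates = _local_minima(track.signal, eligible, radius=w)
    if distance_normalize:
        exp = _distance_expected(m)
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        values = m.counts / exp[dist]
    else:
        values = m.counts
    boundary = np.zeros(n, dtype=bool)
    for i in candidates:
        diamond, flank = _diamond_and_flanks(m, i, w, values)
        if diamond.size == 0:
            continue
        if flank.size == 0:
            boundary[i] = True  # w == 1: no intra values to test against
            continue
        _, p = rank_sum_test(diamond, flank)
        if p < p_threshold:
            boundary[i] = True
    calls: List[Tuple[GenomicInterval, str]] = []
    pos = 0
    while pos < n:
        if boundary[pos]:
            kind, run_end = "boundary_bin", pos + 1
        elif gap[pos]:
            kind, run_end = "gap", pos + 1
            while run_end < n and gap[run_end] and not boundary[run_end]:
                run_end += 1
        else:
            kind, run_end = "domain", pos + 1
            while run_end < n and not gap[run_end] and not boundary[run_end]:
                run_end += 1
        calls.append(
            (
                GenomicInterval(
                    m.chrom,
                    m.start + pos * m.bin_size,
                    m.start + run_end * m.bin_size,
                ),
                kind,
            )
        )
        pos = run_end
    return DomainCallSet(window_w=w, calls=tuple(calls))


def consensus_from_callsets(
    callsets: Sequence[DomainCallSet],
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> ConsensusTADSet:
    """Keep domains whose exact (start, end) recur in >= threshold of sets.

    "At least" is inclusive: with 13 window sizes and threshold 0.40 the
    support cutoff is 6 (6/13 ~ 46.2%).
    """
    if not callsets:
        raise ValueError("need at least one call set")
    support: dict[GenomicInterval, int] = {}
    for cs in callsets:
        for iv in set(cs.domains()):
            support[iv] = support.get(iv, 0) + 1
    nw = len(callsets)
    kept = sorted(
        ((iv, c) for iv, c in support.items() if c / nw >= threshold - 1e-12),
        key=lambda t: (t[0].start, t[0].end),
    )
    return ConsensusTADSet(
        window_range=tuple(cs.window_w for cs in callsets),
        threshold=threshold,
        tads=tuple(kept),
    )


def consensus_tads(
    m: ContactMatrix,
    window_range: Sequence[int] = DEFAULT_WINDOW_RANGE,
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    distance_normalize: bool = True,
) -> ConsensusTADSet:
    """Run the caller over a range of window sizes and keep consensus TADs."""
    if len(window_range) < 1:
        raise ValueError("window_range must contain at least one window size")
    callsets = [
        call_domains(m, w, p_threshold=p_threshold,
                     distance_normalize=distance_normalize)
        for w in window_range
    ]
    return consensus_from_callsets(callsets, threshold=threshold)


def boundary_shift(
    a: ConsensusTADSet,
    b: ConsensusTADSet,
    anchor: GenomicInterval,
    search_radius: int = 500_000,
) -> Optional[int]:
    """Signed displacement (b - a) of the boundary nearest ``anchor``.

    Returns ``None`` ("absent") when either set has no consensus boundary
    within ``search_radius`` of the anchor midpoint.
    """
    mid = anchor.midpoint

    def nearest(s: ConsensusTADSet) -> Optional[int]:
        within = [e for e in s.boundaries() if abs(e - mid) <= search_radius]
        if not within:
            return None
        return min(within, key=lambda e: (abs(e - mid), e))

    pa, pb = nearest(a), nearest(b)
    if pa is None or pb is None:
        return None
    return pb - pa
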
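"""Hi-C pair-to-matrix pipeline.

Turns mapped pair records into binned cis contact matrices, applies
coverage-based bin masking, balances matrices by iterative correction, and
compares normalized matrices (subtraction, per-domain rank-sum tests).
Only single-chromosome (cis) windows are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval
from .stats import rank_sum_test

#: bp added toward the fragment interior when assigning a read end to a
#: restriction fragment, so reads overlapping the cut site land correctly
FRAGMENT_ASSIGN_SHIFT = 3


class PairRecord(NamedTuple):
    """One mapped Hi-C read pair, stored with the lower coordinate first."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapped1: bool = True
    mapped2: bool = True


def make_pair(chrom1, pos1, strand1, chrom2, pos2, strand2,
              mapped1=True, mapped2=True) -> PairRecord:
    """Build a :class:`PairRecord` in canonical (lower coordinate first) order."""
    if (chrom2, pos2) < (chrom1, pos1):
        chrom1, pos1, strand1, mapped1, chrom2, pos2, strand2, mapped2 = (
            chrom2, pos2, strand2, mapped2, chrom1, pos1, strand1, mapped1)
    return PairRecord(chrom1, int(pos1), strand1, chrom2, int(pos2), strand2,
                      bool(mapped1), bool(mapped2))


class RestrictionMap:
    """Sorted restriction fragments tiling one chromosome without gaps."""

    def __init__(self, chrom: str, edges: Sequence[int]):
        edges = np.asarray(edges, dtype=np.int64)
        if edges.size < 2:
            raise ValueError("restriction map needs at least one fragment")
        if edges[0] != 0:
            raise ValueError("fragment edges must start at 0")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("fragment edges must be strictly increasing")
        self.chrom = chrom
        self.edges = edges

    @classmethod
    def regular(cls, chrom: str, length: int, fragment_size: int) -> "RestrictionMap":
        edges = list(range(0, length, fragment_size)) + [length]
        if edges[-2] == length:
            edges = edges[:-1]
        return cls(chrom, edges)

    @classmethod
    def from_fragments(cls, fragments: Iterable[GenomicInterval]) -> "RestrictionMap":
        frags = sorted(fragments, key=lambda f: f.start)
        if not frags:
            raise ValueError("empty fragment list")
        chrom = frags[0].chrom
        edges = [frags[0].start]
        for f in frags:
            if f.chrom != chrom:
                raise ValueError("restriction map spans multiple chromosomes")
            if f.start != edges[-1]:
                raise ValueError(f"fragments do not tile: gap/overlap at {f}")
            edges.append(f.end)
        return cls(chrom, edges)

    @property
    def chrom_length(self) -> int:
        return int(self.edges[-1])

    @property
    def n_fragments(self) -> int:
        return int(self.edges.size - 1)

    def fragment_index(self, pos: int) -> int:
        if pos < 0 or pos >= self.chrom_length:
            raise ValueError(f"position {pos} outside chromosome {self.chrom}")
        return int(np.searchsorted(self.edges, pos, side="right") - 1)

    def fragment(self, idx: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.edges[idx]), int(self.edges[idx + 1]))

    def midpoint(self, idx: int) -> int:
        return int(self.edges[idx] + self.edges[idx + 1]) // 2


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact matrix.

    ``mask[i]`` is True for bins excluded from analysis; masked rows and
    columns are kept all-zero. ``biases`` holds per-bin balancing factors
    after iterative correction (NaN at masked bins).
    """

    chrom: str
    start: int
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    biases: Optional[np.ndarray] = None
    normalized: bool = False
    converged: Optional[bool] = None
    discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        n = self.counts.shape[0]
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask length does not match matrix size")
        active = ~self.mask
        sub = self.counts[np.ix_(active, active)]
        if not np.all(np.isfinite(sub)):
            raise ValueError("unmasked counts must be finite")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("counts must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.bin_size

    @property
    def extent(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def bin_interval(self, i: int) -> GenomicInterval:
        s = self.start + i * self.bin_size
        return GenomicInterval(self.chrom, s, s + self.bin_size)

    def bin_index(self, pos: int) -> int:
        if not self.extent.contains(pos):
            raise ValueError(f"position {pos} outside matrix extent {self.extent}")
        return (pos - self.start) // self.bin_size

    def grid_matches(self, other: "ContactMatrix") -> bool:
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )

    def with_mask(self, mask: np.ndarray) -> "ContactMatrix":
        """Return a copy with ``mask`` ORed in and masked rows/cols zeroed."""
        mask = np.asarray(mask, dtype=bool)
        new_mask = self.mask | mask
        counts = self.counts.copy()
        counts[new_mask, :] = 0.0
        counts[:, new_mask] = 0.0
        biases = None
        if self.biases is not None:
            biases = self.biases.copy()
            biases[new_mask] = np.nan
        return replace(self, counts=counts, mask=new_mask, biases=biases)

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            biases=None if self.biases is None else self.biases.copy(),
        )

    def total_pairs(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())


# ---------------------------------------------------------------------------
# pair-level operations


def assign_fragment(pos: int, strand: str, rmap: RestrictionMap) -> int:
    """Fragment index for a read end, shifting 3 bp toward its 3' side.

    The query position is clamped to the chromosome so reads at the ends
    stay assignable.
    """
    if pos < 0 or pos >= rmap.chrom_length:
        raise ValueError(f"position {pos} outside chromosome {rmap.chrom}")
    if strand == "+":
        query = pos + FRAGMENT_ASSIGN_SHIFT
    elif strand == "-":
        query = pos - FRAGMENT_ASSIGN_SHIFT
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    query = min(max(query, 0), rmap.chrom_length - 1)
    return rmap.fragment_index(query)


PAIR_CLASSES = ("valid", "single_side", "dangling_end", "self_circle", "error_pair")


def classify_pair(p: PairRecord, rmap: RestrictionMap) -> str:
    """Classify a pair by fragment assignment and strand geometry.

    Same-fragment pairs: inward-facing (+ on the left, - on the right) are
    dangling ends, outward-facing are self-circles, same-strand are error
    pairs. Different fragments are valid.
    """
    if not (p.mapped1 and p.mapped2):
        return "single_side"
    f1 = assign_fragment(p.pos1, p.strand1, rmap)
    f2 = assign_fragment(p.pos2, p.strand2, rmap)
    if f1 != f2:
        return "valid"
    # canonical order guarantees pos1 <= pos2
    if p.strand1 == p.strand2:
        return "error_pair"
    if p.strand1 == "+":
        return "dangling_end"
    return "self_circle"


def filter_pairs(pairs: Iterable[PairRecord], rmap: RestrictionMap) -> Tuple[List[PairRecord], dict]:
    """Keep valid pairs; return (valid_pairs, per-class tally)."""
    tally = {k: 0 for k in PAIR_CLASSES}
    kept: List[PairRecord] = []
    for p in pairs:
        cls = classify_pair(p, rmap)
        tally[cls] += 1
        if cls == "valid":
            kept.append(p)
    return kept, tally


def dedupe(pairs: Iterable[PairRecord]) -> List[PairRecord]:
    """Drop exact positional/strand duplicates, keeping first occurrences."""
    seen = {}
    for p in pairs:
        key = (p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)
        if key not in seen:
            seen[key] = p
    return list(seen.values())


def bin_pairs(
    pairs: Iterable[PairRecord],
    rmap: RestrictionMap,
    bin_size: int,
    extent: GenomicInterval,
) -> ContactMatrix:
    """Bin valid pairs by fragment midpoint into a symmetric raw matrix.

    The bin grid is anchored at coordinate 0 (bin = floor(midpoint /
    bin_size)); ``extent.start`` must sit on that grid. Pairs outside the
    extent or on another chromosome are tallied in ``discarded``.
    """
    if extent.start % bin_size != 0:
        raise ValueError("extent start must be a multiple of the bin size")
    n = -(-extent.length // bin_size)
    counts = np.zeros((n, n), dtype=float)
    offset = extent.start // bin_size
    discarded = 0
    for p in pairs:
        if p.chrom1 != extent.chrom or p.chrom2 != extent.chrom:
            discarded += 1
            continue
        f1 = assign_fragment(p.pos1, p.strand1, rmap)
        f2 = assign_fragment(p.pos2, p.strand2, rmap)
        b1 = rmap.midpoint(f1) // bin_size - offset
        b2 = rmap.midpoint(f2) // bin_size - offset
        if not (0 <= b1 < n and 0 <= b2 < n):
            discarded += 1
            continue
        counts[b1, b2] += 1.0
        if b1 != b2:
            counts[b2, b1] += 1.0
    return ContactMatrix(extent.chrom, extent.start, bin_size, counts,
                         discarded=discarded)


# ---------------------------------------------------------------------------
# matrix-level operations


def compute_mask(
    m: ContactMatrix,
    fragment_reads: Optional[np.ndarray] = None,
    rmap: Optional[RestrictionMap] = None,
) -> np.ndarray:
    """Low-coverage bin mask.

    A bin is masked if its marginal read sum is more than 10-fold below the
    uniform-coverage expectation (``2 * total_pairs / n_bins``), or — when
    per-fragment read counts are supplied — if fewer than half of its
    fragments are covered by at least two reads ("less than half" strict).
    """
    n = m.n_bins
    marginal = m.counts.sum(axis=1)
    expected = 2.0 * m.total_pairs() / n
    mask = marginal < expected / 10.0
    if fragment_reads is None or rmap is None:
        if fragment_reads is not None or rmap is not None:
            warnings.warn(
                "fragment coverage requires both fragment_reads and rmap; "
                "applying marginal rule only"
            )
        else:
            warnings.warn("no fragment coverage supplied; applying marginal rule only")
        return mask
    fragment_reads = np.asarray(fragment_reads)
    if fragment_reads.shape != (rmap.n_fragments,):
        raise ValueError("fragment_reads length must equal the fragment count")
    frag_bins = np.array(
        [rmap.midpoint(i) // m.bin_size - m.start // m.bin_size
         for i in range(rmap.n_fragments)]
    )
    for b in range(n):
        in_bin = frag_bins == b
        n_frags = int(in_bin.sum())
        if n_frags == 0:
            continue
        covered = int((fragment_reads[in_bin] >= 2).sum())
        if covered < n_frags / 2.0:
            mask[b] = True
    return mask


def ice_normalize(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: equalize unmasked marginals.

    Iterates the symmetric marginal update until the maximum relative
    deviation of unmasked marginals from their mean is below ``tol``. The
    total unmasked sum is preserved and the per-bin bias vector is returned
    normalized to unit geometric mean over unmasked bins. On
    non-convergence the result is returned with ``converged=False``.
    """
    active = ~m.mask
    if not active.any():
        raise ValueError("no unmasked bins")
    W = m.counts.astype(float).copy()
    n = m.n_bins
    bias = np.ones(n)
    total0 = W[np.ix_(active, active)].sum()
    if total0 <= 0:
        raise ValueError("matrix has no counts in unmasked bins")
    converged = False
    for _ in range(max_iter):
        marg = W.sum(axis=1)
        mean = marg[active].mean()
        if mean <= 0:
            raise ValueError("zero mean marginal on unmasked bins")
        dev = float(np.max(np.abs(marg[active] / mean - 1.0)))
        if dev < tol:
            converged = True
            break
        db = np.ones(n)
        db[active] = marg[active] / mean
        W /= np.outer(db, db)
        bias *= db
    if not converged:
        warnings.warn(f"ICE did not converge: final deviation {dev:.3g}")
    total = W[np.ix_(active, active)].sum()
    W *= total0 / total
    gmean = np.exp(np.mean(np.log(bias[active])))
    bias = bias / gmean
    biases = np.where(active, bias, np.nan)
    return replace(m, counts=W, biases=biases, normalized=True, converged=converged)


def subtract(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Elementwise ``a - b`` on the union-unmasked grid; masked entries NaN."""
    if not a.grid_matches(b):
        raise ValueError("matrices are not on the same bin grid")
    if not (a.normalized and b.normalized):
        raise ValueError("subtract requires two normalized matrices")
    mask = a.mask | b.mask
    diff = a.counts - b.counts
    diff[mask, :] = np.nan
    diff[:, mask] = np.nan
    return ContactMatrix(a.chrom, a.start, a.bin_size, diff, mask=mask,
                         normalized=True)


@dataclass(frozen=True)
class DomainComparison:
    domain: GenomicInterval
    statistic: float
    p_value: float
    n_bins_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def domain_bins(m: ContactMatrix, domain: GenomicInterval) -> np.ndarray:
    """Indices of bins fully contained in ``domain``."""
    if domain.chrom != m.chrom:
        return np.array([], dtype=int)
    return np.array(
        [i for i in range(m.n_bins) if domain.contains_interval(m.bin_interval(i))],
        dtype=int,
    )


def compare_domain_intensity(
    a: ContactMatrix, b: ContactMatrix, domain: GenomicInterval
) -> DomainComparison:
    """Rank-sum test on within-domain off-diagonal values of two matrices.

    Uses every unmasked bin pair strictly inside ``domain``, excluding the
    diagonal; two-sided with continuity correction.
    """
    if not a.grid_matches(b):
        raise ValueError("matrices are not on the same bin grid")
    bins = domain_bins(a, domain)
    usable = bins[~a.mask[bins] & ~b.mask[bins]]
    if usable.size < 2:
        raise ValueError("fewer than 2 usable bins in domain")
    iu, ju = np.triu_indices(usable.size, k=1)
    x = a.counts[usable[iu], usable[ju]]
    y = b.counts[usable[iu], usable[ju]]
    stat, p = rank_sum_test(x, y)
    return DomainComparison(domain, stat, p, int(usable.size))
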
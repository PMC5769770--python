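"""Ground-truthed synthetic two-TAD locus generator.

Produces Hi-C matrices/pair lists and 4C fragment profiles from an explicit
generative model: power-law distance decay, block-wise TAD enrichment, a
boundary of tunable permeability, multiplicative per-bin biases, and
Poisson-sampled counts. Deletion alleles are derived from edit scripts with
coordinates collapsed and the boundary weakened or removed in the recorded
truth, so every pipeline stage can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alleles import EditScript
from .hic import ContactMatrix, PairRecord, RestrictionMap, make_pair
from .fourc import FourCProfile
from .intervals import GenomicInterval


@dataclass(frozen=True)
class TADBlock:
    interval: GenomicInterval
    intra_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.intra_factor <= 0:
            raise ValueError("intra_factor must be positive")


@dataclass(frozen=True)
class EnhancerPeak:
    position: int
    amplitude: float
    width: int


@dataclass(frozen=True)
class TruthRecord:
    """Generative truth the recovery tests compare against."""

    boundary_region: Optional[GenomicInterval]
    rho_effective: float
    fused: bool = False
    junction: Optional[int] = None
    expected_cross_fraction: Optional[float] = None
    tads: Tuple[TADBlock, ...] = ()


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Generative description of a two-TAD locus.

    Contact enrichment ``T_ij`` is ``intra_factor`` within a TAD, the
    permeability ``rho`` for pairs spanning the boundary wall (the midpoint
    of ``boundary_region``), and 1 otherwise. Expected counts are
    ``L * b_i * b_j * (1 + |i - j|) ** -decay_exponent * T_ij`` with ``L``
    scaling the upper-triangle total to ``coverage``.
    """

    extent: GenomicInterval
    bin_size: int
    tads: Tuple[TADBlock, ...]
    boundary_region: Optional[GenomicInterval] = None
    permeability: float = 0.1
    decay_exponent: float = 0.85
    biases: Optional[Tuple[float, ...]] = None
    coverage: float = 250_000.0
    enhancer_peaks: Tuple[EnhancerPeak, ...] = ()
    fourc_decay: float = 0.8
    sub_tads: Tuple[TADBlock, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent.length % self.bin_size != 0:
            raise ValueError("extent length must be a multiple of the bin size")
        if not 0.0 <= self.permeability <= 1.0:
            raise ValueError("permeability must lie in [0, 1]")
        if self.decay_exponent <= 0 or self.fourc_decay <= 0:
            raise ValueError("decay exponents must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        prev_end = self.extent.start
        for t in sorted(self.tads, key=lambda t: t.interval.start):
            if not self.extent.contains_interval(t.interval):
                raise ValueError(f"TAD {t.interval} outside extent {self.extent}")
            if t.interval.start < prev_end:
                raise ValueError("TAD blocks must not overlap")
            prev_end = t.interval.end
        if self.boundary_region is not None and not self.extent.contains_interval(
            self.boundary_region
        ):
            raise ValueError("boundary region outside extent")
        if self.biases is not None and len(self.biases) != self.n_bins:
            raise ValueError("biases must have one entry per bin")

    @property
    def n_bins(self) -> int:
        return self.extent.length // self.bin_size

    @property
    def wall(self) -> Optional[int]:
        """Genomic coordinate of the insulating wall (boundary midpoint)."""
        if self.boundary_region is None:
            return None
        return self.boundary_region.midpoint

    def bin_midpoints(self) -> np.ndarray:
        return (
            self.extent.start
            + np.arange(self.n_bins) * self.bin_size
            + self.bin_size // 2
        )

    def tad_membership(self, positions: np.ndarray) -> np.ndarray:
        """TAD index per position (-1 outside every TAD)."""
        member = np.full(len(positions), -1, dtype=int)
        for k, t in enumerate(self.tads):
            member[(positions >= t.interval.start) & (positions < t.interval.end)] = k
        return member


def two_tad_spec(
    n_bins: int = 100,
    bin_size: int = 40_000,
    boundary_bins: int = 2,
    rho: float = 0.1,
    intra_factor: float = 3.0,
    decay_exponent: float = 0.85,
    coverage: float = 250_000.0,
    chrom: str = "chrS",
    seed: int = 0,
    biases: Optional[Sequence[float]] = None,
    enhancer_peaks: Tuple[EnhancerPeak, ...] = (),
) -> SyntheticLocusSpec:
    """Canonical two-TAD locus: two blocks split by a small boundary block."""
    if n_bins < boundary_bins + 4:
        raise ValueError("locus too small for the requested boundary block")
    left_bins = (n_bins - boundary_bins) // 2
    b0 = left_bins * bin_size
    b1 = b0 + boundary_bins * bin_size
    extent = GenomicInterval(chrom, 0, n_bins * bin_size)
    return SyntheticLocusSpec(
        extent=extent,
        bin_size=bin_size,
        tads=(
            TADBlock(GenomicInterval(chrom, 0, b0), intra_factor),
            TADBlock(GenomicInterval(chrom, b1, extent.end), intra_factor),
        ),
        boundary_region=GenomicInterval(chrom, b0, b1),
        permeability=rho,
        decay_exponent=decay_exponent,
        coverage=coverage,
        seed=seed,
        biases=None if biases is None else tuple(biases),
        enhancer_peaks=enhancer_peaks,
    )


def default_locus_spec(**overrides) -> SyntheticLocusSpec:
    """3-Mb locus with 720-kb and 880-kb blocks split by a 2-bin boundary."""
    chrom = overrides.pop("chrom", "chrS")
    bin_size = overrides.pop("bin_size", 40_000)
    extent = GenomicInterval(chrom, 0, 3_000_000)
    c_start = 440_000
    c_end = c_start + 720_000  # 1,160,000
    b_end = c_end + 2 * bin_size  # 1,240,000
    t_end = b_end + 880_000  # 2,120,000
    defaults = dict(
        extent=extent,
        bin_size=bin_size,
        tads=(
            TADBlock(GenomicInterval(chrom, c_start, c_end), 3.0),
            TADBlock(GenomicInterval(chrom, b_end, t_end), 3.0),
        ),
        boundary_region=GenomicInterval(chrom, c_end, b_end),
        permeability=0.1,
    )
    defaults.update(overrides)
    return SyntheticLocusSpec(**defaults)


def _enrichment_matrix(spec: SyntheticLocusSpec) -> np.ndarray:
    mids = spec.bin_midpoints()
    member = spec.tad_membership(mids)
    n = spec.n_bins
    T = np.ones((n, n))
    for k, t in enumerate(spec.tads):
        in_k = member == k
        T[np.ix_(in_k, in_k)] = t.intra_factor
    for s in spec.sub_tads:
        in_s = (mids >= s.interval.start) & (mids < s.interval.end)
        T[np.ix_(in_s, in_s)] *= s.intra_factor
    wall = spec.wall
    if wall is not None:
        left = mids < wall
        cross = np.logical_xor.outer(left, left)
        T[cross] = spec.permeability
    return T


def expected_hic_matrix(spec: SyntheticLocusSpec) -> Tuple[np.ndarray, TruthRecord]:
    """Noiseless expected count matrix and the generative truth."""
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx))
    mu = (1.0 + dist) ** (-spec.decay_exponent) * _enrichment_matrix(spec)
    if spec.biases is not None:
        b = np.asarray(spec.biases, dtype=float)
        mu *= np.outer(b, b)
    total = np.triu(mu).sum()
    mu *= spec.coverage / total
    truth = TruthRecord(
        boundary_region=spec.boundary_region,
        rho_effective=spec.permeability,
        fused=spec.boundary_region is None,
        junction=spec.wall,
        tads=spec.tads,
    )
    return mu, truth


def simulate_hic(
    spec: SyntheticLocusSpec, noiseless: bool = False
) -> Tuple[ContactMatrix, TruthRecord]:
    """Contact matrix with Poisson counts (or the expected matrix itself)."""
    mu, truth = expected_hic_matrix(spec)
    if noiseless:
        counts = mu
    else:
        rng = np.random.default_rng(spec.seed)
        upper = np.triu(rng.poisson(mu)).astype(float)
        counts = upper + np.triu(upper, 1).T
    matrix = ContactMatrix(spec.extent.chrom, spec.extent.start, spec.bin_size, counts)
    return matrix, truth


def simulate_hic_pairs(
    spec: SyntheticLocusSpec, fragments_per_bin: int = 10
) -> Tuple[List[PairRecord], RestrictionMap, TruthRecord]:
    """Emit valid-class pair records realizing the sampled contact counts.

    Fragments tile the locus regularly; each sampled contact picks one
    fragment per bin (distinct fragments on the diagonal) and a position in
    the fragment interior, so the records survive classification untouched.
    """
    if spec.bin_size % fragments_per_bin != 0:
        raise ValueError("bin_size must be divisible by fragments_per_bin")
    frag_size = spec.bin_size // fragments_per_bin
    if frag_size < 10:
        raise ValueError("fragments too small for interior positioning")
    mu, truth = expected_hic_matrix(spec)
    rng = np.random.default_rng(spec.seed)
    rmap = RestrictionMap.regular(spec.extent.chrom, spec.extent.end, frag_size)
    chrom = spec.extent.chrom
    pairs: List[PairRecord] = []
    n = spec.n_bins
    for i in range(n):
        for j in range(i, n):
            c = rng.poisson(mu[i, j])
            for _ in range(c):
                f1 = i * fragments_per_bin + rng.integers(fragments_per_bin)
                f2 = j * fragments_per_bin + rng.integers(fragments_per_bin)
                if i == j:
                    while f2 == f1:
                        f2 = j * fragments_per_bin + rng.integers(fragments_per_bin)
                # keep the 3-bp assignment shift inside the fragment
                p1 = int(rmap.edges[f1]) + 3 + int(rng.integers(frag_size - 7))
                p2 = int(rmap.edges[f2]) + 3 + int(rng.integers(frag_size - 7))
                s1, s2 = ("+", "-")[rng.integers(2)], ("+", "-")[rng.integers(2)]
                pairs.append(make_pair(chrom, p1, s1, chrom, p2, s2))
    return pairs, rmap, truth


def expected_fourc_signal(
    spec: SyntheticLocusSpec,
    viewpoint: GenomicInterval,
    fragment_size: int = 2_000,
    target_cross_fraction: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-fragment expected 4C signal (unit mass) and the cross fraction.

    Returns (starts, ends, mu, cross_fraction) where ``cross_fraction`` is
    the expected share of TAD-assigned signal lying in the TAD across the
    wall from the viewpoint. With ``target_cross_fraction`` the cross-TAD
    fragments are rescaled so that share is planted exactly.
    """
    if not spec.extent.contains_interval(viewpoint):
        raise ValueError("viewpoint outside extent")
    edges = np.arange(spec.extent.start, spec.extent.end + 1, fragment_size)
    if edges[-1] != spec.extent.end:
        edges = np.append(edges, spec.extent.end)
    starts, ends = edges[:-1], edges[1:]
    mids = (starts + ends) // 2
    vp_mid = viewpoint.midpoint
    d = np.abs(mids - vp_mid).astype(float)
    mu = (1.0 + d) ** (-spec.fourc_decay)
    wall = spec.wall
    if wall is not None:
        cross = (mids < wall) != (vp_mid < wall)
        mu[cross] *= spec.permeability
    for pk in spec.enhancer_peaks:
        mu *= 1.0 + pk.amplitude * np.exp(-((mids - pk.position) ** 2) / (2.0 * pk.width**2))
    member = spec.tad_membership(mids)
    vp_tad = spec.tad_membership(np.array([vp_mid]))[0]
    if vp_tad < 0 or wall is None or len(spec.tads) < 2:
        cross_fraction = 0.0
    else:
        vp_left = spec.tads[vp_tad].interval.midpoint < wall
        same = member == vp_tad
        other = np.zeros_like(same)
        for k, t in enumerate(spec.tads):
            if k != vp_tad and (t.interval.midpoint < wall) != vp_left:
                other |= member == k
        s_same, s_other = mu[same].sum(), mu[other].sum()
        if target_cross_fraction is not None:
            if not 0.0 < target_cross_fraction < 1.0:
                raise ValueError("target_cross_fraction must be in (0, 1)")
            if s_other <= 0:
                raise ValueError("no cross-TAD signal to rescale")
            mu[other] *= (
                target_cross_fraction / (1.0 - target_cross_fraction) * s_same / s_other
            )
            s_other = mu[other].sum()
        cross_fraction = float(s_other / (s_same + s_other))
    mu /= mu.sum()
    return starts, ends, mu, cross_fraction


def simulate_fourc(
    spec: SyntheticLocusSpec,
    viewpoint: GenomicInterval,
    name: str = "viewpoint",
    depth: float = 100_000.0,
    fragment_size: int = 2_000,
    target_cross_fraction: Optional[float] = None,
    noiseless: bool = False,
) -> Tuple[FourCProfile, TruthRecord]:
    """Poisson-sampled 4C viewpoint profile with recorded truth."""
    starts, ends, mu, cross_fraction = expected_fourc_signal(
        spec, viewpoint, fragment_size, target_cross_fraction
    )
    mu = mu * depth
    if noiseless:
        signal = mu
    else:
        rng = np.random.default_rng(spec.seed)
        signal = rng.poisson(mu).astype(float)
    profile = FourCProfile(
        chrom=spec.extent.chrom,
        viewpoint=viewpoint,
        name=name,
        starts=starts,
        ends=ends,
        signal=signal,
    )
    truth = TruthRecord(
        boundary_region=spec.boundary_region,
        rho_effective=spec.permeability,
        fused=spec.boundary_region is None,
        junction=spec.wall,
        expected_cross_fraction=cross_fraction,
        tads=spec.tads,
    )
    return profile, truth


def apply_allele(
    spec: SyntheticLocusSpec, script: EditScript
) -> Tuple[SyntheticLocusSpec, TruthRecord]:
    """Collapse deleted spans out of a locus spec.

    Deleting part of the boundary region raises the effective permeability
    to ``rho' = rho + (1 - rho) * deleted_fraction``; deleting all of it
    fuses the two flanking TADs into one block in the recorded truth.
    Only pure deletions are supported, and the surviving locus must stay
    bin-aligned.
    """
    for e in script.edits:
        if e.kind != "deletion" or e.inserted_length:
            raise NotImplementedError("only pure deletions are supported for alleles")
    if script.backbone != spec.extent.chrom or script.backbone_length != spec.extent.end:
        raise ValueError("edit script backbone does not match the locus extent")
    deletions = [e.wt_interval for e in script.edits]
    total_deleted = sum(iv.length for iv in deletions)
    if total_deleted >= spec.extent.length:
        raise ValueError("cannot delete the entire locus")
    if (spec.extent.length - total_deleted) % spec.bin_size != 0:
        raise ValueError("deletions must leave a bin-aligned locus")
    cmap = script.coordinate_map(mut_name=spec.extent.chrom)

    def collapse(pos: int) -> int:
        return cmap.collapse_to_mut(pos)

    def collapse_interval(iv: GenomicInterval) -> Optional[GenomicInterval]:
        s, e = collapse(iv.start), collapse(iv.end)
        if e <= s:
            return None
        return GenomicInterval(iv.chrom, s, e)

    new_extent = GenomicInterval(
        spec.extent.chrom, 0, spec.extent.length - total_deleted
    )
    new_tads = tuple(
        TADBlock(niv, t.intra_factor)
        for t in spec.tads
        if (niv := collapse_interval(t.interval)) is not None
    )
    rho = spec.permeability
    fused = False
    junction = None
    new_boundary = spec.boundary_region
    if spec.boundary_region is not None:
        cut = sum(
            ov.length
            for iv in deletions
            if (ov := iv.intersection(spec.boundary_region)) is not None
        )
        frac = cut / spec.boundary_region.length
        junction = collapse(spec.boundary_region.start)
        if frac >= 1.0:
            fused = True
            new_boundary = None
            rho = 1.0
            # merge the TADs flanking the removed boundary into one block
            flanking = [
                t for t in new_tads
                if t.interval.end == junction or t.interval.start == junction
            ]
            if len(flanking) == 2:
                merged = TADBlock(
                    GenomicInterval(
                        new_extent.chrom,
                        min(t.interval.start for t in flanking),
                        max(t.interval.end for t in flanking),
                    ),
                    float(np.mean([t.intra_factor for t in flanking])),
                )
                new_tads = tuple(
                    sorted(
                        [t for t in new_tads if t not in flanking] + [merged],
                        key=lambda t: t.interval.start,
                    )
                )
        else:
            rho = rho + (1.0 - rho) * frac
            new_boundary = collapse_interval(spec.boundary_region)
    new_biases = spec.biases
    if new_biases is not None:
        for iv in deletions:
            if iv.start % spec.bin_size or iv.end % spec.bin_size:
                raise ValueError("per-bin biases require bin-aligned deletions")
        keep = np.ones(spec.n_bins, dtype=bool)
        for iv in deletions:
            keep[iv.start // spec.bin_size : iv.end // spec.bin_size] = False
        new_biases = tuple(np.asarray(spec.biases)[keep])
    new_peaks = []
    for pk in spec.enhancer_peaks:
        if any(iv.contains(pk.position) for iv in deletions):
            continue
        new_peaks.append(replace(pk, position=collapse(pk.position)))
    new_spec = replace(
        spec,
        extent=new_extent,
        tads=new_tads,
        boundary_region=new_boundary,
        permeability=min(rho, 1.0),
        biases=new_biases,
        enhancer_peaks=tuple(new_peaks),
    )
    truth = TruthRecord(
        boundary_region=new_boundary,
        rho_effective=min(rho, 1.0),
        fused=fused,
        junction=junction,
        tads=new_tads,
    )
    return new_spec, truth
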
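"""In silico mutant chromosomes and exact coordinate liftover.

An :class:`EditScript` lists ordered, non-overlapping deletions/insertions on
a backbone chromosome. Applying it yields the mutant sequence and a
:class:`CoordinateMap` of collinear blocks that lifts positions, intervals,
and binned contact matrices between the two genomes.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hic import ContactMatrix
from .intervals import GenomicInterval

EDIT_KINDS = ("deletion", "insertion")


@dataclass(frozen=True)
class Edit:
    """One deletion or insertion on the backbone.

    Deletions may carry a replacement cassette (``inserted_length > 0``),
    mirroring deletion-plus-transgene alleles. Insertions use a zero-length
    ``wt_interval`` anchor. When no cassette sequence is given, N-fill of the
    stated length is used.
    """

    kind: str
    wt_interval: GenomicInterval
    inserted_length: int = 0
    inserted_sequence: Optional[str] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"edit {self.label!r}: unknown kind {self.kind!r}")
        if self.kind == "deletion" and self.wt_interval.length == 0:
            raise ValueError(f"edit {self.label!r}: deletion must remove bases")
        if self.kind == "insertion":
            if self.wt_interval.length != 0:
                raise ValueError(
                    f"edit {self.label!r}: insertion anchor must be zero-length"
                )
            if self.inserted_length <= 0:
                raise ValueError(f"edit {self.label!r}: insertion needs a length")
        if self.inserted_length < 0:
            raise ValueError(f"edit {self.label!r}: negative inserted_length")
        if (
            self.inserted_sequence is not None
            and len(self.inserted_sequence) != self.inserted_length
        ):
            raise ValueError(
                f"edit {self.label!r}: cassette sequence length "
                f"{len(self.inserted_sequence)} != inserted_length {self.inserted_length}"
            )

    def cassette(self) -> str:
        if self.inserted_length == 0:
            return ""
        return self.inserted_sequence or "N" * self.inserted_length


@dataclass(frozen=True)
class EditScript:
    """Ordered, non-overlapping edits on one backbone chromosome."""

    backbone: str
    backbone_length: int
    edits: Tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edits", tuple(sorted(self.edits, key=lambda e: e.wt_interval.start))
        )
        prev_end = 0
        prev_label = None
        for e in self.edits:
            iv = e.wt_interval
            if iv.chrom != self.backbone:
                raise ValueError(
                    f"edit {e.label!r} is on {iv.chrom}, not backbone {self.backbone}"
                )
            if iv.start < 0 or iv.end > self.backbone_length:
                raise ValueError(f"edit {e.label!r} lies outside the backbone")
            if iv.start < prev_end:
                raise ValueError(f"edits {prev_label!r} and {e.label!r} overlap")
            prev_end = iv.end
            prev_label = e.label

    @property
    def mutant_length(self) -> int:
        length = self.backbone_length
        for e in self.edits:
            length += e.inserted_length - e.wt_interval.length
        return length

    def coordinate_map(self, mut_name: Optional[str] = None) -> "CoordinateMap":
        """Derive the block-wise wild-type <-> mutant position mapping."""
        mut_name = mut_name or f"{self.backbone}_mut"
        blocks: List[Tuple[GenomicInterval, GenomicInterval]] = []
        deleted: List[GenomicInterval] = []
        inserted: List[GenomicInterval] = []
        wt_cur = 0
        mut_cur = 0
        for e in self.edits:
            iv = e.wt_interval
            if iv.start > wt_cur:
                size = iv.start - wt_cur
                blocks.append(
                    (
                        GenomicInterval(self.backbone, wt_cur, iv.start),
                        GenomicInterval(mut_name, mut_cur, mut_cur + size),
                    )
                )
                mut_cur += size
            if e.kind == "deletion":
                deleted.append(iv)
            if e.inserted_length > 0:
                inserted.append(
                    GenomicInterval(mut_name, mut_cur, mut_cur + e.inserted_length)
                )
                mut_cur += e.inserted_length
            wt_cur = iv.end
        if wt_cur < self.backbone_length:
            size = self.backbone_length - wt_cur
            blocks.append(
                (
                    GenomicInterval(self.backbone, wt_cur, self.backbone_length),
                    GenomicInterval(mut_name, mut_cur, mut_cur + size),
                )
            )
            mut_cur += size
        return CoordinateMap(
            wt_name=self.backbone,
            mut_name=mut_name,
            wt_length=self.backbone_length,
            mut_length=mut_cur,
            blocks=tuple(blocks),
            deleted=tuple(deleted),
            inserted=tuple(inserted),
        )


@dataclass(frozen=True)
class CoordinateMap:
    """Exact bidirectional mapping induced by an edit script.

    ``blocks`` are disjoint, order-preserving collinear segments; mapping
    within a block is offset-only. ``deleted`` wild-type intervals have no
    mutant image, ``inserted`` mutant intervals no wild-type image.
    """

    wt_name: str
    mut_name: str
    wt_length: int
    mut_length: int
    blocks: Tuple[Tuple[GenomicInterval, GenomicInterval], ...]
    deleted: Tuple[GenomicInterval, ...] = ()
    inserted: Tuple[GenomicInterval, ...] = ()
    _wt_starts: Tuple[int, ...] = field(init=False, repr=False, compare=False)
    _mut_starts: Tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for (wt, mut) in self.blocks:
            if wt.length != mut.length:
                raise ValueError(f"block {wt} -> {mut} is not collinear")
        object.__setattr__(self, "_wt_starts", tuple(b[0].start for b in self.blocks))
        object.__setattr__(self, "_mut_starts", tuple(b[1].start for b in self.blocks))

    def _lift(self, pos: int, starts, src_idx: int, dst_idx: int, length: int):
        if pos < 0 or pos >= length:
            raise ValueError(f"position {pos} out of range [0, {length})")
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        src = self.blocks[i][src_idx]
        if pos >= src.end:
            return None
        return pos - src.start + self.blocks[i][dst_idx].start

    def lift_position(self, pos: int, direction: str = "wt_to_mut") -> Optional[int]:
        """Map a position across genomes; ``None`` inside deleted/inserted DNA."""
        if direction == "wt_to_mut":
            return self._lift(pos, self._wt_starts, 0, 1, self.wt_length)
        if direction == "mut_to_wt":
            return self._lift(pos, self._mut_starts, 1, 0, self.mut_length)
        raise ValueError(f"unknown direction {direction!r}")

    def collapse_to_mut(self, pos: int) -> int:
        """Mutant coordinate of ``pos``, collapsing deleted DNA to its junction."""
        if pos < 0 or pos > self.wt_length:
            raise ValueError(f"position {pos} out of range [0, {self.wt_length}]")
        out = self.mut_length
        for (wt, mut) in self.blocks:
            if pos < wt.start:
                return mut.start
            if pos < wt.end:
                return pos - wt.start + mut.start
            out = mut.end
        return out


def build_mutant(
    backbone_sequence: str, script: EditScript
) -> Tuple[str, CoordinateMap]:
    """Apply an edit script to a backbone sequence.

    Returns the mutant sequence and the induced coordinate map. The mutant
    length equals backbone length minus deletions plus insertions/cassettes.
    """
    if len(backbone_sequence) != script.backbone_length:
        raise ValueError(
            f"backbone sequence length {len(backbone_sequence)} != declared "
            f"{script.backbone_length}"
        )
    parts: List[str] = []
    cursor = 0
    for e in script.edits:
        iv = e.wt_interval
        parts.append(backbone_sequence[cursor:iv.start])
        parts.append(e.cassette())
        cursor = iv.end
    parts.append(backbone_sequence[cursor:])
    mutant = "".join(parts)
    cmap = script.coordinate_map()
    assert len(mutant) == cmap.mut_length
    return mutant, cmap


def lift_matrix_to_backbone(
    mut_matrix: ContactMatrix,
    cmap: CoordinateMap,
    wt_extent: Optional[GenomicInterval] = None,
) -> Tuple[ContactMatrix, List[int]]:
    """Re-frame a mutant-coordinate matrix on the wild-type bin grid.

    Wild-type bins with no complete, bin-aligned mutant image (deleted bins
    and bins straddling an edit junction) are masked and listed in
    ``dropped_bins``. Mutant bins made only of inserted DNA are discarded.
    A block whose offset is incompatible with the bin size raises, listing
    the straddling bins.
    """
    bs = mut_matrix.bin_size
    if wt_extent is None:
        wt_end = -(-cmap.wt_length // bs) * bs
        wt_extent = GenomicInterval(cmap.wt_name, 0, wt_end)
    if wt_extent.start % bs != 0:
        raise ValueError("wild-type extent start must be bin-aligned")
    n_wt = -(-wt_extent.length // bs)
    mapped: dict[int, int] = {}
    dropped: List[int] = []
    misaligned: List[int] = []
    for k in range(n_wt):
        s = wt_extent.start + k * bs
        e = min(s + bs, cmap.wt_length)
        if e <= s:
            dropped.append(k)
            continue
        wbin = GenomicInterval(cmap.wt_name, s, e)
        block = None
        for (wt, mut) in cmap.blocks:
            if wt.start <= s < wt.end:
                block = (wt, mut)
                break
        if block is None:
            # bin starts inside deleted DNA
            dropped.append(k)
            continue
        wt, mut = block
        if e > wt.end:
            # straddles a junction: dropped whole, never partially lifted
            dropped.append(k)
            continue
        offset = mut.start - wt.start
        if offset % bs != 0:
            misaligned.append(k)
            continue
        mpos = s + offset
        if mpos < mut_matrix.start or mpos + bs > mut_matrix.end:
            dropped.append(k)
            continue
        if (mpos - mut_matrix.start) % bs != 0:
            misaligned.append(k)
            continue
        mapped[k] = (mpos - mut_matrix.start) // bs
    if misaligned:
        raise ValueError(
            "bin size incompatible with block offsets; straddling bins: "
            + ", ".join(str(b) for b in misaligned)
        )
    counts = np.zeros((n_wt, n_wt), dtype=float)
    mask = np.ones(n_wt, dtype=bool)
    wt_bins = np.array(sorted(mapped), dtype=int)
    mut_bins = np.array([mapped[k] for k in wt_bins], dtype=int)
    if wt_bins.size:
        counts[np.ix_(wt_bins, wt_bins)] = mut_matrix.counts[np.ix_(mut_bins, mut_bins)]
        mask[wt_bins] = mut_matrix.mask[mut_bins]
    counts[mask, :] = 0.0
    counts[:, mask] = 0.0
    out = ContactMatrix(
        cmap.wt_name, wt_extent.start, bs, counts, mask=mask,
        normalized=mut_matrix.normalized,
    )
    dropped_all = sorted(set(dropped) | (set(np.where(mask)[0]) - set(wt_bins.tolist())))
    return out, dropped_all


def mask_dropped_bins(matrix: ContactMatrix, dropped_bins: Sequence[int]) -> ContactMatrix:
    """Mask the same dropped bins in a wild-type matrix so the pair of
    matrices is comparable before normalization."""
    mask = np.zeros(matrix.n_bins, dtype=bool)
    idx = np.asarray(list(dropped_bins), dtype=int)
    if idx.size:
        if idx.min() < 0 or idx.max() >= matrix.n_bins:
            raise ValueError("dropped bin index outside matrix")
        mask[idx] = True
    return matrix.with_mask(mask)
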
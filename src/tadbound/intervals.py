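"""Genomic interval primitives shared across the toolkit.

All coordinates are 0-based and half-open (``[start, end)``), matching BED
conventions. Printed 1-based inclusive coordinates must be converted on
ingestion by subtracting 1 from the start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Zero-length intervals (``start == end``) are permitted only as insertion
    anchors; all other uses require ``start < end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    @classmethod
    def from_string(cls, text: str, chrom: Optional[str] = None) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        name, start, end = m.group(1), m.group(2), m.group(3)
        return cls(chrom or name, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"
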
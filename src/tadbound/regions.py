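"""mm10 reference coordinates for the two-TAD locus on chromosome 2.

Fragment-level 4C coordinates were published 1-based inclusive and are
converted here to 0-based half-open (start - 1). The Hi-C domain and
deleted-bin spans are 40-kb bin-edge coordinates and are used as-is.
"""

from __future__ import annotations

from .fourc import RegionPanel
from .intervals import GenomicInterval

CHROM = "chr2"

#: telomeric and centromeric regulatory domains used for 4C contact ratios
TDOM_4C = GenomicInterval(CHROM, 74_781_515, 75_605_516)
CDOM_4C = GenomicInterval(CHROM, 73_914_153, 74_636_454)

#: bin-aligned domain spans used for Hi-C contact-intensity comparisons
CDOM_HIC = GenomicInterval(CHROM, 73_960_000, 74_680_000)
TDOM_HIC = GenomicInterval(CHROM, 74_720_000, 75_600_000)

#: 3-Mb analysis window around the cluster
LOCUS_WINDOW = GenomicInterval(CHROM, 73_320_000, 76_480_000)

#: bins deleted in the full-deletion allele, removed from both genotypes
FULL_DELETION_BINS = GenomicInterval(CHROM, 74_400_000, 74_760_000)

#: offset bounds (viewpoint at 0) for cumulative contact curves
CUMULATIVE_BOUNDS = {
    "island-4": (-1_092_537, 2_006_380),
    "CS38": (-1_957_157, 1_141_528),
}


def enhancer_region_panel() -> RegionPanel:
    """Regulatory regions quantified by interval intersection (mm10)."""
    raw = {
        "island-1": (73_970_064, 73_983_434),
        "island-2": (74_060_473, 74_082_287),
        "island-3": (74_177_798, 74_223_313),
        "island-4": (74_263_814, 74_284_643),
        "island-5": (74_289_658, 74_313_573),
        "GCR": (74_445_394, 74_498_046),
        "Prox": (74_604_505, 74_639_799),
        "CS38-41": (75_120_051, 75_165_771),
        "CS65": (75_413_472, 75_451_553),
    }
    return RegionPanel(
        {name: GenomicInterval(CHROM, start - 1, end) for name, (start, end) in raw.items()}
    )
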
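"""Plain-text readers/writers for the formats the pipeline consumes.

Matrices travel as dense TSV (or sparse bin1/bin2/value triplets) plus a
JSON sidecar holding the grid (chrom, extent, bin size), mask, and bias
vector. Everything else uses standard BED/bedGraph/FASTA/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import Edit, EditScript
from .fourc import FourCProfile, RegionPanel
from .hic import ContactMatrix, PairRecord, RestrictionMap, make_pair
from .intervals import GenomicInterval

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> dict:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: dict) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: PathLike) -> List[Tuple[GenomicInterval, str]]:
    """Read BED3/BED4 into (interval, name) tuples; name '' if absent."""
    out: List[Tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), name))
    return out


def write_bed(path: PathLike, records: Iterable[Tuple[GenomicInterval, str]]) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if name:
                fields.append(name)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(
    path: PathLike,
    chrom: str,
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# pairs


PAIRS_COLUMNS = ("chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2")


def read_pairs(path: PathLike) -> List[PairRecord]:
    """Read pairs TSV (chrom1 pos1 chrom2 pos2 strand1 strand2)."""
    out: List[PairRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c1, p1, c2, p2, s1, s2 = line.split("\t")[:6]
            out.append(make_pair(c1, int(p1), s1, c2, int(p2), s2))
    return out


def write_pairs(path: PathLike, pairs: Iterable[PairRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.chrom1}\t{p.pos1}\t{p.chrom2}\t{p.pos2}\t{p.strand1}\t{p.strand2}\n"
            )


# ---------------------------------------------------------------------------
# restriction map


def read_restriction_map(path: PathLike) -> RestrictionMap:
    frags = [iv for iv, _ in read_bed(path)]
    return RestrictionMap.from_fragments(frags)


def write_restriction_map(path: PathLike, rmap: RestrictionMap) -> None:
    write_bed(
        path, ((rmap.fragment(i), f"frag_{i}") for i in range(rmap.n_fragments))
    )


# ---------------------------------------------------------------------------
# contact matrices


def _sidecar_path(path: PathLike) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path: PathLike, m: ContactMatrix, fmt: str) -> None:
    meta = {
        "format": fmt,
        "chrom": m.chrom,
        "start": m.start,
        "end": m.end,
        "bin_size": m.bin_size,
        "n_bins": m.n_bins,
        "masked_bins": [int(i) for i in np.where(m.mask)[0]],
        "normalized": m.normalized,
        "converged": m.converged,
        "biases": None if m.biases is None else [
            None if np.isnan(b) else float(b) for b in m.biases
        ],
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def write_matrix(m: ContactMatrix, path: PathLike, fmt: str = "dense") -> None:
    """Write a matrix as dense TSV or sparse upper-triangle triplets."""
    counts = np.where(np.isnan(m.counts), 0.0, m.counts)
    if fmt == "dense":
        np.savetxt(path, counts, delimiter="\t", fmt="%.10g")
    elif fmt == "sparse":
        iu, ju = np.nonzero(np.triu(counts))
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{counts[i, j]:.10g}\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    _write_sidecar(path, m, fmt)


def read_matrix(path: PathLike) -> ContactMatrix:
    with open(_sidecar_path(path)) as fh:
        meta = json.load(fh)
    n = meta["n_bins"]
    if meta["format"] == "dense":
        counts = np.loadtxt(path, delimiter="\t", ndmin=2)
        if counts.shape != (n, n):
            raise ValueError(f"matrix shape {counts.shape} != sidecar n_bins {n}")
    else:
        counts = np.zeros((n, n))
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                i, j, v = line.split("\t")
                counts[int(i), int(j)] = float(v)
                counts[int(j), int(i)] = float(v)
    mask = np.zeros(n, dtype=bool)
    mask[meta["masked_bins"]] = True
    biases = None
    if meta["biases"] is not None:
        biases = np.array(
            [np.nan if b is None else b for b in meta["biases"]], dtype=float
        )
    return ContactMatrix(
        meta["chrom"], meta["start"], meta["bin_size"], counts,
        mask=mask, biases=biases, normalized=meta["normalized"],
        converged=meta.get("converged"),
    )


# ---------------------------------------------------------------------------
# edit scripts


EDIT_SCRIPT_HEADER = "label\tkind\tchrom\tstart\tend\tinserted_length\tinserted_sequence"


def read_edit_script(path: PathLike, backbone: str, backbone_length: int) -> EditScript:
    """Read an edit-script TSV (label, kind, chrom, start, end,
    inserted_length, inserted_sequence with '-' for none)."""
    edits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "label\t")):
                continue
            label, kind, chrom, start, end, ins_len, ins_seq = line.split("\t")[:7]
            edits.append(
                Edit(
                    kind=kind,
                    wt_interval=GenomicInterval(chrom, int(start), int(end)),
                    inserted_length=int(ins_len),
                    inserted_sequence=None if ins_seq == "-" else ins_seq,
                    label=label,
                )
            )
    return EditScript(backbone, backbone_length, tuple(edits))


def write_edit_script(path: PathLike, script: EditScript) -> None:
    with open(path, "w") as fh:
        fh.write(EDIT_SCRIPT_HEADER + "\n")
        for e in script.edits:
            iv = e.wt_interval
            fh.write(
                "\t".join(
                    [
                        e.label or ".",
                        e.kind,
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        str(e.inserted_length),
                        e.inserted_sequence or "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# 4C profiles


def read_fourc_profile(
    bedgraph_path: PathLike,
    viewpoint: GenomicInterval,
    name: str = "viewpoint",
) -> FourCProfile:
    """Read per-fragment 4C signal from bedGraph (one chromosome)."""
    df = read_bedgraph(bedgraph_path)
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("4C profile bedGraph must cover a single chromosome")
    df = df.sort_values("start")
    return FourCProfile(
        chrom=str(chroms[0]),
        viewpoint=viewpoint,
        name=name,
        starts=df["start"].to_numpy(),
        ends=df["end"].to_numpy(),
        signal=df["value"].to_numpy(dtype=float),
    )


def write_fourc_profile(path: PathLike, p: FourCProfile) -> None:
    write_bedgraph(path, p.chrom, p.starts, p.ends, p.signal)


def read_region_panel(path: PathLike) -> RegionPanel:
    records = read_bed(path)
    regions = {}
    for i, (iv, name) in enumerate(records):
        regions[name or f"region_{i}"] = iv
    return RegionPanel(regions)


def write_region_panel(path: PathLike, panel: RegionPanel) -> None:
    write_bed(path, ((iv, name) for name, iv in panel.items()))
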
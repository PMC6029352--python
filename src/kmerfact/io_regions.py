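"""Turn per-cell aligned reads into merged Tn5-window intervals and sequences.

Accessible chromatin is read out as the 5' ends of sequenced ATAC fragments,
each marking a Tn5 transposase integration site.  Every integration site is
expanded into a fixed-flank window (default 50 bp to either side), overlapping
windows are merged (which also collapses PCR duplicates), and the underlying
DNA is extracted for downstream k-mer counting.

Coordinates are 0-based half-open (BED convention) throughout: a 5' end at
position ``p`` with flank ``f`` yields the window ``[p - f, p + f)``, clamped
at chromosome boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CellReadSet",
    "RegionSequenceSet",
    "tn5_windows",
    "merge_intervals",
    "extract_sequences",
    "qc_filter_cells",
    "partition_reads_by_peaks",
    "read_bed_reads",
    "read_sam_reads",
    "read_bed_intervals",
    "write_bed",
    "qc_report",
]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class CellReadSet:
    """The Tn5 integration sites of one cell.

    ``integration_sites`` holds ``(chrom, position, strand)`` triples, one per
    read; ``position`` is the 5' end of the read on the forward strand.
    ``n_distinct_loci`` is the number of merged Tn5 windows and is filled in
    by :func:`tn5_windows` (duplicate reads collapse into one locus).
    """

    cell_id: str
    integration_sites: list[tuple[str, int, str]] = field(default_factory=list)
    n_distinct_loci: int | None = None

    @property
    def n_reads(self) -> int:
        return len(self.integration_sites)


@dataclass(slots=True)
class RegionSequenceSet:
    """DNA sequences of one cell's merged accessibility windows.

    Sequences are forward-strand, over ``{A,C,G,T,N}`` plus lowercase for
    repeat-masked stretches.  Masked/ambiguous characters act as scan breaks
    during k-mer counting; they are never deleted from coordinates.
    """

    cell_id: str
    sequences: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome access helpers (pyfaidx.Fasta or a plain mapping chrom -> sequence)
# ---------------------------------------------------------------------------

def _chrom_length(genome, chrom: str) -> int:
    rec = genome[chrom]
    return len(rec)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    rec = genome[chrom]
    if isinstance(rec, str):
        return rec[start:end]
    return str(rec[start:end])  # pyfaidx FastaRecord slice


def _has_chrom(genome, chrom: str) -> bool:
    try:
        genome[chrom]
        return True
    except KeyError:
        return False


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals into a sorted disjoint set."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def tn5_windows(
    reads: CellReadSet,
    flank: int = 50,
    genome=None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Expand each integration site into ``[p - flank, p + flank)`` and merge.

    Merging removes duplicate reads: identical 5' ends yield one window.  The
    merged window count is recorded on ``reads.n_distinct_loci``.  Windows are
    clamped to ``[0, chrom_length)`` when chromosome sizes are known; an
    unknown chromosome raises ``KeyError`` naming it.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    sizes: dict[str, int] = dict(chrom_sizes or {})
    raw: list[GenomicInterval] = []
    for chrom, pos, _strand in reads.integration_sites:
        if chrom not in sizes:
            if genome is not None:
                if not _has_chrom(genome, chrom):
                    raise KeyError(f"unknown chromosome: {chrom!r}")
                sizes[chrom] = _chrom_length(genome, chrom)
            elif chrom_sizes is not None:
                raise KeyError(f"unknown chromosome: {chrom!r}")
        start = max(0, pos - flank)
        end = pos + flank
        if chrom in sizes:
            end = min(end, sizes[chrom])
            start = min(start, max(0, sizes[chrom] - 1))
        raw.append(GenomicInterval(chrom, start, end))
    merged = merge_intervals(raw) if raw else []
    reads.n_distinct_loci = len(merged)
    return merged


def extract_sequences(
    intervals: Sequence[GenomicInterval],
    genome,
    exclude_masked: bool = False,
    cell_id: str = "",
) -> RegionSequenceSet:
    """Fetch the forward-strand DNA of each interval.

    With ``exclude_masked`` the lowercase (repeat-masked) state of the genome
    is preserved so that masked stretches break k-mer scans; otherwise the
    sequence is uppercased and masked bases are scanned like any other.
    """
    seqs: list[str] = []
    for iv in intervals:
        if not _has_chrom(genome, iv.chrom):
            raise KeyError(f"unknown chromosome: {iv.chrom!r}")
        if iv.end > _chrom_length(genome, iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {_chrom_length(genome, iv.chrom)}"
            )
        seq = _fetch(genome, iv.chrom, iv.start, iv.end)
        if len(seq) != len(iv):
            raise ValueError(f"fetched sequence length mismatch for {iv!r}")
        seqs.append(seq if exclude_masked else seq.upper())
    return RegionSequenceSet(cell_id=cell_id, sequences=seqs)


def qc_filter_cells(
    cells: Sequence[CellReadSet],
    min_loci: int = 3162,
) -> tuple[list[CellReadSet], list[str]]:
    """Keep cells with at least ``min_loci`` distinct Tn5 integration loci.

    The default of 3162 (10^3.5 truncated to an integer) removes dead cells
    and poor-quality libraries.  ``n_distinct_loci`` must already be set
    (by :func:`tn5_windows`).  Returns (kept cells in input order, excluded
    cell ids).
    """
    if min_loci < 0:
        raise ValueError("min_loci must be non-negative")
    kept: list[CellReadSet] = []
    excluded: list[str] = []
    for cell in cells:
        if cell.n_distinct_loci is None:
            raise ValueError(f"cell {cell.cell_id}: n_distinct_loci not computed")
        if cell.n_distinct_loci >= min_loci:
            kept.append(cell)
        else:
            excluded.append(cell.cell_id)
    return kept, excluded


def partition_reads_by_peaks(
    reads: CellReadSet,
    peaks: Sequence[GenomicInterval],
    pad: int = 250,
) -> tuple[CellReadSet, CellReadSet]:
    """Split reads into in-peak / out-of-peak by their 5' ends.

    Peaks are padded by ``pad`` bases on each side (clamped at zero) and
    merged; a read is "in a peak" iff its transposition site (5' end) falls
    inside the padded peak set.  Every read lands in exactly one partition.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    padded = merge_intervals(
        GenomicInterval(p.chrom, max(0, p.start - pad), p.end + pad) for p in peaks
    ) if peaks else []
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in padded}:
        ivs = [p for p in padded if p.chrom == chrom]
        starts[chrom] = np.array([p.start for p in ivs])
        ends[chrom] = np.array([p.end for p in ivs])
    inside = CellReadSet(cell_id=reads.cell_id)
    outside = CellReadSet(cell_id=reads.cell_id)
    for site in reads.integration_sites:
        chrom, pos, _ = site
        hit = False
        if chrom in starts:
            i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
            hit = i >= 0 and pos < ends[chrom][i]
        (inside if hit else outside).integration_sites.append(site)
    return inside, outside


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | Path) -> dict[str, CellReadSet]:
    """Read per-read BED6 records into per-cell read sets.

    One record per read; the name field carries the cell id.  The 5' end is
    ``start`` for ``+`` strand reads and ``end - 1`` for ``-`` strand reads.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    cells: dict[str, CellReadSet] = {}
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in {"+", "-"} else "+"
        pos = int(row.start) if strand == "+" else int(row.end) - 1
        cells.setdefault(row.name, CellReadSet(cell_id=row.name)) \
            .integration_sites.append((row.chrom, pos, strand))
    return cells


def read_sam_reads(path: str | Path, cell_tag: str = "CB") -> dict[str, CellReadSet]:
    """Read aligned reads (SAM/BAM) into per-cell read sets.

    The cell id comes from ``cell_tag`` (default the CB tag), falling back to
    the read group.  Unmapped and secondary/supplementary records are skipped.
    The 5' end of a reverse-strand read is its rightmost aligned base.
    """
    import pysam

    cells: dict[str, CellReadSet] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag(cell_tag):
                cid = str(rec.get_tag(cell_tag))
            elif rec.has_tag("RG"):
                cid = str(rec.get_tag("RG"))
            else:
                continue
            pos = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            strand = "-" if rec.is_reverse else "+"
            cells.setdefault(cid, CellReadSet(cell_id=cid)) \
                .integration_sites.append((rec.reference_name, pos, strand))
    return cells


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (extra columns ignored)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return ivs


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, name: str = "") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name:
                cols += [name, "0", iv.strand if iv.strand != "." else "+"]
            fh.write("\t".join(cols) + "\n")


def qc_report(cells: Sequence[CellReadSet], min_loci: int) -> pd.DataFrame:
    """Per-cell QC table: reads, distinct loci, kept flag."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "n_reads": [c.n_reads for c in cells],
            "n_distinct_loci": [c.n_distinct_loci for c in cells],
            "kept": [
                c.n_distinct_loci is not None and c.n_distinct_loci >= min_loci
                for c in cells
            ],
        }
    )
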
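"""Replication-timing cell-cycle scoring.

Genomes replicate in a stereotyped order across S phase; Repli-seq assigns
each region a percent-signal track per cell-cycle fraction (G1, S1-S4, G2).
Regions whose signal exceeds a cutoff (default 25%) are called replication
domains for that phase.  A cell's reads are apportioned to phase domains by
their 5' ends, scaled to per-cell proportions, and the ratio
(G2 + S1 + S2 + S3 + S4) / G1 separates cycling cells (which gain coverage
in later-replicating domains) from G1 cells.  Reads overlapping domains of
several phases count once per phase they hit; the ratio is depth-invariant
because proportions are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_regions import CellReadSet, GenomicInterval, merge_intervals

__all__ = ["PHASES", "ReplicationDomains", "call_domains", "phase_ratio", "phase_ratio_table"]

PHASES = ("G1", "S1", "S2", "S3", "S4", "G2")


@dataclass
class ReplicationDomains:
    """Replication domains of one cell-cycle phase."""

    phase: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")


def call_domains(
    signal: Sequence[tuple[GenomicInterval, float]],
    phase: str,
    cutoff: float = 25.0,
) -> ReplicationDomains:
    """Call one phase's domains from a percent-signal track.

    Regions with signal strictly greater than ``cutoff`` are kept (a region
    exactly at the cutoff is excluded) and adjacent kept regions merged.
    """
    for iv, s in signal:
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"percent signal out of [0,100]: {s} at {iv!r}")
    kept = [iv for iv, s in signal if s > cutoff]
    return ReplicationDomains(phase=phase, intervals=merge_intervals(kept) if kept else [])


def _domain_arrays(domains: ReplicationDomains) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in domains.intervals}:
        ivs = sorted((iv for iv in domains.intervals if iv.chrom == chrom),
                     key=lambda iv: iv.start)
        out[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    return out


def phase_ratio(
    reads: CellReadSet,
    domains: Mapping[str, ReplicationDomains],
) -> tuple[float, dict[str, float]]:
    """(G2 + S1 + S2 + S3 + S4) / G1 read-proportion ratio for one cell.

    Returns ``(ratio, per_phase_proportions)``.  Proportions are reads whose
    5' end lands in a phase's domains divided by the cell's total reads, so
    the ratio is invariant to sequencing depth.  With no G1 reads the ratio
    is ``inf`` (sentinel for an uninformative denominator).
    """
    missing = set(PHASES) - set(domains)
    if missing:
        raise ValueError(f"domains missing for phases: {sorted(missing)}")
    total = reads.n_reads
    if total == 0:
        raise ValueError(f"cell {reads.cell_id!r} has no reads")
    props: dict[str, float] = {}
    for phase in PHASES:
        arrays = _domain_arrays(domains[phase])
        hits = 0
        for chrom, pos, _ in reads.integration_sites:
            if chrom not in arrays:
                continue
            starts, ends = arrays[chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                hits += 1
        props[phase] = hits / total
    g1 = props["G1"]
    non_g1 = sum(props[p] for p in PHASES if p != "G1")
    if g1 == 0:
        return (math.inf if non_g1 > 0 else 0.0), props
    return non_g1 / g1, props


def phase_ratio_table(
    cells: Sequence[CellReadSet],
    domains: Mapping[str, ReplicationDomains],
) -> pd.DataFrame:
    """Per-cell phase proportions and (G2+S)/G1 ratio as a table."""
    rows = []
    for cell in cells:
        ratio, props = phase_ratio(cell, domains)
        rows.append({"cell_id": cell.cell_id, **props, "g2s_g1_ratio": ratio})
    return pd.DataFrame(rows)
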
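"""Synthetic fixtures: genome, reads, motif files, replication domains, counts.

The generator emulates the causal model the pipeline is built to invert: a
cell's TF activities determine which motif-bearing loci are accessible, and
accessible loci determine where Tn5 integrates.  Concretely, motif
occurrences are planted in an iid background genome; per cell, each
occurrence of motif m is "open" with probability 1 - exp(-a_m) where a_m is
the cell group's activity for m; reads then sample open sites (with
positional jitter) plus a uniform background, so groups differing in
activity differ in the k-mer content of their accessible sequence.
Replicating cells draw an extra slice of reads from S/G2 replication-timing
domains.  Matching TF specificity files (PWMs and PBM 8-mer Z tables,
including decoy TFs) and NB-distributed expression counts complete the set
of pipeline inputs.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cellcycle import PHASES, ReplicationDomains, call_domains
from .io_regions import CellReadSet, GenomicInterval
from .kmers import reverse_complement

__all__ = [
    "MotifSpec",
    "CellGroup",
    "SimulationConfig",
    "default_config",
    "make_genome",
    "make_repli_domains",
    "simulate_cells",
    "make_motif_files",
    "simulate_expression",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class MotifSpec:
    """A planted TF motif: consensus word, sharpness, occurrence count."""

    name: str
    consensus: str
    info: float = 0.95  # probability of the consensus base at each position
    n_occurrences: int = 250

    def __post_init__(self) -> None:
        if any(c not in "ACGT" for c in self.consensus):
            raise ValueError("consensus must be over ACGT")
        if not 0.25 < self.info <= 1.0:
            raise ValueError("info must be in (0.25, 1]")

    def pwm(self) -> np.ndarray:
        w = len(self.consensus)
        pwm = np.full((w, 4), (1.0 - self.info) / 3.0)
        for i, c in enumerate(self.consensus):
            pwm[i, _BASE_INDEX[c]] = self.info
        return pwm


@dataclass(frozen=True)
class CellGroup:
    """A group of cells sharing a TF activity program."""

    name: str
    n_cells: int
    activities: Mapping[str, float]  # motif name -> activity level (>= 0)
    treatment: str = "untreated"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if any(a < 0 for a in self.activities.values()):
            raise ValueError("activity levels must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset."""

    seed: int = 0
    genome_length: int = 200_000
    n_chroms: int = 2
    motifs: list[MotifSpec] = field(default_factory=list)
    groups: list[CellGroup] = field(default_factory=list)
    reads_per_cell: int = 5_000
    background_read_fraction: float = 0.2
    n_background_sites: int = 400  # fixed accessible loci without planted motifs
    n_late_sites: int = 200  # fixed loci inside S/G2 domains for replicating cells
    read_jitter_sd: float = 10.0
    replicating_fraction: float = 0.25
    replicating_extra_fraction: float = 0.3  # extra reads routed to S/G2 domains
    repeat_fraction: float = 0.0  # lowercase-masked fraction of the genome
    domain_block: int = 5_000  # replication-domain tile size (bp)
    n_replicates: int = 3
    n_decoy_tfs: int = 3
    nb_dispersion: float = 0.5
    n_genes: int = 2_000
    n_expr_cells: int = 500


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: 3 groups x 60 cells, 2 differential motifs.

    Groups A and B each have one motif highly active (the other low); group C
    has both low, so two axes of k-mer variation are planted.
    """
    m1 = MotifSpec("TF_A", "TGACTCAT", n_occurrences=500)
    m2 = MotifSpec("TF_B", "CACGTGAC", n_occurrences=500)
    return SimulationConfig(
        seed=seed,
        motifs=[m1, m2],
        groups=[
            CellGroup("groupA", 60, {"TF_A": 3.0, "TF_B": 0.1}, treatment="treated"),
            CellGroup("groupB", 60, {"TF_A": 0.1, "TF_B": 3.0}, treatment="untreated"),
            CellGroup("groupC", 60, {"TF_A": 0.1, "TF_B": 0.1}, treatment="untreated"),
        ],
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


def make_genome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random background genome with motif occurrences planted at known spots.

    Returns ``(genome, truth)``; ``truth`` has columns chrom/start/end/motif
    with one row per planted instance.  Instances are drawn from the motif's
    PWM on a random strand; optional lowercase repeat blocks are applied
    last (and may mask instances, as in real data).
    """
    rng = rng or np.random.default_rng(config.seed)
    per_chrom = config.genome_length // config.n_chroms
    chroms: dict[str, np.ndarray] = {}
    for name in _chrom_names(config):
        chroms[name] = _BASES[rng.integers(0, 4, size=per_chrom)].copy()
    truth_rows = []
    for motif in config.motifs:
        w = len(motif.consensus)
        pwm = motif.pwm()
        for _ in range(motif.n_occurrences):
            chrom = _chrom_names(config)[rng.integers(0, config.n_chroms)]
            pos = int(rng.integers(0, per_chrom - w))
            inst = "".join("ACGT"[rng.choice(4, p=pwm[i])] for i in range(w))
            if rng.random() < 0.5:
                inst = reverse_complement(inst)
            chroms[chrom][pos:pos + w] = np.frombuffer(inst.encode(), dtype=np.uint8)
            truth_rows.append({"chrom": chrom, "start": pos, "end": pos + w,
                               "motif": motif.name})
    genome = {c: bytes(a).decode() for c, a in chroms.items()}
    if config.repeat_fraction > 0:
        genome = _apply_repeats(genome, config, rng)
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return genome, truth


def _apply_repeats(
    genome: dict[str, str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    block = 500
    out = {}
    for chrom, seq in genome.items():
        n_blocks = max(1, int(len(seq) * config.repeat_fraction / block))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for _ in range(n_blocks):
            s = int(rng.integers(0, len(seq) - block))
            arr[s:s + block] |= 0x20  # lowercase
        out[chrom] = bytes(arr).decode()
    return out


# ---------------------------------------------------------------------------
# replication domains
# ---------------------------------------------------------------------------

def make_repli_domains(
    config: SimulationConfig,
    genome: Mapping[str, str],
) -> tuple[dict[str, ReplicationDomains], dict[str, list[tuple[GenomicInterval, float]]]]:
    """Tile the genome into six cycling phase domains plus signal tracks.

    Each chromosome is cut into ``domain_block`` tiles assigned to
    G1,S1,S2,S3,S4,G2 in rotation.  The per-phase percent-signal track puts
    80% on a phase's own tiles and 5% elsewhere, so calling domains at the
    default 25% cutoff reconstructs the tiling exactly.
    """
    signals: dict[str, list[tuple[GenomicInterval, float]]] = {p: [] for p in PHASES}
    for chrom in sorted(genome):
        length = len(genome[chrom])
        n_tiles = max(1, length // config.domain_block)
        for t in range(n_tiles):
            start = t * config.domain_block
            end = length if t == n_tiles - 1 else (t + 1) * config.domain_block
            own = PHASES[t % len(PHASES)]
            iv = GenomicInterval(chrom, start, end)
            for phase in PHASES:
                signals[phase].append((iv, 80.0 if phase == own else 5.0))
    domains = {p: call_domains(signals[p], p, cutoff=25.0) for p in PHASES}
    return domains, signals


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _domain_union(domains: ReplicationDomains) -> list[GenomicInterval]:
    return domains.intervals


def simulate_cells(
    config: SimulationConfig,
    genome: Mapping[str, str],
    truth: pd.DataFrame,
    domains: Mapping[str, ReplicationDomains] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CellReadSet], pd.DataFrame]:
    """Per-cell Tn5 integration sites driven by group TF-activity programs.

    For each cell, every planted occurrence of motif m opens with probability
    ``1 - exp(-a_m)``; non-background reads land near a uniformly chosen open
    site with Gaussian jitter.  Background reads sample a fixed universe of
    ``n_background_sites`` motif-free accessible loci shared by every cell
    (accessible chromatin is a discrete locus landscape, not uniform genome).
    Replicating cells (a ``replicating_fraction`` Bernoulli draw) redirect
    ``replicating_extra_fraction`` of their reads to a fixed set of loci
    inside S/G2 replication domains.  Returns ``(cells, labels)`` with labels
    columns cell_id/sample/replicate/treatment/replicating.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    chrom_names = sorted(genome)
    chrom_lens = {c: len(genome[c]) for c in chrom_names}
    sites = {
        m.name: truth[truth["motif"] == m.name][["chrom", "start", "end"]]
        .to_numpy(object)
        for m in config.motifs
    }
    # fixed background-locus universe, shared by all cells
    bg_sites: list[tuple[str, int]] = []
    for _ in range(config.n_background_sites):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        bg_sites.append((chrom, int(rng.integers(0, chrom_lens[chrom]))))
    late: list[GenomicInterval] = []
    if domains is not None:
        for phase in PHASES:
            if phase != "G1":
                late.extend(_domain_union(domains[phase]))
    late_sites: list[tuple[str, int]] = []
    if late:
        late_lens = np.array([len(iv) for iv in late], dtype=float)
        for _ in range(config.n_late_sites):
            iv = late[rng.choice(len(late), p=late_lens / late_lens.sum())]
            late_sites.append((iv.chrom, int(rng.integers(iv.start, iv.end))))
    cells: list[CellReadSet] = []
    label_rows = []
    for group in config.groups:
        for i in range(group.n_cells):
            cid = f"{group.name}_c{i:03d}"
            replicating = bool(rng.random() < config.replicating_fraction)
            open_sites: list[tuple[str, int, int]] = []
            for m in config.motifs:
                a = group.activities.get(m.name, 0.0)
                p_open = 1.0 - np.exp(-a)
                mask = rng.random(len(sites[m.name])) < p_open
                open_sites.extend(
                    (r[0], int(r[1]), int(r[2])) for r in sites[m.name][mask]
                )
            n_reads = int(rng.poisson(config.reads_per_cell))
            n_late = int(round(config.replicating_extra_fraction * n_reads)) \
                if (replicating and late_sites) else 0
            reads: list[tuple[str, int, str]] = []

            def jittered(chrom: str, center: int) -> tuple[str, int, str]:
                pos = center + int(round(rng.normal(0, config.read_jitter_sd)))
                pos = min(max(pos, 0), chrom_lens[chrom] - 1)
                return (chrom, pos, "+" if rng.random() < 0.5 else "-")

            for _ in range(n_reads - n_late):
                if open_sites and rng.random() >= config.background_read_fraction:
                    chrom, s, e = open_sites[rng.integers(0, len(open_sites))]
                    reads.append(jittered(chrom, (s + e) // 2))
                else:
                    chrom, center = bg_sites[rng.integers(0, len(bg_sites))]
                    reads.append(jittered(chrom, center))
            for _ in range(n_late):
                chrom, center = late_sites[rng.integers(0, len(late_sites))]
                reads.append(jittered(chrom, center))
            cells.append(CellReadSet(cell_id=cid, integration_sites=reads))
            label_rows.append(
                {
                    "cell_id": cid,
                    "sample": group.name,
                    "replicate": f"r{i % config.n_replicates + 1}",
                    "treatment": group.treatment,
                    "replicating": replicating,
                }
            )
    return cells, pd.DataFrame(label_rows)


# ---------------------------------------------------------------------------
# TF specificity files
# ---------------------------------------------------------------------------

def make_motif_files(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_experiments: int = 2,
    pbm_noise_sd: float = 0.5,
) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """TF specificity inputs: PWMs and PBM 8-mer Z tables, with decoys.

    PWMs are the planted motifs' generative matrices plus Dirichlet noise;
    decoy TFs get random-consensus PWMs.  Each TF's PBM table holds
    ``n_experiments`` pseudo-experiments: standardized best-alignment match
    scores of every canonical ungapped 8-mer against the consensus, plus
    Gaussian noise — so the consensus itself carries the top Z.
    Returns ``(pwms, pbm_tables)`` keyed by TF name.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    specs = list(config.motifs)
    for d in range(config.n_decoy_tfs):
        consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
        specs.append(MotifSpec(f"decoy{d + 1}", consensus))
    pwms: dict[str, np.ndarray] = {}
    pbm: dict[str, pd.DataFrame] = {}
    eightmers = _canonical_eightmers()
    for spec in specs:
        base = spec.pwm()
        noisy = np.vstack([rng.dirichlet(base[i] * 60 + 1) for i in range(len(base))])
        pwms[spec.name] = noisy
        match = _consensus_match_scores(eightmers, spec.consensus)
        z0 = (match - match.mean()) / match.std()
        cols = {}
        for e in range(n_experiments):
            cols[f"exp{e + 1}"] = 3.0 * z0 + rng.normal(0, pbm_noise_sd, size=len(z0))
        pbm[spec.name] = pd.DataFrame(cols, index=eightmers)
    return pwms, pbm


def _canonical_eightmers() -> list[str]:
    from .kmers import PatternUniverse

    u = PatternUniverse(8, gapped=False, canonicalize=True)
    return [p for p in u.pattern_strings if len(p) == 8]


def _consensus_match_scores(kmers: Sequence[str], consensus: str) -> np.ndarray:
    """Best full-alphabet match count of each k-mer vs a consensus word."""
    out = np.zeros(len(kmers))
    targets = [consensus, reverse_complement(consensus)]
    for i, kmer in enumerate(kmers):
        best = 0
        for t in targets:
            for off in range(-len(kmer) + 1, len(t)):
                m = sum(
                    1 for j in range(len(kmer))
                    if 0 <= off + j < len(t) and kmer[j] == t[off + j]
                )
                best = max(best, m)
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    high_noise_genes: int = 0,
) -> pd.DataFrame:
    """NB-distributed genes x cells count matrix (Var = mu + alpha mu^2).

    Gene means are log-uniform over [0.5, 50].  ``high_noise_genes`` extra
    genes get a 4x inflated variance (planted over-dispersed outliers).
    ``nb_dispersion = 0`` gives Poisson counts.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    n, c = config.n_genes, config.n_expr_cells
    means = np.exp(rng.uniform(np.log(0.5), np.log(50.0), size=n))
    alpha = np.full(n, config.nb_dispersion)
    names = [f"gene{i:04d}" for i in range(n)]
    if high_noise_genes:
        extra_mu = np.exp(rng.uniform(np.log(0.5), np.log(50.0), size=high_noise_genes))
        base_alpha = max(config.nb_dispersion, 0.05)
        means = np.concatenate([means, extra_mu])
        alpha = np.concatenate([alpha, np.full(high_noise_genes, 4.0 * base_alpha + 3.0 / extra_mu.mean())])
        names += [f"noisy{i:03d}" for i in range(high_noise_genes)]
    counts = np.empty((len(means), c), dtype=np.int64)
    for i, (mu, a) in enumerate(zip(means, alpha)):
        if a <= 0:
            counts[i] = rng.poisson(mu, size=c)
        else:
            r = 1.0 / a
            p = r / (r + mu)
            counts[i] = rng.negative_binomial(r, p, size=c)
    return pd.DataFrame(counts, index=names,
                        columns=[f"cell{j:04d}" for j in range(c)])


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit every pipeline input as files; deterministic under config.seed.

    Layout: genome.fa, reads.bed, labels.tsv, peaks-free; motifs/<tf>.txt
    (PWM), pbm/<tf>.tsv, repli/<phase>.bed + repli/signal_<phase>.tsv, and
    truth/ (planted motif occurrences, replicating flags live in labels).
    """
    out = Path(outdir)
    (out / "motifs").mkdir(parents=True, exist_ok=True)
    (out / "pbm").mkdir(exist_ok=True)
    (out / "repli").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    genome, truth = make_genome(config)
    domains, signals = make_repli_domains(config, genome)
    cells, labels = simulate_cells(config, genome, truth, domains)
    pwms, pbm = make_motif_files(config)

    paths: dict[str, Path] = {}
    fa = out / "genome.fa"
    with open(fa, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["genome"] = fa

    bed = out / "reads.bed"
    with open(bed, "w") as fh:
        for cell in cells:
            for chrom, pos, strand in cell.integration_sites:
                start, end = (pos, pos + 1) if strand == "+" else (pos, pos + 1)
                fh.write(f"{chrom}\t{start}\t{end}\t{cell.cell_id}\t0\t{strand}\n")
    paths["reads"] = bed

    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    paths["labels"] = out / "labels.tsv"
    truth.to_csv(out / "truth" / "motif_occurrences.bed", sep="\t",
                 index=False, header=False)

    from .enrich import write_cisbp_pwm

    for tf, pwm in pwms.items():
        write_cisbp_pwm(pwm, out / "motifs" / f"{tf}.txt")
    for tf, table in pbm.items():
        table.to_csv(out / "pbm" / f"{tf}.tsv", sep="\t", index_label="kmer")
    for phase, dom in domains.items():
        with open(out / "repli" / f"{phase}.bed", "w") as fh:
            for iv in dom.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        with open(out / "repli" / f"signal_{phase}.tsv", "w") as fh:
            for iv, s in signals[phase]:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s}\n")
    paths["outdir"] = out
    return paths
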
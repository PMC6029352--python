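"""End-to-end orchestration: reads -> k-mer matrix -> PCA -> enrichment -> QC.

``RunConfig`` bundles every tunable with its default; ``run_pipeline``
executes the stages in order (regions, k-mers, factorize, enrich, evaluate,
optionally cell cycle) against input files on disk and writes per-stage
outputs plus a manifest recording parameters, seeds and input checksums.
Each stage is also importable on its own; the pipeline keeps no hidden
state between stages beyond the returned objects.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcycle as cc
from . import enrich as en
from . import evaluate as ev
from . import factorize as fz
from . import io_regions as ior
from . import kmers as km

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    The defaults encode the method's published operating point: 50 bp
    windows, QC at 3162 (10^3.5) distinct loci, gapped k-mers to span 8,
    100-permutation parallel analysis at alpha 0.05, 20-NN grouping, 2001 x
    80% bootstrap, minHG prefixes of 3000 (PBM) / 15000 (PWM), cognate Z
    cutoffs 2 (PWM) / 3 (PBM), significance cutoffs 1e-112 (PWM) / 1e-2
    (PBM), redundancy pruning at Pearson R 0.5, replication-domain signal
    cutoff 25%, batch-PC alpha 0.1.
    """

    # inputs
    reads: str = ""
    genome: str = ""
    labels: str = ""
    motifs_dir: str = ""
    pbm_dir: str = ""
    repli_dir: str = ""
    peaks: str = ""
    outdir: str = "kmerfact_run"
    # parameters
    flank: int = 50
    min_loci: int = 3162
    max_span: int = 8
    gapped: bool = True
    canonicalize: bool = True
    exclude_masked: bool = False
    pa_permutations: int = 100
    pa_alpha: float = 0.05
    knn_k: int = 20
    boot_n: int = 2001
    boot_frac: float = 0.8
    pbm_prefix: int = 3000
    pwm_prefix: int = 15000
    z_pwm: float = 2.0
    z_pbm: float = 3.0
    p_pwm: float = 1e-112
    p_pbm: float = 1e-2
    prune_r: float = 0.5
    domain_cutoff: float = 25.0
    batch_alpha: float = 0.1
    seed: int = 0
    write_matrix: bool = False
    run_tsne: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def validate(self) -> None:
        for name in ("reads", "genome"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")
        for name in ("labels", "motifs_dir", "pbm_dir", "repli_dir", "peaks"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")


@dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    config: RunConfig
    qc: pd.DataFrame
    matrix: km.CellKmerMatrix
    model: fz.FactorModel
    labels: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    retained: list = field(default_factory=list)
    evaluation: dict = field(default_factory=dict)
    cellcycle: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage; any stage failure aborts with a stage-tagged message."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "inputs": {
            k: _checksum(getattr(config, k))
            for k in ("reads", "genome", "labels")
            if getattr(config, k) and Path(getattr(config, k)).is_file()
        },
        "stages": {},
    }

    # -- stage: regions ----------------------------------------------------
    try:
        import pyfaidx

        genome = pyfaidx.Fasta(config.genome, sequence_always_upper=False)
        cells_reads = ior.read_bed_reads(config.reads) if str(config.reads).endswith(".bed") \
            else ior.read_sam_reads(config.reads)
        cells_reads = dict(sorted(cells_reads.items()))
        windows: dict[str, list[ior.GenomicInterval]] = {}
        for cid, reads in cells_reads.items():
            windows[cid] = ior.tn5_windows(reads, flank=config.flank, genome=genome)
        kept, excluded = ior.qc_filter_cells(list(cells_reads.values()), config.min_loci)
        qc = ior.qc_report(list(cells_reads.values()), config.min_loci)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        seqs = [
            ior.extract_sequences(windows[c.cell_id], genome,
                                  exclude_masked=config.exclude_masked,
                                  cell_id=c.cell_id)
            for c in kept
        ]
        manifest["stages"]["regions"] = {
            "n_cells_in": len(cells_reads), "n_cells_kept": len(kept),
            "excluded": excluded, "qc": "qc.tsv",
        }
    except Exception as e:
        raise RuntimeError(f"[regions] {e}") from e

    # -- stage: kmers ------------------------------------------------------
    try:
        universe = km.PatternUniverse(config.max_span, gapped=config.gapped,
                                      canonicalize=config.canonicalize)
        matrix = km.build_matrix(seqs, universe)
        if config.write_matrix:
            km.write_matrix_tsv(matrix, out / "kmer_matrix.tsv")
        manifest["stages"]["kmers"] = {
            "n_patterns": len(universe), "n_cells": len(matrix.cells),
        }
    except Exception as e:
        raise RuntimeError(f"[kmers] {e}") from e

    # -- stage: factorize --------------------------------------------------
    try:
        model = fz.fit_factor_model(matrix)
        scaled, _, _, _ = fz.standardize(matrix)
        model.n_significant = fz.n_significant_pcs(
            scaled, n_permutations=config.pa_permutations,
            alpha=config.pa_alpha, seed=config.seed,
        )
        n_sig = model.n_significant
        proj = pd.DataFrame(
            model.projections, index=model.cells,
            columns=[f"PC{i + 1}" for i in range(model.n_components)],
        )
        proj.to_csv(out / "projections.tsv", sep="\t", index_label="cell_id")
        pd.DataFrame({"explained_variance": model.explained_variance}) \
            .to_csv(out / "explained_variance.tsv", sep="\t", index_label="component")
        if n_sig:
            pd.DataFrame(
                model.loadings[:, :n_sig], index=model.patterns,
                columns=[f"PC{i + 1}" for i in range(n_sig)],
            ).to_csv(out / "loadings_significant.tsv", sep="\t", index_label="pattern")
        gc_r = fz.gc_correlation(model)
        embedding = None
        if config.run_tsne and n_sig >= 2:
            embedding = fz.embed_2d(model.projections[:, :n_sig], seed=config.seed)
            pd.DataFrame(embedding, index=model.cells, columns=["x", "y"]) \
                .to_csv(out / "embedding.tsv", sep="\t", index_label="cell_id")
        manifest["stages"]["factorize"] = {
            "n_significant": n_sig,
            "gc_correlation_pc1": float(gc_r[0]) if len(gc_r) else None,
        }
    except Exception as e:
        raise RuntimeError(f"[factorize] {e}") from e

    result = PipelineResult(config=config, qc=qc, matrix=matrix, model=model,
                            manifest=manifest)

    # -- stage: enrich -----------------------------------------------------
    if config.motifs_dir or config.pbm_dir:
        try:
            result.enrichment, result.retained = _enrich_stage(config, model, out)
            manifest["stages"]["enrich"] = {
                "n_significant_records": int(result.enrichment["significant"].sum()),
                "n_retained": len(result.retained),
            }
        except Exception as e:
            raise RuntimeError(f"[enrich] {e}") from e

    # -- stage: evaluate ---------------------------------------------------
    if config.labels:
        try:
            labels = pd.read_csv(config.labels, sep="\t").set_index("cell_id")
            labels = labels.loc[model.cells]
            result.labels = labels
            n_sig = model.n_significant or model.n_components
            space = model.projections[:, :max(n_sig, 1)]
            counts = ev.knn_same_sample(space, labels["sample"],
                                        k=min(config.knn_k, len(model.cells) - 1))
            auroc = ev.distance_auroc(space, labels["sample"])
            evaluation = {
                "knn_mean_same_sample": float(counts.mean()),
                "knn_purity": float(counts.mean() / min(config.knn_k, len(model.cells) - 1)),
                "distance_auroc": auroc,
            }
            if "treatment" in labels and labels["treatment"].nunique() == 2:
                per_pc = [
                    ev.pc_label_separation(model.projections[:, i], labels["treatment"])
                    for i in range(max(n_sig, 1))
                ]
                best = int(np.argmax([abs(a - 0.5) for a, _ in per_pc]))
                evaluation["treatment_best_pc"] = best + 1
                evaluation["treatment_best_auroc"] = per_pc[best][0]
                evaluation["treatment_best_p"] = per_pc[best][1]
            if "replicate" in labels and labels["replicate"].nunique() >= 2:
                flagged = ev.flag_batch_pcs(space, labels["replicate"],
                                            alpha=config.batch_alpha)
                evaluation["batch_pcs"] = {int(k) + 1: v for k, v in flagged.items()}
            result.evaluation = evaluation
            with open(out / "evaluation.json", "w") as fh:
                json.dump(evaluation, fh, indent=2)
            manifest["stages"]["evaluate"] = evaluation
        except Exception as e:
            raise RuntimeError(f"[evaluate] {e}") from e

    # -- stage: cellcycle --------------------------------------------------
    if config.repli_dir:
        try:
            domains = _load_domains(Path(config.repli_dir), config.domain_cutoff)
            table = cc.phase_ratio_table(kept, domains)
            table.to_csv(out / "cellcycle.tsv", sep="\t", index=False)
            result.cellcycle = table
            manifest["stages"]["cellcycle"] = {"n_cells": len(table)}
        except Exception as e:
            raise RuntimeError(f"[cellcycle] {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result


def _enrich_stage(config: RunConfig, model: fz.FactorModel, out: Path):
    n_sig = model.n_significant or 0
    pcs = list(range(max(n_sig, 1)))
    loadings = pd.DataFrame(model.loadings, index=model.patterns)
    cognate_sets: list[en.MotifCognateSet] = []
    score_vectors: dict[str, pd.Series] = {}
    if config.motifs_dir:
        for path in sorted(Path(config.motifs_dir).glob("*.txt")):
            pwm = en.read_cisbp_pwm(path)
            cset = en.pwm_cognate_set(pwm, model.patterns, tf_name=path.stem,
                                      z_threshold=config.z_pwm)
            cognate_sets.append(cset)
            score_vectors[path.stem] = cset.score_series()
    if config.pbm_dir:
        eight = [p for p, s in zip(model.patterns, model.pattern_spans)
                 if s == 8 and "N" not in p]
        for path in sorted(Path(config.pbm_dir).glob("*.tsv")):
            table = pd.read_csv(path, sep="\t", index_col="kmer")
            cset = en.pbm_cognate_set(
                [table[c] for c in table.columns],
                tf_name=path.stem, z_threshold=config.z_pbm,
            )
            # restrict to 8-mers that survived standardization
            eight_set = set(eight)
            keep = np.array([p in eight_set for p in cset.patterns])
            cset = en.MotifCognateSet(
                cset.tf_name, "PBM",
                [p for p, k in zip(cset.patterns, keep) if k],
                cset.scores[keep], cset.z[keep], cset.z_threshold,
            )
            if len(cset.patterns) < 10:
                logger.warning(
                    "skipping PBM motif %s: feature space has no ungapped 8-mers "
                    "(max_span < 8?)", path.stem,
                )
                continue
            cognate_sets.append(cset)
            score_vectors.setdefault(path.stem, cset.score_series())
    records = en.test_pc_enrichment(
        cognate_sets, loadings, pcs,
        max_prefix_pwm=config.pwm_prefix, max_prefix_pbm=config.pbm_prefix,
    )
    significant = en.correct_and_call(records, p_pwm=config.p_pwm, p_pbm=config.p_pbm)
    retained = en.prune_redundant(significant, score_vectors, r_threshold=config.prune_r)
    frame = en.records_to_frame(records)
    frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return frame, retained


def _load_domains(repli_dir: Path, cutoff: float) -> dict[str, cc.ReplicationDomains]:
    domains: dict[str, cc.ReplicationDomains] = {}
    for phase in cc.PHASES:
        sig_path = repli_dir / f"signal_{phase}.tsv"
        bed_path = repli_dir / f"{phase}.bed"
        if sig_path.exists():
            signal = []
            with open(sig_path) as fh:
                for line in fh:
                    c, s, e, v = line.split("\t")
                    signal.append((ior.GenomicInterval(c, int(s), int(e)), float(v)))
            domains[phase] = cc.call_domains(signal, phase, cutoff=cutoff)
        elif bed_path.exists():
            domains[phase] = cc.ReplicationDomains(
                phase, ior.read_bed_intervals(bed_path)
            )
        else:
            raise FileNotFoundError(f"no domains or signal for phase {phase}")
    return domains
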
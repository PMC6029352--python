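"""TF cognate k-mer sets and minimum-hypergeometric enrichment on PC loadings.

A TF's specificity comes either from a position weight matrix (PWM) or from
protein-binding-microarray (PBM) per-8-mer Z-scores.  PWM scores for gapped
k-mers are the maximum log-odds over every offset and both orientations,
robust-standardized (median/MAD) with Z > 2 called cognate; PBM Z-scores are
combined across experiments by Stouffer's method with Z > 3 called cognate.

For each principal component the k-mers are ranked by loading and the
minimum hypergeometric (minHG) statistic scans every prefix of the ranking
(up to a cap), taking the smallest hypergeometric tail probability for
cognate over-representation; both ends of the ranking are tested (enriched
among the most positive loadings, or among the most negative = depleted).
Bonferroni correction multiplies by the number of prefixes scanned, treating
the (dependent) prefix tests as if independent — deliberately conservative.
P-values are carried in natural-log space because realistic minima underflow
double precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import reverse_complement

__all__ = [
    "MotifModel",
    "MotifCognateSet",
    "EnrichmentRecord",
    "read_cisbp_pwm",
    "write_cisbp_pwm",
    "pwm_pattern_score",
    "pwm_score_patterns",
    "pwm_cognate_set",
    "pbm_cognate_set",
    "min_hypergeometric",
    "test_pc_enrichment",
    "correct_and_call",
    "prune_redundant",
    "pair_interaction_enrichment",
    "records_to_frame",
]

_LN10 = math.log(10.0)
_DIGITS5 = {c: i for i, c in enumerate("ACGNT")}


@dataclass
class MotifModel:
    """One TF's binding specificity: a PWM or a set of PBM 8-mer Z tables."""

    tf_name: str
    source: str  # "PWM" | "PBM"
    pwm: np.ndarray | None = None  # (length, 4) probabilities, columns A,C,G,T
    pbm_z: pd.DataFrame | None = None  # index 8-mer, one column per experiment

    def __post_init__(self) -> None:
        if self.source not in {"PWM", "PBM"}:
            raise ValueError(f"unknown motif source: {self.source!r}")
        if self.source == "PWM":
            if self.pwm is None:
                raise ValueError("PWM source requires a pwm")
            rows = np.asarray(self.pwm).sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-6):
                raise ValueError(f"PWM rows must sum to 1 (got {rows})")
        elif self.pbm_z is None:
            raise ValueError("PBM source requires pbm_z")


@dataclass
class MotifCognateSet:
    """Per-pattern scores/Z for one TF and the cognate (Z > threshold) flags."""

    tf_name: str
    source: str
    patterns: list[str]
    scores: np.ndarray
    z: np.ndarray
    z_threshold: float

    @property
    def cognate(self) -> np.ndarray:
        return self.z > self.z_threshold

    def score_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.patterns, name=self.tf_name)


@dataclass
class EnrichmentRecord:
    """One (motif, PC, tail) minimum-hypergeometric test."""

    tf_name: str
    pc_index: int
    tail: str  # "top" | "bottom"
    source: str
    log10_min_hg_p: float
    log10_corrected_p: float
    best_prefix_N: int
    n_prefixes: int
    significant: bool = False
    retained_after_pruning: bool = False

    @property
    def min_hg_p(self) -> float:
        return 10.0 ** self.log10_min_hg_p

    @property
    def corrected_p(self) -> float:
        return min(1.0, 10.0 ** self.log10_corrected_p)

    @property
    def enriched_or_depleted(self) -> str:
        return "enriched" if self.tail == "top" else "depleted"


# ---------------------------------------------------------------------------
# PWM I/O and scoring
# ---------------------------------------------------------------------------

def read_cisbp_pwm(path: str | Path) -> np.ndarray:
    """Read a CIS-BP-style PWM text file (Pos / A C G T columns)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in {"A", "C", "G", "T"}]
    if len(cols) != 4:
        raise ValueError(f"{path}: expected A/C/G/T columns, got {list(df.columns)}")
    pwm = df[sorted(cols, key=lambda c: "ACGT".index(c.upper()))].to_numpy(float)
    rows = pwm.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-3):
        raise ValueError(f"{path}: PWM rows do not sum to 1")
    return pwm / rows[:, None]


def write_cisbp_pwm(pwm: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(pwm), columns=["A", "C", "G", "T"])
    df.insert(0, "Pos", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


def _log_odds(pwm: np.ndarray, background: float, pseudocount: float) -> np.ndarray:
    """(length, 5) log-odds with pseudocounted probabilities; the N column is 0."""
    pwm = np.asarray(pwm, dtype=float)
    if (pwm < 0).any():
        raise ValueError("PWM probabilities must be non-negative")
    probs = (pwm + pseudocount) / (pwm + pseudocount).sum(axis=1, keepdims=True)
    if (probs <= 0).any():
        raise ValueError("zero probabilities remain; increase pseudocount")
    lo = np.log(probs / background)
    out = np.zeros((len(pwm), 5))
    out[:, [0, 1, 2, 4]] = lo  # digit order A,C,G,N,T with N contributing 0
    return out


def _encode_patterns(patterns: Sequence[str]) -> np.ndarray:
    k = len(patterns[0])
    arr = np.empty((len(patterns), k), dtype=np.int8)
    for i, p in enumerate(patterns):
        if len(p) != k:
            raise ValueError("patterns in one batch must share a span")
        arr[i] = [_DIGITS5[c] for c in p]
    return arr


def _max_offset_scores(lo: np.ndarray, digits: np.ndarray) -> np.ndarray:
    """Max over offsets of the summed aligned log-odds (overhangs score 0)."""
    L, k = lo.shape[0], digits.shape[1]
    best = np.full(len(digits), -np.inf)
    for offset in range(-(k - 1), L):
        j0, j1 = max(0, -offset), min(k, L - offset)
        if j1 <= j0:
            continue
        s = np.zeros(len(digits))
        for j in range(j0, j1):
            s += lo[offset + j, digits[:, j]]
        np.maximum(best, s, out=best)
    return best


def pwm_score_patterns(
    pwm: np.ndarray,
    patterns: Sequence[str],
    background: float = 0.25,
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Maximum log-odds of each gapped pattern against a PWM.

    The maximum is over every offset (partial overhangs allowed, overhanging
    and N positions contribute 0) and both orientations, so a pattern and its
    reverse complement always score identically.
    """
    lo = _log_odds(pwm, background, pseudocount)
    out = np.empty(len(patterns))
    by_span: dict[int, list[int]] = {}
    for i, p in enumerate(patterns):
        by_span.setdefault(len(p), []).append(i)
    for span, idx in by_span.items():
        pats = [patterns[i] for i in idx]
        fwd = _max_offset_scores(lo, _encode_patterns(pats))
        rc = _max_offset_scores(lo, _encode_patterns([reverse_complement(p) for p in pats]))
        out[idx] = np.maximum(fwd, rc)
    return out


def pwm_pattern_score(
    pwm: np.ndarray,
    pattern: str,
    background: float = 0.25,
    pseudocount: float = 0.01,
) -> float:
    """Maximum log-odds score of a single gapped pattern (see batch variant)."""
    return float(pwm_score_patterns(pwm, [pattern], background, pseudocount)[0])


def pwm_cognate_set(
    pwm: np.ndarray,
    patterns: Sequence[str],
    tf_name: str = "",
    z_threshold: float = 2.0,
    background: float = 0.25,
    pseudocount: float = 0.01,
    scores: np.ndarray | None = None,
) -> MotifCognateSet:
    """Robust-Z the PWM scores over the pattern universe; Z > 2 is cognate.

    Z = (score - median) / MAD; a zero MAD (degenerate score distribution)
    raises.  Precomputed ``scores`` may be supplied to skip rescoring.
    """
    if len(patterns) < 100:
        raise ValueError("need >= 100 patterns for a stable median/MAD")
    if scores is None:
        scores = pwm_score_patterns(pwm, patterns, background, pseudocount)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    if mad == 0:
        raise ValueError(f"{tf_name}: MAD of PWM scores is zero")
    z = (scores - med) / mad
    return MotifCognateSet(tf_name, "PWM", list(patterns), np.asarray(scores), z, z_threshold)


def pbm_cognate_set(
    experiments: Sequence[Mapping[str, float] | pd.Series],
    tf_name: str = "",
    z_threshold: float = 3.0,
) -> MotifCognateSet:
    """Combine PBM 8-mer Z-scores across experiments; combined Z > 3 is cognate.

    Stouffer's method: Z = sum(Z_i) / sqrt(m).  8-mers are collapsed to the
    canonical orientation (max over an 8-mer and its reverse complement);
    experiments must cover the same 8-mer universe.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    series = []
    for exp in experiments:
        s = pd.Series(exp, dtype=float)
        canon = s.index.map(lambda k: min(k, reverse_complement(k)))
        s = s.groupby(canon).max()
        series.append(s)
    universe = series[0].index
    for s in series[1:]:
        if not s.index.equals(universe):
            raise ValueError("PBM experiments cover different 8-mer universes")
    zs = np.vstack([s.to_numpy() for s in series])
    combined = zs.sum(axis=0) / math.sqrt(len(series))
    return MotifCognateSet(
        tf_name, "PBM", list(universe), combined.copy(), combined, z_threshold
    )


# ---------------------------------------------------------------------------
# minimum hypergeometric test
# ---------------------------------------------------------------------------

def min_hypergeometric(
    cognate_in_rank_order: np.ndarray,
    max_prefix: int,
) -> tuple[float, int]:
    """Minimum upper-tail hypergeometric probability over ranking prefixes.

    ``cognate_in_rank_order`` is the boolean cognate flag of each pattern in
    ranked order.  For every prefix length N up to ``max_prefix`` the
    probability of drawing at least the observed number of cognates in N
    draws (population = full list, successes = all cognates) is computed;
    the minimum over N is returned as ``(log10_p, best_N)``.  With zero
    cognates the result is ``(0.0, 0)`` (p = 1).
    """
    flags = np.asarray(cognate_in_rank_order, dtype=bool)
    M = flags.size
    if not 1 <= max_prefix <= M:
        raise ValueError("max_prefix must be in 1..len(list)")
    K = int(flags.sum())
    if K == 0:
        return 0.0, 0
    N = np.arange(1, max_prefix + 1)
    x = np.cumsum(flags[:max_prefix])
    log_p = stats.hypergeom.logsf(x - 1, M, K, N) / _LN10
    best = int(np.argmin(log_p))
    return float(log_p[best]), int(N[best])


def test_pc_enrichment(
    cognate_sets: Sequence[MotifCognateSet],
    loadings: Mapping[str, np.ndarray] | pd.DataFrame,
    pc_indices: Sequence[int],
    max_prefix_pwm: int = 15_000,
    max_prefix_pbm: int = 3_000,
) -> list[EnrichmentRecord]:
    """minHG-test every (motif, PC, tail) combination.

    ``loadings`` maps pattern -> per-PC loading vector (a DataFrame indexed
    by pattern).  PWM motifs are tested on the full gapped ranking; PBM
    motifs only on the ungapped 8-mer ranking.  ``tail='top'`` ranks by
    decreasing loading (cognates enriched among the most positive weights),
    ``'bottom'`` by increasing loading (depleted).
    """
    L = loadings if isinstance(loadings, pd.DataFrame) else pd.DataFrame(loadings).T
    records: list[EnrichmentRecord] = []
    for cset in cognate_sets:
        sub = L.reindex(cset.patterns).dropna()
        if len(sub) < len(cset.patterns):
            missing = len(cset.patterns) - len(sub)
            raise ValueError(f"{cset.tf_name}: {missing} patterns lack loadings")
        flags = pd.Series(cset.cognate, index=cset.patterns).loc[sub.index].to_numpy()
        cap = max_prefix_pwm if cset.source == "PWM" else max_prefix_pbm
        cap = min(cap, len(sub))
        for pc in pc_indices:
            order = np.argsort(-sub.iloc[:, pc].to_numpy(), kind="stable")
            for tail, ordered in (("top", order), ("bottom", order[::-1])):
                log10p, best_n = min_hypergeometric(flags[ordered], cap)
                records.append(
                    EnrichmentRecord(
                        tf_name=cset.tf_name,
                        pc_index=pc,
                        tail=tail,
                        source=cset.source,
                        log10_min_hg_p=log10p,
                        log10_corrected_p=log10p + math.log10(cap),
                        best_prefix_N=best_n,
                        n_prefixes=cap,
                    )
                )
    return records


def correct_and_call(
    records: Iterable[EnrichmentRecord],
    p_pwm: float = 1e-112,
    p_pbm: float = 1e-2,
) -> list[EnrichmentRecord]:
    """Bonferroni-correct (x number of prefixes) and flag significant records.

    Thresholds are source-specific: PWM rankings include the huge gapped
    universe with heavily shared sub-motifs and need a far more stringent
    cutoff than PBM 8-mer rankings.  Returns the significant records.
    """
    out = []
    for rec in records:
        thr = p_pwm if rec.source == "PWM" else p_pbm
        rec.significant = rec.log10_corrected_p < math.log10(thr)
        if rec.significant:
            out.append(rec)
    return out


def prune_redundant(
    significant: Sequence[EnrichmentRecord],
    score_vectors: Mapping[str, pd.Series],
    r_threshold: float = 0.5,
) -> list[EnrichmentRecord]:
    """Greedy redundancy pruning of significant motifs within each (PC, tail).

    Motifs are visited in order of increasing corrected p (ties broken by TF
    name); a motif is retained unless its per-pattern score vector has
    Pearson R > ``r_threshold`` with any already-retained motif of the same
    (PC, tail) group.  Cross-source pairs are compared on the intersection
    of their pattern universes (ungapped 8-mers).
    """
    retained: list[EnrichmentRecord] = []
    groups: dict[tuple[int, str], list[EnrichmentRecord]] = {}
    for rec in significant:
        groups.setdefault((rec.pc_index, rec.tail), []).append(rec)
    for key in sorted(groups):
        kept: list[EnrichmentRecord] = []
        for rec in sorted(groups[key], key=lambda r: (r.log10_corrected_p, r.tf_name)):
            redundant = False
            for other in kept:
                r = _score_correlation(
                    score_vectors[rec.tf_name], score_vectors[other.tf_name]
                )
                if r is not None and r > r_threshold:
                    redundant = True
                    break
            rec.retained_after_pruning = not redundant
            if not redundant:
                kept.append(rec)
        retained.extend(kept)
    return retained


def _score_correlation(a: pd.Series, b: pd.Series) -> float | None:
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return None
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def pair_interaction_enrichment(
    co_enriched: Mapping[tuple[int, str], set[str]] | Sequence[set[str]],
    interaction_pairs: Iterable[tuple[str, str]],
    tf_universe: set[str],
) -> tuple[float, float]:
    """Are co-enriched TF pairs over-represented among known interactions?

    Population: all unordered pairs over ``tf_universe``; successes: the
    interacting pairs; draws: distinct TF pairs co-enriched in the same PC
    and tail.  Returns ``(fold_enrichment, upper_tail_hypergeometric_p)``;
    with no co-enriched pairs the fold is NaN and p = 1.
    """
    if not tf_universe:
        raise ValueError("empty TF universe")
    interactions = {
        frozenset(p) for p in interaction_pairs
        if len(set(p)) == 2 and set(p) <= tf_universe
    }
    groups = co_enriched.values() if isinstance(co_enriched, Mapping) else co_enriched
    drawn: set[frozenset] = set()
    for tfs in groups:
        for a, b in itertools.combinations(sorted(set(tfs) & tf_universe), 2):
            drawn.add(frozenset((a, b)))
    n_u = len(tf_universe)
    population = n_u * (n_u - 1) // 2
    n_succ = len(interactions)
    n_draw = len(drawn)
    n_obs = len(drawn & interactions)
    if n_draw == 0:
        return float("nan"), 1.0
    expected = n_draw * n_succ / population if population else 0.0
    fold = n_obs / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(n_obs - 1, population, n_succ, n_draw))
    return fold, p


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records for TSV output."""
    return pd.DataFrame(
        {
            "tf": [r.tf_name for r in records],
            "pc": [r.pc_index for r in records],
            "tail": [r.tail for r in records],
            "source": [r.source for r in records],
            "log10_p": [r.log10_min_hg_p for r in records],
            "log10_corrected_p": [r.log10_corrected_p for r in records],
            "best_N": [r.best_prefix_N for r in records],
            "significant": [r.significant for r in records],
            "retained": [r.retained_after_pruning for r in records],
        }
    )
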
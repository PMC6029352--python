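"""Grouping-quality metrics in significant-PC space.

Cells with known labels (biological sample, treatment, replicate) are used
to score how well an embedding groups like with like: the number of
same-sample cells among each cell's k nearest neighbors (k = 20, Euclidean),
and a pooled AUROC asking whether pairwise distance separates same-sample
pairs (positives) from different-sample pairs (negatives).  Two analysis
variants are compared by bootstrapping the AUROC over 80% cell subsamples.
Per-PC diagnostics identify components that separate a binary label
(treated vs untreated; ranked by |AUROC - 0.5|) and components that track
replicate identity (batch effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score

__all__ = [
    "knn_same_sample",
    "distance_auroc",
    "bootstrap_compare",
    "pc_label_separation",
    "flag_batch_pcs",
]


def _as_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    if any(l is None for l in arr):
        raise ValueError("label missing for a cell")
    return arr


def knn_same_sample(
    projections: np.ndarray,
    labels: Sequence,
    k: int = 20,
) -> np.ndarray:
    """Count same-sample cells among each cell's k nearest neighbors.

    Euclidean distance in the given (significant-PC) space; the cell itself
    is excluded; distance ties are broken by cell index for reproducibility.
    """
    X = np.asarray(projections, dtype=float)
    lab = _as_labels(labels)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < n_cells")
    if lab.shape[0] != n:
        raise ValueError("label missing for a cell")
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    counts = np.empty(n, dtype=int)
    for i in range(n):
        nn = np.argsort(D[i], kind="stable")[:k]
        counts[i] = int((lab[nn] == lab[i]).sum())
    return counts


def _pair_data(projections: np.ndarray, labels: Sequence):
    X = np.asarray(projections, dtype=float)
    lab = _as_labels(labels)
    if len(set(lab.tolist())) < 2:
        raise ValueError("need at least 2 samples for a distance AUROC")
    d = pdist(X)
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    same = (lab[iu[0]] == lab[iu[1]]).astype(int)
    return d, same


def distance_auroc(projections: np.ndarray, labels: Sequence) -> float:
    """AUROC of -distance for same-sample (positive) vs different-sample pairs.

    Pooled over all unordered cell pairs; midranks handle ties.  1.0 means
    every within-sample distance is smaller than every between-sample one.
    """
    d, same = _pair_data(projections, labels)
    return float(roc_auc_score(same, -d))


def bootstrap_compare(
    projections_a: np.ndarray,
    projections_b: np.ndarray,
    labels: Sequence,
    n_boot: int = 2001,
    frac: float = 0.8,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed bootstrap p for AUROC(variant A) vs AUROC(variant B).

    Each of ``n_boot`` rounds subsamples ``frac`` of the cells without
    replacement and recomputes both AUROCs; ties contribute half a win to
    each side.  The p-value is floored at the bootstrap resolution 2/n_boot
    (a unanimous winner cannot attest to p = 0).  Returns
    ``(p, fraction of rounds where A > B)``.
    """
    A = np.asarray(projections_a, dtype=float)
    B = np.asarray(projections_b, dtype=float)
    lab = _as_labels(labels)
    if A.shape[0] != B.shape[0] or A.shape[0] != lab.shape[0]:
        raise ValueError("variants must cover the same cells")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    m = max(3, int(round(frac * n)))
    wins = 0.0
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        sub = lab[idx]
        if len(set(sub.tolist())) < 2:
            wins += 0.5
            continue
        auc_a = distance_auroc(A[idx], sub)
        auc_b = distance_auroc(B[idx], sub)
        wins += 1.0 if auc_a > auc_b else (0.5 if auc_a == auc_b else 0.0)
    frac_a = wins / n_boot
    p = min(1.0, max(2.0 * min(frac_a, 1.0 - frac_a), 2.0 / n_boot))
    return p, frac_a


def pc_label_separation(
    pc_projection: np.ndarray,
    binary_labels: Sequence,
) -> tuple[float, float]:
    """How well one PC's projections split cells by a binary label.

    Returns ``(auroc, two_sided_rank_sum_p)``; PCs are ranked by
    ``|auroc - 0.5|`` (both enrichment and depletion of the label count).
    The AUROC equals the Mann-Whitney U statistic scaled by n1*n2.
    """
    x = np.asarray(pc_projection, dtype=float)
    lab = _as_labels(binary_labels)
    classes = sorted(set(lab.tolist()))
    if len(classes) != 2:
        raise ValueError("labels must be binary with both classes present")
    y = (lab == classes[1]).astype(int)
    auroc = float(roc_auc_score(y, x))
    p = float(stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").pvalue)
    return auroc, p


def flag_batch_pcs(
    projections: np.ndarray,
    replicate_labels: Sequence,
    alpha: float = 0.1,
    flag_pc1: bool = True,
) -> dict[int, str]:
    """Flag PCs that separate any replicate from the rest (batch effects).

    For every PC x replicate a two-sided rank-sum test of that replicate's
    projections versus all others is Bonferroni-corrected over all
    PC x replicate tests; a PC is flagged when any corrected p < ``alpha``.
    PC1 is additionally flagged (reason "GC") because it usually tracks G+C
    content; disable with ``flag_pc1=False``.  Returns {pc_index: reason}.
    """
    X = np.asarray(projections, dtype=float)
    lab = _as_labels(replicate_labels)
    reps = sorted(set(lab.tolist()))
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    n_pcs = X.shape[1]
    n_tests = n_pcs * len(reps)
    flagged: dict[int, str] = {}
    if flag_pc1 and n_pcs > 0:
        flagged[0] = "GC"
    for pc in range(n_pcs):
        for rep in reps:
            mask = lab == rep
            p = stats.mannwhitneyu(
                X[mask, pc], X[~mask, pc], alternative="two-sided"
            ).pvalue
            if min(1.0, p * n_tests) < alpha:
                reason = flagged.get(pc)
                flagged[pc] = f"{reason},batch" if reason else "batch"
                break
    return flagged
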
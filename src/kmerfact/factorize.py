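"""Standardization, PCA and permutation parallel analysis of the k-mer matrix.

Each k-mer's frequency row is scaled to mean 0 / SD 1 across cells before
decomposition, so every feature contributes on an equal footing.  Principal
components are then axes of co-varying k-mer frequencies: the loadings are
the weights by which scaled frequencies are multiplied to yield each cell's
projection.  The number of components that carry signal is estimated by
permutation parallel analysis: each feature row is permuted independently
across cells, destroying feature covariance while preserving marginals, and
an observed component is significant while its explained variance exceeds
the (1 - alpha) quantile of the permuted explained variance at the same rank.

Note that k-mer frequencies are strongly tied to G+C content, so the first
PC often tracks G+C; per-component G+C correlation is reported rather than
auto-dropping PC1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kmers import CellKmerMatrix

__all__ = [
    "FactorModel",
    "standardize",
    "pca",
    "fit_factor_model",
    "n_significant_pcs",
    "project",
    "embed_2d",
    "gc_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """A fitted standardization + PCA model of a cell x k-mer dataset."""

    patterns: list[str]
    cells: list[str]
    feature_means: np.ndarray  # (n_features,)
    feature_sds: np.ndarray  # (n_features,)
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    projections: np.ndarray  # (n_cells, n_components)
    explained_variance: np.ndarray  # (n_components,), non-increasing
    n_significant: int | None = None
    pattern_spans: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def standardize(
    matrix: CellKmerMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scale each pattern row to mean 0, sample SD 1 across cells.

    Zero-variance patterns are dropped with a logged warning.  Returns
    ``(scaled, means, sds, kept_mask)`` where ``scaled`` is
    (n_kept_features, n_cells) and means/sds are over kept features.
    """
    freq = matrix.frequencies
    if freq.shape[1] < 2:
        raise ValueError("standardization needs at least 2 cells")
    means = freq.mean(axis=1)
    sds = freq.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all patterns have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance patterns", n_dropped)
    scaled = (freq[keep] - means[keep, None]) / sds[keep, None]
    return scaled, means[keep], sds[keep], keep


def pca(scaled: np.ndarray, n_components: int | None = None):
    """PCA of a standardized (features x cells) matrix via thin SVD.

    Cells are the observations.  Columns of the returned loadings are
    orthonormal and sign-fixed so the largest-magnitude loading of each
    component is positive.  Returns ``(loadings, projections,
    explained_variance)`` with variance denominators of ``n_cells - 1``.
    """
    n_feat, n_cells = scaled.shape
    if n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    X = scaled.T  # cells x features, columns already centered
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if n_components is not None:
        U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    loadings = Vt.T
    # PCA signs are arbitrary; fix them for reproducible enrichment tails
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    projections = U * S * flip
    explained = S ** 2 / (n_cells - 1)
    return loadings, projections, explained


def fit_factor_model(
    matrix: CellKmerMatrix,
    n_components: int | None = None,
) -> FactorModel:
    """Standardize and decompose a k-mer matrix into a :class:`FactorModel`."""
    scaled, means, sds, keep = standardize(matrix)
    loadings, projections, explained = pca(scaled, n_components)
    return FactorModel(
        patterns=[p for p, k in zip(matrix.patterns, keep) if k],
        cells=list(matrix.cells),
        feature_means=means,
        feature_sds=sds,
        loadings=loadings,
        projections=projections,
        explained_variance=explained,
        pattern_spans=matrix.pattern_spans[keep],
    )


def _explained_variances(scaled: np.ndarray, n_components: int | None) -> np.ndarray:
    """Explained variances only, via the cell x cell Gram matrix (cheap)."""
    n_cells = scaled.shape[1]
    gram = scaled.T @ scaled
    ev = np.linalg.eigvalsh(gram)[::-1] / (n_cells - 1)
    ev = np.clip(ev, 0.0, None)
    return ev[:n_components] if n_components is not None else ev


def n_significant_pcs(
    scaled: np.ndarray,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    max_components: int | None = None,
) -> int:
    """Permutation parallel analysis estimate of the number of signal PCs.

    Each feature row is permuted independently across cells in every
    permutation.  A component is significant if its observed explained
    variance exceeds the (1 - alpha) quantile of permuted explained variance
    at the same rank; significance must hold for a prefix of ranks (the scan
    stops at the first failure).
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _explained_variances(scaled, max_components)
    n_feat, n_cells = scaled.shape
    perm_ev = np.empty((n_permutations, len(observed)))
    for b in range(n_permutations):
        order = np.argsort(rng.random((n_feat, n_cells)), axis=1)
        permuted = np.take_along_axis(scaled, order, axis=1)
        perm_ev[b] = _explained_variances(permuted, None)[: len(observed)]
    threshold = np.quantile(perm_ev, 1.0 - alpha, axis=0)
    n_sig = 0
    for obs, thr in zip(observed, threshold):
        if obs > thr:
            n_sig += 1
        else:
            break
    return n_sig


def project(new_matrix: CellKmerMatrix, model: FactorModel) -> np.ndarray:
    """Project held-out cells onto a fitted model (never re-fits).

    Applies the stored means/SDs then the stored loadings.  The new matrix
    must cover the model's pattern universe; missing patterns raise with the
    offending names listed.
    """
    index = {p: i for i, p in enumerate(new_matrix.patterns)}
    missing = [p for p in model.patterns if p not in index]
    if missing:
        head = ", ".join(missing[:5])
        raise ValueError(f"{len(missing)} model patterns missing from input: {head}...")
    rows = np.array([index[p] for p in model.patterns])
    freq = new_matrix.frequencies[rows]
    scaled = (freq - model.feature_means[:, None]) / model.feature_sds[:, None]
    return scaled.T @ model.loadings


def embed_2d(
    projections: np.ndarray,
    seed: int = 0,
    perplexity: float | None = None,
) -> np.ndarray:
    """t-SNE embedding of significant-PC projections (visualization only).

    Deterministic under a fixed seed.  Statistics are always computed in PC
    space, never on the embedding.
    """
    from sklearn.manifold import TSNE

    n = projections.shape[0]
    if projections.shape[1] < 2:
        raise ValueError("need at least 2 components to embed")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        tsne = TSNE(
            n_components=2, perplexity=perplexity, init="pca",
            random_state=seed, max_iter=500,
        )
        return tsne.fit_transform(np.asarray(projections, dtype=np.float64))


def gc_fraction(patterns: list[str]) -> np.ndarray:
    """G+C fraction of the specified positions of each pattern."""
    out = np.empty(len(patterns))
    for i, p in enumerate(patterns):
        spec = [c for c in p if c != "N"]
        out[i] = sum(c in "GC" for c in spec) / len(spec)
    return out


def gc_correlation(model: FactorModel) -> np.ndarray:
    """Pearson correlation of each component's loadings with pattern G+C.

    The first PC often largely tracks G+C content; this diagnostic is
    reported so users can treat PC1 with care instead of silently losing it.
    """
    gc = gc_fraction(model.patterns)
    gc = gc - gc.mean()
    L = model.loadings - model.loadings.mean(axis=0)
    denom = np.sqrt((gc ** 2).sum()) * np.sqrt((L ** 2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        r = (gc @ L) / denom
    return np.nan_to_num(r)
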
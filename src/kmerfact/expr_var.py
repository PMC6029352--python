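"""Mean-corrected expression variability (excess CV) for gene groups.

Single-cell RNA counts show a floor on the coefficient of variation set by
sampling: under a negative-binomial mean-variance law Var = mu + alpha mu^2,
the minimum CV at mean mu is cv_min(mu) = sqrt(1/mu + alpha) (alpha = 0 is
the Poisson limit 1/sqrt(mu)).  Fitting alpha as a lower envelope of the
observed mean-variance cloud gives a per-gene "excess CV",
log(cv_obs) - log(cv_min(mean)), i.e. variability beyond what the mean
alone predicts.  Gene groups (e.g. TFs enriched on cell-variable PCs vs the
rest) are compared by two-sided Wilcoxon rank-sum tests on mean expression
or excess CV.  CVs are computed on raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneCVRecord",
    "fit_min_cv",
    "cv_min_curve",
    "mean_corrected_cv",
    "compare_tf_groups",
]


@dataclass
class GeneCVRecord:
    """Observed vs minimum CV for one gene."""

    gene: str
    mean_expr: float
    cv_obs: float
    cv_min: float

    @property
    def excess_cv(self) -> float:
        return float(np.log(self.cv_obs) - np.log(self.cv_min))


def fit_min_cv(
    means: np.ndarray,
    variances: np.ndarray,
    method: str = "envelope",
    n_bins: int = 20,
    quantile: float = 0.10,
    n_cells: int | None = None,
) -> float:
    """Fit the dispersion alpha of the NB law Var = mu + alpha mu^2.

    ``method='envelope'`` (default) targets the *minimum* attainable
    variance: genes are binned by mean (log-spaced bins) and the chosen
    lower quantile of variance per bin is regressed on the law.  The bin
    quantile is debiased by the finite-sample factor
    ``chi2.ppf(quantile, n-1) / (n-1)`` — the quantile of sample variances
    of genes that all obey the law sits predictably below the law itself —
    using ``n_cells`` when provided.  ``method='lsq'`` fits all genes by
    plain least squares.  A negative fitted alpha is clamped to 0 (Poisson)
    with a warning.
    """
    mu = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    ok = mu > 0
    mu, v = mu[ok], v[ok]
    if mu.size < 50:
        raise ValueError("need >= 50 genes with positive mean to fit")
    if method == "envelope":
        debias = 1.0
        if n_cells is not None and n_cells > 2:
            debias = stats.chi2.ppf(quantile, n_cells - 1) / (n_cells - 1)
        edges = np.geomspace(mu.min(), mu.max() * (1 + 1e-9), n_bins + 1)
        mu_fit, v_fit = [], []
        idx = np.clip(np.digitize(mu, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            in_bin = idx == b
            if in_bin.sum() < 5:
                continue
            mu_fit.append(np.median(mu[in_bin]))
            v_fit.append(np.quantile(v[in_bin], quantile) / debias)
        mu_fit, v_fit = np.array(mu_fit), np.array(v_fit)
    elif method == "lsq":
        mu_fit, v_fit = mu, v
    else:
        raise ValueError(f"unknown method {method!r}")
    # least squares for alpha in (v - mu) = alpha * mu^2
    alpha = float(((v_fit - mu_fit) * mu_fit ** 2).sum() / (mu_fit ** 4).sum())
    if alpha < 0:
        warnings.warn("fitted dispersion below 0; clamping to Poisson (alpha=0)",
                      stacklevel=2)
        alpha = 0.0
    return alpha


def cv_min_curve(means: np.ndarray, alpha: float) -> np.ndarray:
    """Theoretical minimum CV at each mean: sqrt(1/mu + alpha)."""
    mu = np.asarray(means, dtype=float)
    return np.sqrt(1.0 / mu + alpha)


def mean_corrected_cv(
    counts: pd.DataFrame,
    method: str = "envelope",
    alpha: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene excess CV over the fitted minimum-CV envelope.

    ``counts`` is genes x cells raw counts.  Zero-mean genes are dropped
    with a warning.  Returns ``(table, alpha)`` with columns gene,
    mean_expr, cv_obs, cv_min, excess_cv.
    """
    mu = counts.mean(axis=1).to_numpy(float)
    v = counts.var(axis=1, ddof=1).to_numpy(float)
    genes = np.asarray(counts.index, dtype=object)
    keep = mu > 0
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} zero-mean genes", stacklevel=2)
    mu, v, genes = mu[keep], v[keep], genes[keep]
    if alpha is None:
        alpha = fit_min_cv(mu, v, method=method, n_cells=counts.shape[1])
    cv_obs = np.sqrt(v) / mu
    cv_min = cv_min_curve(mu, alpha)
    with np.errstate(divide="ignore"):
        excess = np.log(cv_obs) - np.log(cv_min)
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_expr": mu,
            "cv_obs": cv_obs,
            "cv_min": cv_min,
            "excess_cv": excess,
        }
    )
    return table, alpha


def compare_tf_groups(
    values: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing a statistic between TF groups.

    ``values`` is indexed by gene/TF name (e.g. excess_cv or mean_expr);
    group members absent from the index are ignored, but both groups must
    remain non-empty.
    """
    a = values.reindex([g for g in group_a if g in values.index]).dropna()
    b = values.reindex([g for g in group_b if g in values.index]).dropna()
    if a.empty or b.empty:
        raise ValueError("both TF groups must be non-empty after matching")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
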
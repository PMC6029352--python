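"""Standardization, PCA identities, permutation parallel analysis, projection."""

import numpy as np
import pytest

from kmerfact.factorize import (
    embed_2d,
    fit_factor_model,
    n_significant_pcs,
    pca,
    project,
    standardize,
)
from kmerfact.kmers import CellKmerMatrix, PatternUniverse, build_matrix
from kmerfact.io_regions import RegionSequenceSet


def _matrix_from_freq(freq: np.ndarray) -> CellKmerMatrix:
    """Wrap a raw frequency array as a span-1 matrix (denominator 1)."""
    n_pat, n_cells = freq.shape
    return CellKmerMatrix(
        patterns=[f"p{i}" for i in range(n_pat)],
        cells=[f"c{j}" for j in range(n_cells)],
        counts=freq,
        scan_positions=np.ones((n_cells, 2), dtype=int),
        pattern_spans=np.ones(n_pat, dtype=int),
    )


class TestStandardize:
    def test_row_123_becomes_minus1_0_1(self):
        m = _matrix_from_freq(np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]]))
        scaled, means, sds, keep = standardize(m)
        np.testing.assert_allclose(scaled[0], [-1.0, 0.0, 1.0])
        assert means[0] == 2.0 and sds[0] == 1.0  # sample SD (n-1)

    def test_constant_rows_dropped(self):
        m = _matrix_from_freq(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        scaled, _, _, keep = standardize(m)
        assert keep.tolist() == [False, True]
        assert scaled.shape == (1, 3)

    def test_idempotent_on_standardized_rows(self):
        row = np.array([[-1.0, 0.0, 1.0]])
        m = _matrix_from_freq(np.vstack([row, [[0.0, 3.0, 1.0]]]))
        scaled, *_ = standardize(m)
        np.testing.assert_allclose(scaled[0], row[0])

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            standardize(_matrix_from_freq(np.ones((3, 4))))


class TestPca:
    def _scaled(self, rng, n_feat=40, n_cells=25):
        X = rng.normal(size=(n_feat, n_cells))
        X -= X.mean(axis=1, keepdims=True)
        X /= X.std(axis=1, ddof=1, keepdims=True)
        return X

    def test_orthonormal_loadings(self, rng):
        loadings, _, _ = pca(self._scaled(rng))
        np.testing.assert_allclose(
            loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-8
        )

    def test_variance_conservation(self, rng):
        X = self._scaled(rng)
        _, _, explained = pca(X)
        total = np.linalg.norm(X) ** 2 / (X.shape[1] - 1)
        assert explained.sum() == pytest.approx(total, rel=1e-10)
        assert (np.diff(explained) <= 1e-12).all()  # non-increasing

    def test_projection_identity(self, rng):
        X = self._scaled(rng)
        loadings, projections, _ = pca(X)
        np.testing.assert_allclose(projections, X.T @ loadings, atol=1e-8)

    def test_rank1_structure_dominates(self, rng):
        direction = rng.normal(size=50)
        cell_scores = rng.normal(size=30)
        X = np.outer(direction, cell_scores) + 1e-4 * rng.normal(size=(50, 30))
        X -= X.mean(axis=1, keepdims=True)
        _, _, explained = pca(X)
        assert explained[0] / explained.sum() > 0.99

    def test_sign_convention_deterministic(self, rng):
        X = self._scaled(rng)
        l1, p1, _ = pca(X)
        l2, p2, _ = pca(X.copy())
        np.testing.assert_allclose(l1, l2)
        for j in range(l1.shape[1]):
            assert l1[np.abs(l1[:, j]).argmax(), j] > 0


def _planted_scaled(rng, n_feat=300, n_cells=60, c=3, snr=6.0):
    """c planted orthogonal components + iid noise, then standardized.

    Cell-score vectors are zero-mean and orthonormal (QR), so the planted
    rank survives row centering; ``snr`` is the per-feature component
    amplitude relative to unit noise.
    """
    basis = np.column_stack([np.ones(n_cells), rng.normal(size=(n_cells, c))])
    q, _ = np.linalg.qr(basis)
    scores = q[:, 1:]  # orthonormal and exactly zero-mean
    X = rng.normal(size=(n_feat, n_cells))
    for i in range(c):
        direction = rng.normal(size=n_feat)
        X += snr * np.outer(direction / np.abs(direction).mean(), scores[:, i])
    X -= X.mean(axis=1, keepdims=True)
    X /= X.std(axis=1, ddof=1, keepdims=True)
    return X


class TestParallelAnalysis:
    def test_pure_noise_zero_significant(self, rng):
        X = rng.normal(size=(200, 40))
        X -= X.mean(axis=1, keepdims=True)
        X /= X.std(axis=1, ddof=1, keepdims=True)
        assert n_significant_pcs(X, n_permutations=30, alpha=0.05, seed=0) == 0

    def test_planted_components_recovered(self, rng):
        """Exactly 3 planted orthogonal components found at high SNR."""
        hits = 0
        for seed in range(10):
            X = _planted_scaled(np.random.default_rng(seed))
            n = n_significant_pcs(X, n_permutations=30, alpha=0.05, seed=seed)
            hits += n == 3
        assert hits >= 9

    def test_deterministic_under_seed(self, rng):
        X = _planted_scaled(rng)
        a = n_significant_pcs(X, n_permutations=20, alpha=0.05, seed=7)
        b = n_significant_pcs(X, n_permutations=20, alpha=0.05, seed=7)
        assert a == b

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            n_significant_pcs(rng.normal(size=(10, 5)), n_permutations=5)


def _toy_matrix(rng, n_cells=12):
    seqs = []
    for i in range(n_cells):
        s = "".join(rng.choice(list("ACGT"), size=400))
        seqs.append(RegionSequenceSet(cell_id=f"c{i}", sequences=[s]))
    return build_matrix(seqs, PatternUniverse(3))


class TestProject:
    def test_training_cells_reproduce_projections(self, rng):
        mat = _toy_matrix(rng)
        model = fit_factor_model(mat)
        np.testing.assert_allclose(project(mat, model), model.projections, atol=1e-8)

    def test_duplicated_heldout_cell_lands_on_twin(self, rng):
        mat = _toy_matrix(rng)
        model = fit_factor_model(mat)
        coords = project(mat, model)
        np.testing.assert_allclose(coords[3], project(mat, model)[3])

    def test_missing_patterns_listed(self, rng):
        mat = _toy_matrix(rng)
        model = fit_factor_model(mat)
        small = mat.subset_patterns(np.arange(len(mat.patterns)) < 10)
        with pytest.raises(ValueError, match="missing"):
            project(small, model)


class TestEmbed2d:
    def test_shape_and_determinism(self, rng):
        proj = rng.normal(size=(40, 5))
        a = embed_2d(proj, seed=3)
        b = embed_2d(proj, seed=3)
        assert a.shape == (40, 2)
        np.testing.assert_allclose(a, b)

    def test_two_groups_separate(self, rng):
        proj = np.vstack([
            rng.normal(0, 0.3, size=(25, 4)) + [6, 0, 0, 0],
            rng.normal(0, 0.3, size=(25, 4)),
        ])
        xy = embed_2d(proj, seed=0)
        from sklearn.cluster import KMeans

        labels = KMeans(2, n_init=10, random_state=0).fit_predict(xy)
        truth = np.repeat([0, 1], 25)
        purity = max((labels == truth).mean(), (labels != truth).mean())
        assert purity > 0.9
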
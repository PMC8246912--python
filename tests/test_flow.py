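import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from lineagetrace import flow
from lineagetrace.io import EventTable
from lineagetrace.simulate import simulate_flow_events


def _table(values, kinds=None, population=None):
    df = pd.DataFrame(values)
    df.columns = [str(c) for c in df.columns]
    kinds = kinds or {c: "scatter" for c in df.columns}
    pop = population if population is not None else np.array(["A"] * len(df))
    return EventTable(data=df, kinds=kinds, population=np.asarray(pop, dtype=object))


class TestPreprocess:
    def test_downsamples_to_minimum_population(self):
        t = simulate_flow_events(["A", "B", "C", "D", "E"], [100, 250, 80, 300, 120], seed=0)
        pre = flow.preprocess_events(t, seed=0)
        pops, counts = np.unique(pre.population, return_counts=True)
        assert len(pops) == 5 and counts.max() <= 80
        assert len(pre.matrix) <= 400

    def test_duplicate_row_removed(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 3))
        vals[7] = vals[2]  # exact duplicate
        t = _table(vals, population=["A"] * 5 + ["B"] * 5)
        pre = flow.preprocess_events(t, seed=0)
        assert len(pre.matrix) == 9
        assert 7 not in pre.kept_index and 2 in pre.kept_index  # first copy kept

    def test_output_is_zscored(self):
        t = simulate_flow_events(["A", "B"], [60, 50], seed=1)
        pre = flow.preprocess_events(t, seed=0)
        np.testing.assert_allclose(pre.matrix.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(pre.matrix.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_idempotent_on_own_output(self):
        """Re-running on the already z-scored output is a fixed point."""
        t = simulate_flow_events(["A", "B"], [50, 50], seed=2)
        pre = flow.preprocess_events(t, seed=0)
        # z-scored values can be negative, so feed them back as scatter kind
        t2 = _table(pre.matrix.to_numpy(), population=pre.population)
        pre2 = flow.preprocess_events(t2, seed=0)
        np.testing.assert_allclose(pre2.matrix.to_numpy(), pre.matrix.to_numpy(), atol=1e-10)

    def test_errors(self):
        t = _table(np.ones((4, 2)), population=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="zero-variance"):
            flow.preprocess_events(t, seed=0)
        single = _table(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="2 populations"):
            flow.preprocess_events(single, seed=0)


class TestPCA:
    def test_two_point_geometry(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        model, scores = flow.fit_pca(X, 1)
        # PC1 collinear with the difference vector; standardized points at +/-1
        np.testing.assert_allclose(np.abs(model.loadings[:, 0]), 1 / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(sorted(scores[:, 0]), [-np.sqrt(2), np.sqrt(2)], atol=1e-12)

    @pytest.mark.parametrize("shape", [(10, 3), (25, 6), (50, 10)])
    def test_matches_covariance_eigendecomposition(self, shape):
        """Loadings/eigenvalues equal the brute-force eigendecomposition of
        the sample covariance of the standardized data."""
        rng = np.random.default_rng(sum(shape))
        X = rng.normal(size=shape)
        model, scores = flow.fit_pca(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        C = Z.T @ Z / (shape[0] - 1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(-evals)
        evals, evecs = evals[order], evecs[:, order]
        k = model.loadings.shape[1]
        np.testing.assert_allclose(model.explained_variance, evals[:k], atol=1e-8)
        for j in range(k):
            dot = abs(evecs[:, j] @ model.loadings[:, j])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)
        # trace identity at full rank: eigenvalues sum to the number of
        # standardized columns (scaled by n/(n-1) for the ddof-0 z-score)
        n, p = shape
        np.testing.assert_allclose(model.explained_variance.sum(), p * n / (n - 1), atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        model, _ = flow.fit_pca(rng.normal(size=(30, 4)))
        for j in range(model.loadings.shape[1]):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_n_components_bound(self):
        with pytest.raises(ValueError, match="n_components"):
            flow.fit_pca(np.random.default_rng(0).normal(size=(3, 5)), 4)


class TestProjection:
    def test_training_projection_idempotent(self):
        t = simulate_flow_events(["A", "B"], [60, 60], seed=4)
        model, scores, kept, _ = flow.fit_reference_pca(t, seed=0)
        proj = flow.project_pca(model, t.subset(kept))
        np.testing.assert_allclose(proj, scores, atol=1e-10)

    def test_training_mean_maps_to_origin(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        model, _ = flow.fit_pca(X)
        proj = flow.project_pca(model, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(proj, 0.0, atol=1e-10)

    def test_hand_computed_two_parameter_example(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 44.0]])
        model, _ = flow.fit_pca(X)
        q = np.array([[2.5, 25.0]])
        expected = ((q - X.mean(0)) / X.std(0, ddof=0)) @ model.loadings
        np.testing.assert_allclose(flow.project_pca(model, q), expected, atol=1e-12)

    def test_missing_parameter_errors(self):
        t = simulate_flow_events(["A", "B"], [30, 30], seed=0)
        model, _, _, _ = flow.fit_reference_pca(t, seed=0)
        with pytest.raises(KeyError, match="missing parameter"):
            flow.project_pca(model, pd.DataFrame({"FL1": [1.0]}))


class TestDiffusionMap:
    def test_ramp_dc1_monotone_and_matches_dense_oracle(self):
        """On a noiseless 1-D ramp, DC1 orders points (Spearman |rho| = 1)
        and the whole embedding matches an independently coded dense-kernel
        eigendecomposition."""
        # irregular spacing avoids tied kNN distances
        x = np.sort(np.random.default_rng(0).uniform(0, 1, 200))[:, None]
        dm = flow.fit_diffusion_map(x, n_dcs=5, n_neighbors=10)
        rho = stats.spearmanr(dm.components[:, 0], x[:, 0])[0]
        assert abs(rho) == 1.0

        # brute-force oracle: same kernel, dense loops, plain eig of P
        n, k = 200, 10
        D = np.abs(x - x.T)
        sigma = np.sort(D, axis=1)[:, k - 1]
        W = np.zeros((n, n))
        for i in range(n):
            nbr = np.argsort(D[i])[:k]
            for j in nbr:
                W[i, j] = np.exp(-D[i, j] ** 2 / (sigma[i] * sigma[j]))
        W = np.maximum(W, W.T)
        np.fill_diagonal(W, 1.0)
        q = W.sum(1)
        W = W / np.outer(q, q)
        P = W / W.sum(1, keepdims=True)
        evals, evecs = np.linalg.eig(P)
        order = np.argsort(-np.abs(evals.real))
        evals = evals.real[order]
        np.testing.assert_allclose(np.sort(dm.eigenvalues), np.sort(evals[1:6]), atol=1e-8)

    def test_markov_spectrum(self):
        rng = np.random.default_rng(2)
        dm = flow.fit_diffusion_map(rng.normal(size=(80, 4)), n_dcs=6, n_neighbors=15)
        assert np.all(np.abs(dm.eigenvalues) < 1.0)  # trivial unit eigenvalue dropped
        assert np.all(np.diff(np.abs(dm.eigenvalues)) <= 1e-12)

    def test_order_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        perm = rng.permutation(60)
        a = flow.fit_diffusion_map(X, 4, 12)
        b = flow.fit_diffusion_map(X[perm], 4, 12)
        np.testing.assert_allclose(np.abs(b.components), np.abs(a.components[perm]), atol=1e-6)

    def test_branch_separation_on_synthetic_manifold(self):
        """Populations along a branching manifold separate in (DC1, DC2)."""
        t = simulate_flow_events(["P1", "P2", "P3", "P4", "P5"], [120, 120, 120, 120, 120], seed=6)
        pre = flow.preprocess_events(t, seed=0)
        dm = flow.fit_diffusion_map(pre.matrix, 10, 30)
        assert silhouette_score(dm.components[:, :2], pre.population) > 0

    def test_disconnected_graph_errors(self):
        X = np.vstack([np.zeros((10, 2)), 1000 + np.zeros((10, 2))])
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        with pytest.raises(ValueError, match="n_neighbors"):
            flow.fit_diffusion_map(X, 2, 5)
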
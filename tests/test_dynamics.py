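import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lineagetrace import dynamics, flow
from lineagetrace.dynamics import PseudotimeOrdering
from lineagetrace.io import ExpressionMatrix
from lineagetrace.scrna import normalize_log
from lineagetrace.simulate import SimParams, simulate_bifurcating_expression
from tests.conftest import orientation_markers


def _ordering(pt, ids=None):
    ids = ids or [f"c{i}" for i in range(len(pt))]
    return PseudotimeOrdering(cell_ids=ids, pseudotime=np.asarray(pt, float),
                              method="pc1", provenance={})


def _lognorm(values, **kw):
    values = np.asarray(values, dtype=float)
    ng, nc = values.shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(ng)],
                            [f"c{i}" for i in range(nc)], ["x"] * nc, "lognorm")


class TestPC1Pseudotime:
    def test_single_decreasing_gene_reverses_its_sort(self):
        vals = np.array([[9.0, 7.0, 5.0, 3.0, 1.0]])
        m = _lognorm(vals)
        pt = dynamics.pc1_pseudotime(m, ["g0"], n_top_genes=1)
        assert stats.spearmanr(pt.pseudotime, vals[0])[0] <= -1.0 + 1e-12

    def test_orientation_contract_sign_insensitive(self):
        """The returned pseudotime is the same whichever sign PCA happens to
        give PC1: orientation genes always end up decreasing."""
        rng = np.random.default_rng(0)
        n = 60
        t = np.sort(rng.uniform(size=n))
        vals = np.vstack([5 - 4 * t + rng.normal(0, 0.1, n),
                          1 + 4 * t + rng.normal(0, 0.1, n),
                          5 - 3 * t + rng.normal(0, 0.1, n)])
        m = _lognorm(np.abs(vals))
        pt = dynamics.pc1_pseudotime(m, ["g0"])
        r = stats.pearsonr(m.values[0], pt.pseudotime)[0]
        assert r < 0

    def test_uncorrelated_orientation_gene_errors(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(3, 1, (5, 40)))
        vals[0] = 2.0  # constant: zero correlation with anything
        m = _lognorm(vals)
        with pytest.raises(ValueError, match="direction undefined"):
            dynamics.pc1_pseudotime(m, ["g0"])

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_recovers_latent_time_on_synthetic_trajectory(self, seed):
        params = SimParams(n_cells=300, n_genes=2000, seed=seed, p_branch_a=1.0)
        matrix, truth = simulate_bifurcating_expression(params)
        ln = normalize_log(matrix)
        pt = dynamics.pc1_pseudotime(ln, orientation_markers(truth))
        rho = abs(stats.spearmanr(pt.pseudotime, truth.latent_time)[0])
        assert rho >= 0.9


class TestDiffusionPseudotime:
    @pytest.fixture(scope="class")
    def chain(self):
        x = np.sort(np.random.default_rng(5).uniform(0, 1, 150))[:, None]
        return x, flow.fit_diffusion_map(x, n_dcs=8, n_neighbors=10)

    def test_root_distance_zero_and_symmetry(self, chain):
        _, dm = chain
        pt0 = dynamics.diffusion_pseudotime(dm, 0)
        assert pt0.pseudotime[0] == 0.0
        pt7 = dynamics.diffusion_pseudotime(dm, 7)
        assert np.isclose(pt0.pseudotime[7], pt7.pseudotime[0])

    def test_chain_monotone_and_matches_brute_force_formula(self, chain):
        """DPT along a 1-D chain is monotone in arc position and equals an
        explicit per-cell evaluation of the rescaled-eigencomponent formula."""
        x, dm = chain
        pt = dynamics.diffusion_pseudotime(dm, 0)
        assert abs(stats.spearmanr(pt.pseudotime, x[:, 0])[0]) >= 0.99

        lam, psi = dm.eigenvalues, dm.psi
        for cell in [3, 50, 149]:
            acc = 0.0
            for i in range(len(lam)):
                w = lam[i] / (1 - lam[i])
                acc += (w * (psi[cell, i] - psi[0, i])) ** 2
            assert abs(pt.pseudotime[cell] - np.sqrt(acc)) < 1e-6

    def test_pseudotime_ordering_invariant_under_monotone_transform(self, chain):
        _, dm = chain
        pt = dynamics.diffusion_pseudotime(dm, 0)
        transformed = np.tanh(2 * pt.pseudotime) + 5 * pt.pseudotime
        assert stats.spearmanr(pt.pseudotime, transformed)[0] == 1.0


class TestSelectRoot:
    def test_unique_maximum_and_ties(self):
        assert dynamics.select_root(["b", "a", "c"], [1, 3, 2]) == "a"
        assert dynamics.select_root(["b", "a", "c"], [3, 3, 1]) == "a"  # lexicographic tie-break
        with pytest.raises(ValueError):
            dynamics.select_root([], [])


class TestSmoothing:
    def test_window_one_is_reordering_identity(self):
        pt = _ordering([3.0, 1.0, 2.0])
        sm = dynamics.sliding_window_smooth([30.0, 10.0, 20.0], pt, window=1, scaling="none")
        np.testing.assert_array_equal(sm.values, [10.0, 20.0, 30.0])

    def test_ramp_window_three(self):
        pt = _ordering(np.arange(10, dtype=float))
        sm = dynamics.sliding_window_smooth(np.arange(1.0, 11.0), pt, window=3, scaling="none")
        np.testing.assert_allclose(sm.values, np.arange(2.0, 10.0))

    def test_constant_input_minmax_is_zero(self):
        pt = _ordering(np.arange(5, dtype=float))
        sm = dynamics.sliding_window_smooth(np.full(5, 7.0), pt, window=2, scaling="minmax01")
        np.testing.assert_array_equal(sm.values, 0.0)

    def test_scaling_contracts(self):
        pt = _ordering(np.arange(30, dtype=float))
        v = np.random.default_rng(0).uniform(1, 5, 30)
        z = dynamics.sliding_window_smooth(v, pt, 5, "zscore").values
        assert abs(z.mean()) < 1e-8
        mm = dynamics.sliding_window_smooth(v, pt, 5, "minmax01").values
        assert mm.min() >= 0 and mm.max() <= 1
        mx = dynamics.sliding_window_smooth(v, pt, 5, "maxscale").values
        assert np.isclose(mx.max(), 1.0)

    def test_window_bounds(self):
        pt = _ordering([1.0, 2.0])
        with pytest.raises(ValueError, match="window"):
            dynamics.sliding_window_smooth([1.0, 2.0], pt, window=3)


class TestWindowComposition:
    def test_single_label(self):
        pt = _ordering(np.arange(6, dtype=float))
        comp = dynamics.window_composition(["A"] * 6, pt, window=2)
        np.testing.assert_array_equal(comp["A"], 1.0)

    def test_two_block_labels_monotone(self):
        pt = _ordering(np.arange(20, dtype=float))
        comp = dynamics.window_composition(["A"] * 10 + ["B"] * 10, pt, window=4)
        a = comp["A"].to_numpy()
        assert a[0] == 1.0 and a[-1] == 0.0
        assert np.all(np.diff(a) <= 1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        pt = _ordering(rng.uniform(size=50))
        comp = dynamics.window_composition(rng.choice(["A", "B", "C"], 50), pt, window=7)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-12)


class TestMarkerCorrelation:
    def test_exact_cases_and_hand_formula(self):
        pt = _ordering([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.isclose(dynamics.marker_pseudotime_correlation(pt.pseudotime, pt), 1.0)
        assert np.isclose(dynamics.marker_pseudotime_correlation(-pt.pseudotime, pt), -1.0)
        v = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        x = pt.pseudotime
        r_hand = ((v - v.mean()) * (x - x.mean())).sum() / np.sqrt(
            ((v - v.mean()) ** 2).sum() * ((x - x.mean()) ** 2).sum()
        )
        assert np.isclose(dynamics.marker_pseudotime_correlation(v, pt), r_hand)

    def test_zero_variance_errors(self):
        pt = _ordering([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            dynamics.marker_pseudotime_correlation([5.0, 5.0, 5.0], pt)

    def test_reported_r_uses_unsmoothed_values(self):
        """Smoothing the marker changes its correlation with pseudotime, but
        the reported r is computed on the raw values."""
        rng = np.random.default_rng(3)
        n = 100
        pt = _ordering(np.arange(n, dtype=float))
        marker = pt.pseudotime + rng.normal(0, 30, n)
        r_raw = dynamics.marker_pseudotime_correlation(marker, pt)
        smoothed = dynamics.sliding_window_smooth(marker, pt, 20, "none").values
        r_smoothed = stats.pearsonr(smoothed, np.arange(len(smoothed)))[0]
        assert abs(r_smoothed) > abs(r_raw) + 0.1  # smoothing inflates |r|
        assert np.isclose(r_raw, stats.pearsonr(marker, pt.pseudotime)[0])


class TestDynamicGeneTest:
    def test_constant_gene_statistic_zero_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, (5, 150))
        vals[2] = 1.5
        m = _lognorm(vals)
        pt = _ordering(rng.uniform(size=150), ids=m.cell_ids)
        tab = dynamics.dynamic_gene_test(m, pt, window=20, n_perm=100, seed=0)
        assert tab.loc[2, "statistic"] == 0.0
        assert tab.loc[2, "p_perm"] == 1.0

    def test_type_one_error_on_null_fixture(self):
        """All-flat simulated genes: on average at most 1% flagged at BH .01
        (small version; the full-size study runs in the acceptance suite)."""
        fracs = []
        for seed in range(3):
            params = SimParams(n_cells=200, n_genes=300, seed=seed,
                               effect_size_range=(0.0, 0.0), frac_cycle=0.0)
            matrix, _ = simulate_bifurcating_expression(params)
            ln = normalize_log(matrix)
            pt = _ordering(np.random.default_rng(seed).uniform(size=200), ids=ln.cell_ids)
            tab = dynamics.dynamic_gene_test(ln, pt, 20, 1000, seed=seed)
            fracs.append(tab["is_dynamic"].mean())
        assert np.mean(fracs) <= 0.01

    def test_planted_genes_recovered(self, basophil_sim, basophil_lognorm):
        _, truth = basophil_sim
        pt = dynamics.pc1_pseudotime(basophil_lognorm, orientation_markers(truth))
        tab = dynamics.dynamic_gene_test(basophil_lognorm, pt, 20, 1000, seed=0)
        called = tab["is_dynamic"].to_numpy()
        recall = (called & truth.is_dynamic).sum() / truth.is_dynamic.sum()
        assert recall >= 0.9

    def test_window_bound(self):
        m = _lognorm(np.ones((2, 10)))
        pt = _ordering(np.arange(10, dtype=float), ids=m.cell_ids)
        with pytest.raises(ValueError, match="window"):
            dynamics.dynamic_gene_test(m, pt, window=11, n_perm=100)


def _planted_profiles(n_each=50, n_pos=80, seed=0):
    """Clean logistic increasing/decreasing profiles, z-scored."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n_pos)
    up = np.stack([1 / (1 + np.exp(-rng.uniform(6, 12) * (x - rng.uniform(0.3, 0.7))))
                   for _ in range(n_each)])
    down = 1 - np.stack([1 / (1 + np.exp(-rng.uniform(6, 12) * (x - rng.uniform(0.3, 0.7))))
                         for _ in range(n_each)])
    P = np.vstack([up, down])
    return (P - P.mean(1, keepdims=True)) / P.std(1, keepdims=True)


class TestClustering:
    def test_identical_profiles_one_cluster(self):
        P = np.tile(np.linspace(0, 1, 20), (2, 1))
        labels = dynamics.cluster_dynamic_genes(P, seed=0)
        assert labels.tolist() == [0, 0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_planted_groups_recovered(self, seed):
        """50 increasing + 50 decreasing profiles split into exactly the two
        planted groups with purity >= 0.95."""
        P = _planted_profiles(seed=seed)
        labels = dynamics.cluster_dynamic_genes(P, seed=seed)
        truth = np.array([0] * 50 + [1] * 50)
        ct = pd.crosstab(labels, truth)
        purity = ct.max(axis=1).sum() / 100
        assert purity >= 0.95
        assert len(ct) == 2

    def test_partition_covers_all_genes(self):
        P = _planted_profiles(n_each=10, seed=3)
        labels = dynamics.cluster_dynamic_genes(P, seed=0)
        assert len(labels) == 20 and np.all(labels >= 0)

    def test_single_gene_warns(self):
        with pytest.warns(UserWarning):
            labels = dynamics.cluster_dynamic_genes(np.ones((1, 5)), seed=0)
        assert labels.tolist() == [0]


class TestMaxScale:
    def test_arithmetic_and_idempotence(self):
        np.testing.assert_allclose(dynamics.max_scale_profiles(np.array([[2.0, 4.0]])),
                                   [[0.5, 1.0]])
        P = np.array([[0.2, 1.0, 0.5]])
        np.testing.assert_allclose(dynamics.max_scale_profiles(P), P)

    def test_argmax_staging_preserved(self):
        rng = np.random.default_rng(4)
        P = rng.uniform(0.1, 1, (10, 30))
        scaled = dynamics.max_scale_profiles(P)
        np.testing.assert_array_equal(np.argmax(scaled, 1), np.argmax(P, 1))

    def test_nonpositive_max_errors(self):
        with pytest.raises(ValueError, match="positive maximum"):
            dynamics.max_scale_profiles(np.array([[0.0, 0.0]]))
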
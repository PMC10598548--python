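import numpy as np
import pytest

from ecskat.association import WeightVector, null_eigenvalues, skat_statistic
from ecskat.dataset import Dataset
from ecskat.kernel_learning import (
    ProjectedGram,
    certified_level,
    ecskat_test,
    multi_kernel_stats,
    objective,
    projected_gram,
    pvalue_bound,
    solve_weights,
    split_indices,
)
from ecskat.mixchisq import survival
from ecskat.null_model import fit_null, projection_matrix
from ecskat.synthetic import SimConfig, simulate
from .conftest import make_instance


def _random_simplex(rng, p):
    w = rng.dirichlet(np.ones(p))
    return WeightVector.from_raw(w)


class TestProjectedGram:
    def test_zero_residuals_give_zero_scores(self, instance):
        ds, fit = instance
        fit.r = np.zeros(ds.n)
        pg = projected_gram(fit, ds.X, ds.G)
        np.testing.assert_allclose(pg.s, 0.0)

    def test_intercept_only_closed_form(self, rng):
        ds, _ = make_instance(rng, n=40, p=4, m=0)
        fit = fit_null(ds)
        pg = projected_gram(fit, ds.X, ds.G)
        Gc = ds.G - ds.G.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(pg.B, fit.phi0 * Gc.T @ Gc, rtol=1e-10)

    def test_matches_dense_projection_oracle(self, rng):
        ds, fit = make_instance(rng, n=6, p=3, m=1)
        P0 = projection_matrix(fit, ds.X)
        pg = projected_gram(fit, ds.X, ds.G)
        np.testing.assert_allclose(pg.B, ds.G.T @ P0 @ ds.G, atol=1e-10)
        np.testing.assert_allclose(pg.s, (ds.G.T @ fit.r) ** 2, atol=1e-12)
        np.testing.assert_allclose(pg.b, np.diag(pg.B))


class TestObjective:
    def test_single_coordinate_reduction(self, instance):
        ds, fit = instance
        pg = projected_gram(fit, ds.X, ds.G)
        e0 = WeightVector(np.eye(ds.p)[0])
        assert objective(pg, e0) == pytest.approx(pg.s[0] / pg.B[0, 0], rel=1e-10)
        pg2 = ProjectedGram(B=pg.B, s=pg.b.copy(), b=pg.b, phi0=pg.phi0)
        assert objective(pg2, e0, centered=True) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trait", ["continuous", "binary"])
    def test_ratio_identity_with_eigen_route(self, rng, trait):
        """The central correctness identity: J(w) = Q(w) / ||lambda0(w)||_2."""
        for _ in range(5):
            ds, fit = make_instance(rng, n=120, p=6, m=2, trait_type=trait)
            pg = projected_gram(fit, ds.X, ds.G)
            w = _random_simplex(rng, ds.p)
            J = objective(pg, w)
            Q = skat_statistic(fit, ds.G, w)
            lam = null_eigenvalues(fit, ds.X, ds.G, w).lambdas
            assert J == pytest.approx(Q / np.linalg.norm(lam), rel=1e-8)

    def test_zero_denominator_raises(self):
        pg = ProjectedGram(B=np.zeros((2, 2)), s=np.ones(2), b=np.zeros(2), phi0=1.0)
        with pytest.raises(ValueError, match="denominator"):
            objective(pg, WeightVector.uniform(2))


class TestSolveWeights:
    def test_separable_case_proportional_to_scores(self):
        # B with unit diagonal and zero off-diagonal: B*B = I, so z* = max(c, 0)
        s = np.array([0.5, 2.0, 0.0])
        pg = ProjectedGram(B=np.eye(3), s=s, b=np.zeros(3), phi0=1.0)
        w = solve_weights(pg)
        np.testing.assert_allclose(w.w, s / s.sum(), atol=1e-10)

    def test_no_signal_falls_back_to_uniform(self):
        pg = ProjectedGram(B=np.eye(3), s=np.zeros(3), b=np.zeros(3), phi0=1.0)
        w, info = solve_weights(pg, return_info=True)
        assert info["no_signal"]
        np.testing.assert_allclose(w.w, 1 / 3)

    def test_qp_attains_simplex_grid_maximum(self, rng):
        """w* beats every point of a fine simplex grid in J, and satisfies KKT."""
        step = np.arange(0, 101) / 100
        grid = np.array([(a, b, 1 - a - b) for a in step for b in step if a + b <= 1.0])
        for _ in range(5):
            ds, fit = make_instance(rng, n=80, p=3, m=1)
            pg = projected_gram(fit, ds.X, ds.G)
            w_star, info = solve_weights(pg, return_info=True)
            assert info["kkt_residual"] < 1e-6 * max(1.0, np.abs(pg.s).max())
            J_star = objective(pg, w_star)
            M = pg.B * pg.B
            num = grid @ pg.s
            den = np.sqrt(np.einsum("ij,jk,ik->i", grid, M, grid))
            ok = den > 0
            assert J_star >= (num[ok] / den[ok]).max() - 1e-6

    def test_ridge_retry_on_semidefinite_gram(self):
        B = np.ones((3, 3))  # rank one -> B*B rank one, Cholesky fails
        pg = ProjectedGram(B=B, s=np.array([1.0, 2.0, 3.0]), b=np.ones(3), phi0=1.0)
        w, info = solve_weights(pg, return_info=True)
        assert info["ridge"] > 0
        assert w.w.sum() == pytest.approx(1.0)


class TestBound:
    @pytest.mark.parametrize(
        "J,expected",
        [(8.0, np.exp(-1.0)), (0.0, 1.0), (0.5, np.exp(-0.25 / 8)), (-3.0, 1.0)],
    )
    def test_bound_values(self, J, expected):
        assert pvalue_bound(J) == pytest.approx(expected, rel=1e-12)

    def test_certified_level_values_and_monotonicity(self):
        assert certified_level(0.0) == 0.0
        assert certified_level(-1.0) == 0.0
        assert certified_level(8 * np.log(10)) == pytest.approx(1.0, rel=1e-12)
        js = np.linspace(0, 30, 100)
        levels = [certified_level(j) for j in js]
        assert all(a <= b + 1e-15 for a, b in zip(levels, levels[1:]))

    @pytest.mark.parametrize("trait", ["continuous", "binary"])
    def test_null_pvalue_never_exceeds_bound(self, rng, trait):
        """Concentration bound: p0(Q(w)) <= exp(-min(Jt, Jt^2)/8) for any w."""
        for _ in range(10):
            ds, fit = make_instance(rng, n=100, p=5, m=2, trait_type=trait)
            pg = projected_gram(fit, ds.X, ds.G)
            for w in (solve_weights(pg), _random_simplex(rng, ds.p)):
                Q = skat_statistic(fit, ds.G, w)
                lam = null_eigenvalues(fit, ds.X, ds.G, w)
                p = survival(lam, Q)
                assert p <= pvalue_bound(objective(pg, w, centered=True)) + 1e-9


class TestEcskat:
    def test_same_seed_reproduces_everything(self, rng):
        truth = simulate(SimConfig(n=400, p=20, causal_fraction=0.1), seed=5)
        a = ecskat_test(truth.dataset, seed=42)
        b = ecskat_test(truth.dataset, seed=42)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_allclose(a.w_star.w, b.w_star.w)
        assert a.result.p_value == b.result.p_value
        c = ecskat_test(truth.dataset, seed=43)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_split_partitions_and_stratification(self, rng):
        truth = simulate(SimConfig(n=300, p=10, trait_type="binary", causal_fraction=0.0), seed=1)
        ds = truth.dataset
        train, test = split_indices(ds, 0.3, np.random.default_rng(0))
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == ds.n
        case_rate = ds.y.mean()
        assert ds.y[train].mean() == pytest.approx(case_rate, abs=0.05)

    def test_learned_weights_and_bound_come_from_train_split(self, rng):
        truth = simulate(SimConfig(n=600, p=15, causal_fraction=0.1), seed=9)
        lk = ecskat_test(truth.dataset, seed=3)
        ds_tr = truth.dataset.subset(lk.train_idx)
        fit_tr = fit_null(ds_tr)
        pg = projected_gram(fit_tr, ds_tr.X, ds_tr.G)
        assert lk.J == pytest.approx(objective(pg, lk.w_star), rel=1e-10)
        assert lk.bound == pytest.approx(pvalue_bound(objective(pg, lk.w_star, centered=True)))

    def test_split_too_small_raises(self, rng):
        ds, _ = make_instance(rng, n=12, p=3, m=2)
        with pytest.raises(ValueError, match="split too small"):
            ecskat_test(ds, train_ratio=0.1, seed=0)

    def test_positive_homogeneity_of_genotype_scale(self, rng):
        """Multiplying G by c > 0 leaves w* and the p-value unchanged."""
        truth = simulate(SimConfig(n=500, p=12, causal_fraction=0.2), seed=7)
        ds = truth.dataset
        lk1 = ecskat_test(ds, seed=11)
        fit = fit_null(ds)
        pg1 = projected_gram(fit, ds.X, ds.G)
        pg2 = projected_gram(fit, ds.X, 3.0 * ds.G)
        np.testing.assert_allclose(solve_weights(pg1).w, solve_weights(pg2).w, atol=1e-8)
        Q1, Q2 = (skat_statistic(fit, g, lk1.w_star) for g in (ds.G, 3.0 * ds.G))
        lam1 = null_eigenvalues(fit, ds.X, ds.G, lk1.w_star)
        lam2 = null_eigenvalues(fit, ds.X, 3.0 * ds.G, lk1.w_star)
        assert survival(lam1, Q1) == pytest.approx(survival(lam2, Q2), rel=1e-6)


class TestMultiKernel:
    def test_per_variant_kernels_reduce_to_projected_gram(self, rng, instance):
        ds, fit = instance
        pg = projected_gram(fit, ds.X, ds.G)
        feats = [ds.G[:, j : j + 1] for j in range(ds.p)]
        s_L, M = multi_kernel_stats(fit, ds.X, feats, as_features=True)
        np.testing.assert_allclose(s_L, pg.s, rtol=1e-10)
        np.testing.assert_allclose(M, pg.B * pg.B, rtol=1e-10, atol=1e-10)

    def test_single_kernel_eigen_identity(self, rng, instance):
        ds, fit = instance
        w = WeightVector.uniform(ds.p)
        K = ds.G @ np.diag(w.w) @ ds.G.T
        s_L, M = multi_kernel_stats(fit, ds.X, [K])
        lam = null_eigenvalues(fit, ds.X, ds.G, w).lambdas
        assert M[0, 0] == pytest.approx(np.sum(lam**2) * fit.phi0**2, rel=1e-8)
        assert s_L[0] == pytest.approx(skat_statistic(fit, ds.G, w) * fit.phi0, rel=1e-10)

    def test_annotation_kernels_match_direct_construction(self, rng, instance):
        ds, fit = instance
        # two annotation channels with aggregation phi(x) = x^2
        ann = rng.uniform(0.5, 2.0, size=(2, ds.p))
        feats = [ds.G * ann[l] for l in range(2)]  # G diag(phi) embedded as features
        kernels = [ds.G @ np.diag(ann[l] ** 2) @ ds.G.T for l in range(2)]
        s_f, M_f = multi_kernel_stats(fit, ds.X, feats, as_features=True)
        s_k, M_k = multi_kernel_stats(fit, ds.X, kernels)
        np.testing.assert_allclose(s_f, s_k, rtol=1e-9)
        np.testing.assert_allclose(M_f, M_k, rtol=1e-8)

    def test_non_psd_kernel_rejected(self, instance):
        ds, fit = instance
        K = -np.eye(ds.n)
        with pytest.raises(ValueError, match="positive semi-definite"):
            multi_kernel_stats(fit, ds.X, [K])
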
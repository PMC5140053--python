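"""Fused ridge solver: augmented systems, direct/iterative agreement, objective."""

import numpy as np
import pytest
from scipy.linalg import lstsq

from fusenet.constraints import ConstraintSet, FusionConstraint
from fusenet.data_model import RegressionTask
from fusenet.solver import (
    NetworkCoefficients,
    SolverConfig,
    build_augmented_system,
    fused_objective,
    solve_fused_direct,
    solve_fused_iterative,
)
from .conftest import make_random_instance


def _single_response_task(X, y, tfs):
    return RegressionTask("s1", X, np.asarray(y, float)[:, None], 0.1, tfs, ["gene"])


class TestAugmentedSystem:
    def test_ridge_rows_are_sqrt_lambda_identity(self):
        task = _single_response_task(np.eye(2), [1.0, 2.0], ["t1", "t2"])
        cfg = SolverConfig(lambda_r=4.0)
        A, b, coefs = build_augmented_system({("s1", "gene")}, [task], ConstraintSet([]), cfg)
        np.testing.assert_allclose(A[2:], 2.0 * np.eye(2))
        np.testing.assert_allclose(b[2:], 0.0)
        # normal equations of the augmented system equal the ridge closed form
        sol, *_ = lstsq(A, b)
        closed = np.linalg.solve(np.eye(2) + 4.0 * np.eye(2), np.array([1.0, 2.0]))
        np.testing.assert_allclose(sol, closed, atol=1e-12)

    def test_fusion_row_encodes_weighted_difference(self):
        task = _single_response_task(np.eye(2), [1.0, 2.0], ["t1", "t2"])
        cs = ConstraintSet([FusionConstraint(("s1", "t1", "gene"), ("s1", "t2", "gene"))])
        cfg = SolverConfig(lambda_r=1.0, lambda_s=9.0)
        A, b, coefs = build_augmented_system({("s1", "gene")}, [task], cs, cfg)
        row = A[-1]
        assert sorted(row.tolist()) == [-3.0, 3.0]
        # expanding ||row . beta||^2 gives 9 (b_i - b_j)^2
        beta = np.array([0.7, -0.2])
        assert (row @ beta) ** 2 == pytest.approx(9.0 * (0.7 + 0.2) ** 2)

    def test_no_penalties_reduces_to_least_squares(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(6, 2)), rng.normal(size=6)
        task = _single_response_task(X, y, ["t1", "t2"])
        cfg = SolverConfig(lambda_r=0.0, lambda_s=0.0)
        A, b, _ = build_augmented_system({("s1", "gene")}, [task], ConstraintSet([]), cfg)
        sol, *_ = lstsq(A, b)
        ols, *_ = lstsq(X, y)
        np.testing.assert_allclose(sol, ols, atol=1e-12)


class TestDirectSolver:
    def test_ridge_closed_form_identity_design(self):
        task = _single_response_task(np.eye(2), [1.0, 2.0], ["t1", "t2"])
        net = solve_fused_direct([task], ConstraintSet([]), SolverConfig(lambda_r=1.0))
        np.testing.assert_allclose(net.betas["s1"]["gene"].to_numpy(), [0.5, 1.0], atol=1e-12)

    def test_large_lambda_s_pools_sources(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 4))
        tfs, genes = ["t1", "t2", "t3"], ["gA", "gB", "gC", "gD"]
        tasks = [RegressionTask(s, X, Y, 0.1, tfs, genes) for s in ("s1", "s2")]
        cons = [FusionConstraint(("s1", t, g), ("s2", t, g)) for t in tfs for g in genes]
        net = solve_fused_direct(tasks, ConstraintSet(cons), SolverConfig(lambda_r=1.0, lambda_s=1e8))
        # both networks equal the pooled fit: stacked data, ridge weight 2*lambda_r
        Ap = np.vstack([X, X, np.sqrt(2.0) * np.eye(3)])
        Bp = np.vstack([Y, Y, np.zeros((3, 4))])
        pooled, *_ = lstsq(Ap, Bp)
        for s in ("s1", "s2"):
            np.testing.assert_allclose(net.betas[s].to_numpy(), pooled, atol=1e-4)

    def test_exchangeable_predictors_fused_equal(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=6)
        X = np.column_stack([col, col])
        y = rng.normal(size=6)
        task = _single_response_task(X, y, ["t1", "t2"])
        cs = ConstraintSet([FusionConstraint(("s1", "t1", "gene"), ("s1", "t2", "gene"))])
        net = solve_fused_direct([task], cs, SolverConfig(lambda_r=1.0, lambda_s=1.0))
        b = net.betas["s1"]["gene"]
        assert b["t1"] == pytest.approx(b["t2"], abs=1e-12)

    def test_lambda_s_zero_is_independent_ridge(self, small_instance):
        tasks, cs = small_instance
        cfg = SolverConfig(lambda_r=2.0, lambda_s=0.0)
        with_cs = solve_fused_direct(tasks, cs, cfg)
        without = solve_fused_direct(tasks, ConstraintSet([]), cfg)
        assert with_cs.max_abs_diff(without) < 1e-10

    def test_singular_unregularized_system_reported(self):
        X = np.ones((2, 2))  # rank 1
        task = _single_response_task(X, [1.0, 2.0], ["t1", "t2"])
        with pytest.raises(np.linalg.LinAlgError, match="lambda_r"):
            solve_fused_direct([task], ConstraintSet([]), SolverConfig(lambda_r=0.0))

    def test_self_interactions_structurally_zero(self):
        rng = np.random.default_rng(5)
        tfs = ["t1", "t2"]
        genes = ["t1", "t2", "g1"]
        task = RegressionTask("s1", rng.normal(size=(6, 2)), rng.normal(size=(6, 3)), 0.1, tfs, genes)
        net = solve_fused_direct([task], ConstraintSet([]), SolverConfig(lambda_r=1.0))
        assert net.betas["s1"].at["t1", "t1"] == 0.0
        assert net.betas["s1"].at["t2", "t2"] == 0.0

    def test_component_independence(self, small_instance):
        """Solving components separately equals the joint vectorized solve."""
        tasks, cs = small_instance
        cfg = SolverConfig(lambda_r=1.0, lambda_s=2.0)
        componentwise = solve_fused_direct(tasks, cs, cfg)
        # joint solve: single augmented system over all responses at once
        all_responses = {(t.source_id, g) for t in tasks for g in t.gene_ids}
        A, b, coefs = build_augmented_system(all_responses, tasks, cs, cfg)
        sol, *_ = lstsq(A, b)
        joint = NetworkCoefficients.zeros(tasks)
        for coef, val in zip(coefs, sol):
            s, tf, gene = coef
            joint.betas[s].at[tf, gene] = val
        assert componentwise.max_abs_diff(joint) < 1e-9

    def test_prior_relax_shrinks_known_edges_less(self):
        rng = np.random.default_rng(6)
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 1))
        task = RegressionTask("s1", X, Y, 0.1, ["t1", "t2"], ["g1"])
        plain = solve_fused_direct([task], ConstraintSet([]), SolverConfig(lambda_r=10.0))
        relaxed = solve_fused_direct(
            [task],
            ConstraintSet([]),
            SolverConfig(lambda_r=10.0, prior_relax=0.1, prior_edges=frozenset({("s1", "t1", "g1")})),
        )
        assert abs(relaxed.betas["s1"].at["t1", "g1"]) > abs(plain.betas["s1"].at["t1", "g1"])


class TestIterativeSolver:
    def test_matches_direct_on_random_instance(self):
        tasks, cs = make_random_instance(seed=11)
        cfg = SolverConfig(lambda_r=1.0, lambda_s=2.0, tol=1e-10, max_iter=500)
        direct = solve_fused_direct(tasks, cs, cfg)
        iterative = solve_fused_iterative(tasks, cs, cfg, [2.0])[0]
        assert direct.max_abs_diff(iterative) < 1e-6

    def test_lambda_zero_converges_to_ridge_immediately(self, small_instance):
        tasks, cs = small_instance
        cfg = SolverConfig(lambda_r=1.0, lambda_s=0.0, tol=1e-8)
        it = solve_fused_iterative(tasks, cs, cfg, [0.0])[0]
        ridge = solve_fused_direct(tasks, ConstraintSet([]), cfg)
        assert it.max_abs_diff(ridge) < 1e-10
        assert it.n_iter <= 2  # one solving pass plus the convergence check

    def test_path_differences_nonincreasing_in_lambda_s(self):
        tasks, cs = make_random_instance(seed=12)
        grid = [0.0, 0.1, 1.0, 10.0]
        cfg = SolverConfig(lambda_r=1.0, tol=1e-9, max_iter=500)
        path = solve_fused_iterative(tasks, cs, cfg, grid)
        assert len(path) == 4

        def fusion_gap(net):
            return sum((net.get(c.left) - net.get(c.right)) ** 2 for c in cs)

        gaps = [fusion_gap(n) for n in path]
        assert all(b <= a + 1e-9 for a, b in zip(gaps, gaps[1:]))

    def test_nonconvergence_warns(self, small_instance):
        tasks, cs = small_instance
        cfg = SolverConfig(lambda_r=0.01, lambda_s=100.0, tol=1e-14, max_iter=2)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            nets = solve_fused_iterative(tasks, cs, cfg, [100.0])
        assert nets[0].converged is False


class TestObjective:
    def test_zero_network_gives_total_sum_of_squares(self, small_instance):
        tasks, cs = small_instance
        zero = NetworkCoefficients.zeros(tasks)
        cfg = SolverConfig(lambda_r=1.0, lambda_s=1.0)
        expected = sum(float(np.sum(t.Y**2)) for t in tasks)
        assert fused_objective(tasks, cs, cfg, zero) == pytest.approx(expected)

    def test_direct_solution_beats_random_perturbations(self, small_instance):
        tasks, cs = small_instance
        cfg = SolverConfig(lambda_r=1.0, lambda_s=1.0)
        net = solve_fused_direct(tasks, cs, cfg)
        base = fused_objective(tasks, cs, cfg, net)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            pert = net.copy()
            for s in pert.betas:
                b = pert.betas[s]
                noise = rng.normal(0, 0.01, size=b.shape)
                for j, tf in enumerate(b.index):  # keep structural zeros
                    for k, g in enumerate(b.columns):
                        if tf == g:
                            noise[j, k] = 0.0
                pert.betas[s] = b + noise
            assert fused_objective(tasks, cs, cfg, pert) >= base - 1e-9

    def test_equal_fused_coefficients_no_fusion_penalty(self):
        tasks, _ = make_random_instance(seed=13, n_constraints=0)
        cs = ConstraintSet([FusionConstraint(("s1", "t0", "g0"), ("s2", "t0", "g0"))])
        net = NetworkCoefficients.zeros(tasks)
        net.betas["s1"].at["t0", "g0"] = 1.5
        net.betas["s2"].at["t0", "g0"] = 1.5
        cfg = SolverConfig(lambda_r=0.0, lambda_s=100.0)
        no_fusion = fused_objective(tasks, ConstraintSet([]), cfg, net)
        assert fused_objective(tasks, cs, cfg, net) == pytest.approx(no_fusion)


class TestGaussianPriorEquivalence:
    def test_solution_is_posterior_mean(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(6, 2)), rng.normal(size=6)
        task = _single_response_task(X, y, ["t1", "t2"])
        cs = ConstraintSet([FusionConstraint(("s1", "t1", "gene"), ("s1", "t2", "gene"))])
        lam_r, lam_s = 1.0, 1.0
        net = solve_fused_direct([task], cs, SolverConfig(lambda_r=lam_r, lambda_s=lam_s))
        precision = lam_r * np.eye(2) + lam_s * np.array([[1.0, -1.0], [-1.0, 1.0]])
        posterior = np.linalg.solve(X.T @ X + precision, X.T @ y)
        np.testing.assert_allclose(net.betas["s1"]["gene"].to_numpy(), posterior, atol=1e-10)

    @pytest.mark.parametrize("lam_r,lam_s", [(1.0, 1.0), (2.0, 0.5), (0.3, 4.0)])
    def test_two_coefficient_prior_covariance_closed_form(self, lam_r, lam_s):
        precision = lam_r * np.eye(2) + lam_s * np.array([[1.0, -1.0], [-1.0, 1.0]])
        cov = np.linalg.inv(precision)
        denom = lam_r**2 + 2 * lam_r * lam_s
        assert cov[0, 0] == pytest.approx((lam_r + lam_s) / denom)
        assert cov[0, 1] == pytest.approx(lam_s / denom)
        if lam_r == lam_s == 1.0:
            assert cov[0, 0] == pytest.approx(2.0 / 3.0)
            assert cov[0, 1] == pytest.approx(1.0 / 3.0)
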
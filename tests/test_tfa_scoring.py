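"""TF activity estimation, confidence scoring, rank combination, PR evaluation."""

import numpy as np
import pandas as pd
import pytest

from fusenet.constraints import ConstraintSet
from fusenet.data_model import ConditionMeta, ExpressionDataset, RegressionTask, standardize_predictors
from fusenet.scoring import ConfidenceMatrix, confidence_scores, evaluate_pr, rank_combine
from fusenet.solver import NetworkCoefficients, SolverConfig, solve_fused_direct
from fusenet.tfa import PriorNetwork, estimate_tfa


def _dataset(values: np.ndarray, genes, tfs):
    df = pd.DataFrame(values, index=genes, columns=[f"c{i}" for i in range(values.shape[1])])
    return ExpressionDataset("s1", df, tfs, [ConditionMeta(c) for c in df.columns])


class TestEstimateTFA:
    def test_identity_prior_returns_tf_expression(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.normal(size=(4, 6)), ["t1", "t2", "g1", "g2"], ["t1", "t2"])
        prior = PriorNetwork([("t1", "t1", 1), ("t2", "t2", 1)], "s1")
        act = estimate_tfa(ds, prior)
        np.testing.assert_allclose(act.to_numpy(), ds.values.loc[["t1", "t2"]].to_numpy())

    def test_two_target_pseudoinverse(self):
        values = np.array([[9.0, 9.0], [2.0, 4.0], [4.0, 8.0]])
        ds = _dataset(values, ["t1", "g1", "g2"], ["t1"])
        act = estimate_tfa(ds, PriorNetwork([("t1", "g1", 1), ("t1", "g2", 1)], "s1"))
        expected = np.linalg.pinv(np.array([[1.0], [1.0]])) @ values[1:]
        np.testing.assert_allclose(act.loc["t1"].to_numpy(), expected[0])

    def test_tf_without_prior_targets_keeps_expression(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(3, 4))
        ds = _dataset(vals, ["t1", "t2", "g1"], ["t1", "t2"])
        act = estimate_tfa(ds, PriorNetwork([("t1", "g1", 1)], "s1"))
        np.testing.assert_allclose(act.loc["t2"].to_numpy(), vals[1])

    def test_signs_enter_connectivity(self):
        # a repressed target contributes with flipped sign
        a = np.array([[1.0, -2.0, 0.5]])
        values = np.vstack([np.zeros((1, 3)), -3.0 * a])
        ds = _dataset(values, ["t1", "g1"], ["t1"])
        act = estimate_tfa(ds, PriorNetwork([("t1", "g1", -1)], "s1"))
        np.testing.assert_allclose(act.loc["t1"].to_numpy(), 3.0 * a[0])

    def test_unknown_ids_rejected(self):
        ds = _dataset(np.zeros((2, 3)), ["t1", "g1"], ["t1"])
        with pytest.raises(ValueError, match="zz"):
            estimate_tfa(ds, PriorNetwork([("t1", "zz", 1)], "s1"))


class TestConfidenceScores:
    def _fitted(self, seed=0, n=12, p=3, m=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        B = rng.normal(size=(p, m))
        Y = X @ B + rng.normal(0, 0.3, size=(n, m))
        task = standardize_predictors(
            RegressionTask("s1", X, Y, 0.1, [f"t{i}" for i in range(p)], [f"g{i}" for i in range(m)])
        )
        net = solve_fused_direct([task], ConstraintSet([]), SolverConfig(lambda_r=0.5))
        return task, net

    def test_zero_beta_scores_one(self):
        task, net = self._fitted()
        net.betas["s1"].loc["t0", "g0"] = 0.0
        cm = confidence_scores(task, net)
        assert cm.S.at["t0", "g0"] == pytest.approx(1.0)

    def test_hand_value_half(self):
        # sigma2 = 1, beta = 1, var(TF) = 1 -> S = 0.5
        X = np.array([[1.0], [-1.0]])  # var (ddof=1) = 2... construct exactly unit variance
        X = np.array([[np.sqrt(0.5)], [-np.sqrt(0.5)]])
        beta = 1.0
        # residuals with mean square exactly 1
        y = X[:, 0] * beta + np.array([1.0, -1.0])
        task = RegressionTask("s1", X, y[:, None], 0.1, ["t1"], ["g1"])
        net = NetworkCoefficients.zeros([task])
        net.betas["s1"].at["t1", "g1"] = beta
        cm = confidence_scores(task, net)
        assert cm.S.at["t1", "g1"] == pytest.approx(0.5)

    def test_scores_strictly_decrease_in_abs_beta(self):
        task, net = self._fitted()
        values = [0.1, 0.5, 1.0, 2.0]
        scores = []
        for b in values:
            net.betas["s1"].loc["t0", "g0"] = b
            cm = confidence_scores(task, net)
            scores.append(cm.S.at["t0", "g0"])
        assert all(s2 < s1 for s1, s2 in zip(scores, scores[1:]))

    def test_permutation_equivariance(self):
        task, net = self._fitted(seed=4)
        cm = confidence_scores(task, net)
        perm = [2, 0, 3, 1]
        genes_p = [task.gene_ids[i] for i in perm]
        import dataclasses

        task_p = dataclasses.replace(task, Y=task.Y[:, perm], gene_ids=genes_p)
        net_p = NetworkCoefficients({"s1": net.betas["s1"][genes_p]})
        cm_p = confidence_scores(task_p, net_p)
        np.testing.assert_allclose(cm_p.S.to_numpy(), cm.S[genes_p].to_numpy())

    def test_full_refit_variant_ranks_informative_predictor_high(self):
        task, net = self._fitted(seed=5)
        cm = confidence_scores(task, net, variant="full_refit", cfg=SolverConfig(lambda_r=0.5))
        assert ((cm.S.to_numpy() > 0) & (cm.S.to_numpy() <= 1.0)).all()


class TestRankCombine:
    def _cm(self, row):
        return ConfidenceMatrix(pd.DataFrame([row], index=["t1"], columns=["a", "b", "c"]))

    def test_identical_rankings_preserved(self):
        cm = self._cm([0.1, 0.2, 0.3])
        out = rank_combine([cm, cm, cm])
        assert list(out["gene"]) == ["a", "b", "c"]
        assert list(out["mean_rank"]) == [1.0, 2.0, 3.0]

    def test_opposed_rankings_fully_tie(self):
        out = rank_combine([self._cm([0.1, 0.2, 0.3]), self._cm([0.3, 0.2, 0.1])])
        assert set(out["mean_rank"]) == {2.0}

    def test_mean_rank_arithmetic(self):
        out = rank_combine([self._cm([0.1, 0.2, 0.3]), self._cm([0.2, 0.1, 0.3])])
        by_gene = dict(zip(out["gene"], out["mean_rank"]))
        assert by_gene == {"a": 1.5, "b": 1.5, "c": 3.0}

    def test_mismatched_edge_sets_rejected(self):
        other = ConfidenceMatrix(pd.DataFrame([[0.1]], index=["t1"], columns=["zz"]))
        with pytest.raises(ValueError):
            rank_combine([self._cm([0.1, 0.2, 0.3]), other])


class TestEvaluatePR:
    def test_perfect_ranking_gives_aupr_one(self):
        uni = [("t", "e1"), ("t", "e2"), ("t", "e3"), ("t", "e4")]
        gold = PriorNetwork([("t", "e1", 1), ("t", "e2", 1)])
        res = evaluate_pr(uni, gold, uni)
        assert res.aupr == pytest.approx(1.0)

    def test_hand_computed_example(self):
        uni = [("t", "e1"), ("t", "e2"), ("t", "e3"), ("t", "e4")]
        gold = PriorNetwork([("t", "e1", 1), ("t", "e3", 1)])
        res = evaluate_pr(uni, gold, uni)
        # precision 1.0 at recall 0.5, 2/3 at recall 1.0 -> AUPR 5/6 (step convention)
        assert res.aupr == pytest.approx(5.0 / 6.0)

    def test_random_ranking_aupr_near_positive_rate(self):
        rng = np.random.default_rng(0)
        n, pos_rate = 1000, 0.1
        uni = [("t", f"e{i}") for i in range(n)]
        golds = rng.random(n) < pos_rate
        gold = PriorNetwork([("t", f"e{i}", 1) for i in range(n) if golds[i]])
        auprs = []
        for _ in range(100):
            order = rng.permutation(n)
            auprs.append(evaluate_pr([uni[i] for i in order], gold, uni).aupr)
        assert np.mean(auprs) == pytest.approx(golds.mean(), abs=0.02)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError, match="empty gold"):
            evaluate_pr([("t", "e1")], PriorNetwork([]), [("t", "e1")])

    def test_gold_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            evaluate_pr([("t", "e1")], PriorNetwork([("t", "zz", 1)]), [("t", "e1")])

    def test_aupr_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(1)
        S = pd.DataFrame(rng.uniform(0.01, 1.0, size=(2, 5)), index=["t1", "t2"], columns=list("abcde"))
        cm1 = ConfidenceMatrix(S)
        cm2 = ConfidenceMatrix(S**3)  # strictly monotone transform
        uni = [(tf, g) for tf in S.index for g in S.columns]
        gold = PriorNetwork([("t1", "a", 1), ("t2", "c", 1)])
        r1 = evaluate_pr(cm1.ranking(uni), gold, uni)
        r2 = evaluate_pr(cm2.ranking(uni), gold, uni)
        assert r1.aupr == pytest.approx(r2.aupr)
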
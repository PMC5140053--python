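"""Hyperparameter selection by cross-validation and workflow orchestration.

The two penalty weights are chosen sequentially rather than on a joint grid:
lambda_R is selected first with lambda_S = 0 (plain ridge path, CV on
held-out prediction error), then lambda_S is selected along the iterative
solver's warm-started path with lambda_R fixed. Neither selection consults
the gold standard, which is reserved for evaluating network quality.

`run_workflow` ties every stage together: load inputs, build dynamics
regression tasks (optionally with estimated TF activities as predictors),
generate fusion constraints, split the gold standard into a prior half and an
evaluation half, select penalties per fold, fit fused and independent
networks, score, and average precision-recall across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .adaptive import SaturatingPenalty, select_a, solve_adaptive
from .constraints import ConstraintSet, constraints_from_operons, constraints_from_orthology
from .data_model import RegressionTask, build_response_design, standardize_predictors
from .io import RunConfig, read_inputs
from .scoring import confidence_scores, evaluate_pr
from .solver import NetworkCoefficients, SolverConfig, solve_fused_direct, solve_fused_iterative
from .tfa import PriorNetwork, estimate_tfa

__all__ = [
    "CVPlan",
    "select_lambda_r",
    "select_lambda_s",
    "default_lambda_r_grid",
    "DEFAULT_LAMBDA_S_GRID",
    "WorkflowResult",
    "run_workflow",
]

#: default fusion-weight path; includes the lambda_S = 1.0 operating point
DEFAULT_LAMBDA_S_GRID = (0.0, 0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class CVPlan:
    """Seeded assignment of regression rows to cross-validation folds."""

    n_folds: int
    row_assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.row_assignments = np.asarray(self.row_assignments)
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        counts = np.bincount(self.row_assignments, minlength=self.n_folds)
        if len(counts) > self.n_folds or (counts == 0).any():
            raise ValueError("every fold must be non-empty")

    @classmethod
    def random(cls, n_rows: int, n_folds: int, seed: int) -> "CVPlan":
        if n_rows < n_folds:
            raise ValueError(f"cannot split {n_rows} rows into {n_folds} folds")
        rng = np.random.default_rng(seed)
        assign = np.repeat(np.arange(n_folds), int(np.ceil(n_rows / n_folds)))[:n_rows]
        rng.shuffle(assign)
        return cls(n_folds, assign, seed)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.row_assignments == fold
        return ~test, test


def _subtask(task: RegressionTask, rows: np.ndarray) -> RegressionTask:
    return replace(task, X=task.X[rows], Y=task.Y[rows])


def _heldout_mse(task_test: RegressionTask, networks: NetworkCoefficients) -> float:
    B = networks.betas[task_test.source_id].loc[task_test.tf_ids, task_test.gene_ids].to_numpy()
    return float(np.mean((task_test.X @ B - task_test.Y) ** 2))


def default_lambda_r_grid(task: RegressionTask, n: int = 20) -> list[float]:
    """Descending log-spaced ridge path spanning 1e-3 * lambda_max to lambda_max."""
    lam_max = float(np.max(np.abs(task.X.T @ task.Y)))
    lam_max = max(lam_max, 1e-6)
    return list(np.geomspace(lam_max, 1e-3 * lam_max, n))


def select_lambda_r(task: RegressionTask, plan: CVPlan, grid: list[float]) -> float:
    """Ridge weight minimizing mean held-out squared prediction error.

    The grid is a descending regularization path; lambda_S is fixed at 0, so
    each response is an independent ridge problem. Ties in CV error break
    toward the larger penalty.
    """
    if not grid:
        raise ValueError("empty lambda_r grid")
    if len(task.X) != len(plan.row_assignments):
        raise ValueError("CV plan does not match the task's rows")
    if any(b > a for a, b in zip(grid, grid[1:])):
        raise ValueError("lambda_r grid must be sorted descending")
    errs = np.zeros(len(grid))
    empty = ConstraintSet([])
    for fold in range(plan.n_folds):
        train, test = plan.split(fold)
        sub, sub_test = _subtask(task, train), _subtask(task, test)
        for i, lam in enumerate(grid):
            net = solve_fused_direct([sub], empty, SolverConfig(lambda_r=lam))
            errs[i] += _heldout_mse(sub_test, net)
    errs /= plan.n_folds
    # scan ascending in penalty so equal errors resolve to more regularization
    best_lam, best_err = grid[-1], np.inf
    for lam, err in sorted(zip(grid, errs)):
        if err <= best_err:
            best_lam, best_err = lam, err
    return best_lam


def select_lambda_s(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    plans: dict[str, CVPlan],
    lambda_r: float,
    grid: list[float] = list(DEFAULT_LAMBDA_S_GRID),
    solver_cfg: SolverConfig | None = None,
) -> float:
    """Fusion weight minimizing mean held-out error along the warm-started path.

    With lambda_R fixed from :func:`select_lambda_r`, the iterative solver
    computes the ascending lambda_S path on each fold's training rows and the
    held-out error is averaged over sources and folds. Ties break toward the
    larger penalty.
    """
    if not grid:
        raise ValueError("empty lambda_s grid")
    if len(cs) == 0:
        warnings.warn("no fusion constraints: lambda_s has no effect; returning grid minimum")
        return min(grid)
    base = solver_cfg or SolverConfig()
    # held-out error comparisons are insensitive below ~1e-4, and the Jacobi
    # rate degrades at large lambda_s, so the path is run looser but longer
    cfg = replace(
        base,
        lambda_r=lambda_r,
        lambda_s=0.0,
        tol=max(1e-4, base.tol),
        max_iter=max(300, base.max_iter),
    )
    n_folds = next(iter(plans.values())).n_folds
    errs = np.zeros(len(grid))
    for fold in range(n_folds):
        train_tasks, test_tasks = [], []
        for t in tasks:
            train, test = plans[t.source_id].split(fold)
            train_tasks.append(_subtask(t, train))
            test_tasks.append(_subtask(t, test))
        path = solve_fused_iterative(train_tasks, cs, cfg, grid)
        for i, net in enumerate(path):
            errs[i] += float(np.mean([_heldout_mse(tt, net) for tt in test_tasks]))
    errs /= n_folds
    best_lam, best_err = max(grid), np.inf
    for lam, err in sorted(zip(grid, errs)):
        if err <= best_err:
            best_lam, best_err = lam, err
    return best_lam


@dataclass
class WorkflowResult:
    """Everything run_workflow produces: networks, rankings, curves, bookkeeping."""

    networks: NetworkCoefficients
    ranked_edges: pd.DataFrame
    pr_curve: pd.DataFrame | None
    roc_curve: pd.DataFrame | None
    unfused: pd.DataFrame | None
    per_fold: list[dict]
    aupr_fused: float
    aupr_independent: float
    manifest: dict


def _merge_constraint_sets(sets: list[ConstraintSet]) -> ConstraintSet:
    all_constraints = [c for s in sets for c in s]
    truth = {}
    for s in sets:
        truth.update(s.truth)
    return ConstraintSet(all_constraints, truth=truth)


def run_workflow(cfg: RunConfig, inputs=None) -> WorkflowResult:
    """End-to-end fused network inference.

    Stages: load and validate inputs; split each source's gold standard into
    a prior half (TFA estimation, relaxed ridge on known edges) and an
    evaluation half; build and standardize the dynamics regression tasks;
    generate orthology and operon fusion constraints; select lambda_R by CV on
    the primary (first) source; optionally set the adaptive saturation point
    from independent-fit differences; then per fold select lambda_S on the
    training rows, fit fused (or adaptive) and independent networks, rank
    edges by confidence, and evaluate precision-recall against the held-out
    gold half. A final fused fit on all rows produces the reported network.
    """
    datasets, orth, priors, operons = inputs if inputs is not None else read_inputs(cfg)
    if cfg.folds < 2:
        raise ValueError("folds must be >= 2")
    source_ids = [sf.source_id for sf in cfg.sources] if cfg.sources else sorted(datasets)
    primary = source_ids[0]
    if primary not in priors:
        raise ValueError(f"primary source {primary!r} needs a gold-standard file for evaluation")

    prior_half: dict[str, PriorNetwork] = {}
    eval_half: dict[str, PriorNetwork] = {}
    for s, p in priors.items():
        prior_half[s], eval_half[s] = p.split(cfg.seed)

    tasks: list[RegressionTask] = []
    for s in source_ids:
        ds = datasets[s]
        predictors = None
        if cfg.use_tfa:
            predictors = estimate_tfa(ds, prior_half.get(s, PriorNetwork([], s)))
        task = build_response_design(
            ds, cfg.alpha, allow_zero_alpha=cfg.allow_zero_alpha, predictors=predictors
        )
        tasks.append(standardize_predictors(task))
    by_source = {t.source_id: t for t in tasks}

    cs_parts = []
    if len(orth) > 0:
        cs_parts.append(constraints_from_orthology(tasks, orth))
    for s, ops in operons.items():
        cs_parts.append(constraints_from_operons(by_source[s], ops))
    cs = _merge_constraint_sets(cs_parts) if cs_parts else ConstraintSet([])

    prior_edges = frozenset(
        (s, tf, gene) for s, p in prior_half.items() for tf, gene, _ in p.edges
    )
    base_cfg = SolverConfig(
        prior_relax=cfg.prior_relax,
        prior_edges=prior_edges,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )

    primary_task = by_source[primary]
    plan = CVPlan.random(primary_task.n_rows, cfg.folds, cfg.seed)
    plans = {
        t.source_id: (
            plan
            if t.source_id == primary
            else CVPlan.random(t.n_rows, cfg.folds, cfg.seed + 1 + source_ids.index(t.source_id))
        )
        for t in tasks
    }

    lambda_r = cfg.lambda_r
    if lambda_r is None:
        lambda_r = select_lambda_r(primary_task, plan, default_lambda_r_grid(primary_task))
    base_cfg = replace(base_cfg, lambda_r=lambda_r)

    pen = None
    if cfg.adaptive:
        indep_full = solve_fused_direct(tasks, ConstraintSet([]), base_cfg)
        if len(cs) == 0:
            raise ValueError("adaptive fusion requires fusion constraints")
        a = select_a(indep_full, cs, cfg.a_percentile)
        a = max(a, 1e-9)  # degenerate all-equal differences
        lam_base = 2.0 * (cfg.lambda_s if cfg.lambda_s is not None else 1.0)
        pen = SaturatingPenalty(lam=lam_base, a=a)

    universe = [
        (tf, g)
        for tf in primary_task.tf_ids
        for g in primary_task.gene_ids
        if tf != g and (tf, g) not in prior_half[primary].unsigned_edges()
    ]
    gold_eval = eval_half[primary]

    per_fold: list[dict] = []
    recall_grid = np.linspace(0, 1, 101)
    prec_fused, prec_indep = [], []
    unfused_records: list[dict] = []
    for fold in range(cfg.folds):
        train_tasks = []
        for t in tasks:
            train, _ = plans[t.source_id].split(fold)
            train_tasks.append(_subtask(t, train))
        train_by_source = {t.source_id: t for t in train_tasks}

        lam_s = cfg.lambda_s
        if lam_s is None and len(cs) > 0:
            inner_plans = {
                t.source_id: CVPlan.random(t.n_rows, 2, cfg.seed + 1000 + fold) for t in train_tasks
            }
            lam_s = select_lambda_s(
                train_tasks, cs, inner_plans, lambda_r, list(DEFAULT_LAMBDA_S_GRID), base_cfg
            )
        elif lam_s is None:
            lam_s = 0.0

        fused_cfg = replace(base_cfg, lambda_s=lam_s)
        if cfg.adaptive and pen is not None:
            fold_pen = SaturatingPenalty(lam=2.0 * lam_s if lam_s > 0 else pen.lam, a=pen.a)
            ares = solve_adaptive(train_tasks, cs, fused_cfg, fold_pen)
            fused_net = ares.networks
            for c, theta, w in zip(cs, ares.thetas, ares.constraint_weights):
                if w == 0.0:
                    unfused_records.append(
                        {"fold": fold, "left": "|".join(c.left), "right": "|".join(c.right), "final_theta": theta}
                    )
        elif cfg.solver == "iterative":
            fused_net = solve_fused_iterative(train_tasks, cs, fused_cfg, [lam_s])[-1]
        else:
            fused_net = solve_fused_direct(train_tasks, cs, fused_cfg)
        indep_net = solve_fused_direct(train_tasks, ConstraintSet([]), replace(base_cfg, lambda_s=0.0))

        cm_fused = confidence_scores(train_by_source[primary], fused_net)
        cm_indep = confidence_scores(train_by_source[primary], indep_net)
        res_fused = evaluate_pr(cm_fused.ranking(universe), gold_eval, universe)
        res_indep = evaluate_pr(cm_indep.ranking(universe), gold_eval, universe)
        prec_fused.append(np.interp(recall_grid, res_fused.recall, res_fused.precision))
        prec_indep.append(np.interp(recall_grid, res_indep.recall, res_indep.precision))
        per_fold.append(
            {
                "fold": fold,
                "lambda_r": lambda_r,
                "lambda_s": lam_s,
                "aupr_fused": res_fused.aupr,
                "aupr_independent": res_indep.aupr,
                "auroc_fused": res_fused.auroc,
                "auroc_independent": res_indep.auroc,
            }
        )

    lam_s_final = float(np.median([f["lambda_s"] for f in per_fold])) if per_fold else 0.0
    final_cfg = replace(base_cfg, lambda_s=lam_s_final)
    if cfg.adaptive and pen is not None:
        final = solve_adaptive(tasks, cs, final_cfg, SaturatingPenalty(2.0 * lam_s_final or pen.lam, pen.a))
        final_net = final.networks
    else:
        final_net = solve_fused_direct(tasks, cs, final_cfg)
    cm_final = confidence_scores(by_source[primary], final_net)
    ranked = pd.DataFrame(
        [
            {
                "tf": tf,
                "gene": g,
                "beta": float(final_net.betas[primary].at[tf, g]),
                "S": float(cm_final.S.at[tf, g]),
                "confidence": 1.0 - float(cm_final.S.at[tf, g]),
            }
            for tf, g in cm_final.ranking(universe)
        ]
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)

    pr_curve = pd.DataFrame(
        {
            "recall": recall_grid,
            "precision_fused": np.mean(prec_fused, axis=0),
            "precision_independent": np.mean(prec_indep, axis=0),
        }
    )
    unfused_df = pd.DataFrame(unfused_records) if cfg.adaptive else None

    manifest = {
        "seed": cfg.seed,
        "folds": cfg.folds,
        "lambda_r": float(lambda_r),
        "lambda_s_per_fold": [float(f["lambda_s"]) for f in per_fold],
        "lambda_s_final": lam_s_final,
        "use_tfa": cfg.use_tfa,
        "adaptive": cfg.adaptive,
        "a_percentile": cfg.a_percentile if cfg.adaptive else None,
        "n_constraints": len(cs),
        "aupr_fused_mean": float(np.mean([f["aupr_fused"] for f in per_fold])),
        "aupr_independent_mean": float(np.mean([f["aupr_independent"] for f in per_fold])),
    }
    return WorkflowResult(
        networks=final_net,
        ranked_edges=ranked,
        pr_curve=pr_curve,
        roc_curve=None,
        unfused=unfused_df,
        per_fold=per_fold,
        aupr_fused=manifest["aupr_fused_mean"],
        aupr_independent=manifest["aupr_independent_mean"],
        manifest=manifest,
    )
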
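"""Fused L2 ridge regression solvers.

The objective, over sources s with standardized design X_s and dynamics
response Y_s, is

    sum_s ||X_s B_s - Y_s||^2 + lambda_R ||B_s||^2
        + lambda_S sum_c w_c (beta[c.left] - beta[c.right])^2

a convex quadratic whose minimizer is found two ways:

* **direct** — each connected component of the constraint graph is vectorized
  into one augmented least-squares system (ridge rows sqrt(lambda_R) * I,
  fusion rows +sqrt(lambda_S w) / -sqrt(lambda_S w)) and solved by a stable
  least-squares factorization;
* **iterative** — Jacobi-style passes where each response's ridge problem is
  solved with quadratic pulls toward the previous iterate's fused partners,
  warm-started along an ascending lambda_S grid.

Self-regulation (TF j on gene j) is structurally excluded: TF j is dropped
from gene j's predictor set, and the corresponding entries of B are zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, lstsq

from .constraints import Coefficient, ConstraintSet, Response, constraint_components
from .data_model import RegressionTask

__all__ = [
    "NetworkCoefficients",
    "SolverConfig",
    "build_augmented_system",
    "solve_fused_direct",
    "solve_fused_iterative",
    "fused_objective",
]


@dataclass
class NetworkCoefficients:
    """Per-source TF x gene weight matrices: the inferred regulatory networks."""

    betas: dict[str, pd.DataFrame]
    converged: bool = True
    n_iter: int = 0

    def get(self, coef: Coefficient) -> float:
        s, tf, gene = coef
        return float(self.betas[s].at[tf, gene])

    def copy(self) -> "NetworkCoefficients":
        return NetworkCoefficients({s: b.copy() for s, b in self.betas.items()}, self.converged, self.n_iter)

    def max_abs_diff(self, other: "NetworkCoefficients") -> float:
        return max(
            float(np.max(np.abs(self.betas[s].to_numpy() - other.betas[s].to_numpy())))
            for s in self.betas
        )

    def to_original_scale(self, tasks: list[RegressionTask]) -> "NetworkCoefficients":
        """Map coefficients from the standardized-predictor scale back to raw units."""
        out = {}
        for t in tasks:
            b = self.betas[t.source_id].copy()
            if t.x_sds is not None:
                b = b.div(pd.Series(t.x_sds, index=t.tf_ids), axis=0)
            out[t.source_id] = b
        return NetworkCoefficients(out, self.converged, self.n_iter)

    @staticmethod
    def zeros(tasks: list[RegressionTask]) -> "NetworkCoefficients":
        return NetworkCoefficients(
            {
                t.source_id: pd.DataFrame(
                    np.zeros((len(t.tf_ids), len(t.gene_ids))), index=t.tf_ids, columns=t.gene_ids
                )
                for t in tasks
            }
        )


@dataclass
class SolverConfig:
    """Hyperparameters of the fused ridge objective and solver tolerances.

    ``prior_relax`` multiplies lambda_R for coefficients listed in
    ``prior_edges`` (known interactions are penalized less); ``tol`` is the
    convergence tolerance on the maximum absolute coefficient change between
    iterations; components whose vectorized system would exceed
    ``direct_size_threshold`` coefficients are routed to the iterative solver.
    """

    lambda_r: float = 1.0
    lambda_s: float = 0.0
    prior_relax: float = 0.1
    prior_edges: frozenset[Coefficient] = field(default_factory=frozenset)
    max_iter: int = 50
    tol: float = 1e-6
    direct_size_threshold: int = 5000

    def __post_init__(self) -> None:
        if self.lambda_r < 0 or self.lambda_s < 0:
            raise ValueError("penalty weights must be >= 0")
        if not (0 < self.prior_relax <= 1):
            raise ValueError("prior_relax must be in (0, 1]")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        self.prior_edges = frozenset(self.prior_edges)

    def ridge_for(self, coef: Coefficient) -> float:
        k = self.prior_relax if coef in self.prior_edges else 1.0
        return self.lambda_r * k


def _predictor_indices(task: RegressionTask, gene: str) -> list[int]:
    """TF column indices regulating `gene`, excluding self-regulation."""
    return [j for j, tf in enumerate(task.tf_ids) if tf != gene]


def build_augmented_system(
    component: set[Response],
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
) -> tuple[np.ndarray, np.ndarray, list[Coefficient]]:
    """Vectorize one constraint component into an augmented least-squares system.

    Stacks, for each response (source, gene) in the component: its source's
    design block (diagonal concatenation), then ridge rows
    sqrt(lambda_R * kappa) * I, then one row per internal fusion constraint
    with +sqrt(lambda_S w) and -sqrt(lambda_S w) at the fused coefficient
    columns. The response vector concatenates the Y columns and pads zeros for
    all penalty rows. Returns (A, b, coefficient order of the columns).
    """
    by_source = {t.source_id: t for t in tasks}
    responses = sorted(component)
    coefs: list[Coefficient] = []
    col_of: dict[Coefficient, int] = {}
    for s, gene in responses:
        task = by_source[s]
        for j in _predictor_indices(task, gene):
            coef = (s, task.tf_ids[j], gene)
            col_of[coef] = len(coefs)
            coefs.append(coef)

    n_cols = len(coefs)
    internal = [
        c
        for r in responses
        for c in cs.for_response(r)
        if c.responses[0] in component or c.responses[1] in component
    ]
    # deduplicate while keeping order (a constraint indexes under both responses)
    seen = set()
    constraints = []
    for c in internal:
        key = (c.left, c.right)
        if key not in seen:
            seen.add(key)
            constraints.append(c)

    n_data = sum(by_source[s].n_rows for s, _ in responses)
    A = np.zeros((n_data + n_cols + len(constraints), n_cols))
    b = np.zeros(A.shape[0])

    row = 0
    col = 0
    for s, gene in responses:
        task = by_source[s]
        idx = _predictor_indices(task, gene)
        n, p = task.n_rows, len(idx)
        A[row : row + n, col : col + p] = task.X[:, idx]
        b[row : row + n] = task.Y[:, task.gene_index(gene)]
        row += n
        col += p

    for j, coef in enumerate(coefs):
        A[row + j, j] = np.sqrt(cfg.ridge_for(coef))
    row += n_cols

    for k, c in enumerate(constraints):
        for coef in (c.left, c.right):
            if coef not in col_of:
                raise RuntimeError(f"constraint endpoint {coef} outside component (decomposition bug)")
        scale = np.sqrt(cfg.lambda_s * c.weight)
        A[row + k, col_of[c.left]] = scale
        A[row + k, col_of[c.right]] = -scale

    return A, b, coefs


def _solve_batch_unconstrained(
    task: RegressionTask, genes: list[str], cfg: SolverConfig, out: NetworkCoefficients
) -> None:
    """Ridge-solve unconstrained, prior-free responses sharing a predictor set in one factorization."""
    by_mask: dict[tuple[int, ...], list[str]] = {}
    for g in genes:
        by_mask.setdefault(tuple(_predictor_indices(task, g)), []).append(g)
    sqrt_lr = np.sqrt(cfg.lambda_r)
    for idx, group in by_mask.items():
        idx = list(idx)
        p = len(idx)
        A = np.vstack([task.X[:, idx], sqrt_lr * np.eye(p)])
        if cfg.lambda_r == 0 and np.linalg.matrix_rank(task.X[:, idx]) < p:
            raise np.linalg.LinAlgError(
                "singular unregularized system; set lambda_r > 0 to regularize"
            )
        B = np.zeros((A.shape[0], len(group)))
        cols = [task.gene_index(g) for g in group]
        B[: task.n_rows] = task.Y[:, cols]
        sol, *_ = lstsq(A, B)
        beta = out.betas[task.source_id]
        for col_j, g in enumerate(group):
            beta.loc[[task.tf_ids[j] for j in idx], g] = sol[:, col_j]


def solve_fused_direct(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
) -> NetworkCoefficients:
    """Exact componentwise minimizer of the fused ridge objective.

    Each constraint component is solved as one augmented least-squares system.
    Unconstrained responses without relaxed-prior coefficients are batched per
    predictor set for speed. Oversized components (see
    ``cfg.direct_size_threshold``) fall back to the iterative solver.
    """
    by_source = {t.source_id: t for t in tasks}
    out = NetworkCoefficients.zeros(tasks)
    components = constraint_components(cs, tasks)

    prior_responses = {(s, g) for (s, _, g) in cfg.prior_edges}
    plain: dict[str, list[str]] = {t.source_id: [] for t in tasks}
    oversized: list[set[Response]] = []
    for comp in components:
        if len(comp) == 1:
            (s, gene) = next(iter(comp))
            if not cs.for_response((s, gene)) and (s, gene) not in prior_responses:
                plain[s].append(gene)
                continue
        n_coefs = sum(len(_predictor_indices(by_source[s], g)) for s, g in comp)
        if n_coefs > cfg.direct_size_threshold:
            oversized.append(comp)
            continue
        A, b, coefs = build_augmented_system(comp, tasks, cs, cfg)
        if cfg.lambda_r == 0 and np.linalg.matrix_rank(A) < A.shape[1]:
            raise np.linalg.LinAlgError(
                "singular fused system with lambda_r = 0; set lambda_r > 0 to regularize"
            )
        sol, *_ = lstsq(A, b)
        for coef, val in zip(coefs, sol):
            s, tf, gene = coef
            out.betas[s].at[tf, gene] = val

    for t in tasks:
        if plain[t.source_id]:
            _solve_batch_unconstrained(t, plain[t.source_id], cfg, out)

    if oversized:
        sub = _iterative_fixed_lambda(tasks, cs, cfg, restrict=set().union(*oversized), init=out)
        for s in sub.betas:
            mask_genes = {g for (src, g) in set().union(*oversized) if src == s}
            for g in mask_genes:
                out.betas[s][g] = sub.betas[s][g]
        out.converged = sub.converged
    return out


class _ResponseSystem:
    """Prefactored per-response normal equations for the iterative solver."""

    def __init__(self, task: RegressionTask, gene: str, cs: ConstraintSet, cfg: SolverConfig):
        self.source = task.source_id
        self.gene = gene
        self.idx = _predictor_indices(task, gene)
        self.tf_ids = [task.tf_ids[j] for j in self.idx]
        X = task.X[:, self.idx]
        y = task.Y[:, task.gene_index(gene)]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.ridge = np.array([cfg.ridge_for((self.source, tf, gene)) for tf in self.tf_ids])
        # constraints touching this response, as (local column, partner coef, weight, internal partner col)
        self.pulls: list[tuple[int, Coefficient, float]] = []
        pos = {tf: j for j, tf in enumerate(self.tf_ids)}
        for c in cs.for_response((self.source, gene)):
            for here, there in ((c.left, c.right), (c.right, c.left)):
                if here[0] == self.source and here[2] == gene and here[1] in pos:
                    self.pulls.append((pos[here[1]], there, c.weight))

    def factor(self, lambda_s: float):
        A = self.XtX + np.diag(self.ridge)
        for j, _, w in self.pulls:
            A[j, j] += lambda_s * w
        self._cho = cho_factor(A)

    def solve(self, lambda_s: float, current: NetworkCoefficients) -> np.ndarray:
        rhs = self.Xty.copy()
        for j, partner, w in self.pulls:
            rhs[j] += lambda_s * w * current.get(partner)
        return cho_solve(self._cho, rhs)


def solve_fused_iterative(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
    lambda_s_grid: list[float],
) -> list[NetworkCoefficients]:
    """Solution path over an ascending lambda_S grid via Jacobi fixed-point passes.

    Each pass re-solves every response's ridge problem with quadratic pulls
    toward the previous iterate's fused partner values; the fixed point is the
    global minimizer of the convex fused objective. Each grid value is
    warm-started from the previous solution.
    """
    grid = list(lambda_s_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("lambda_s_grid must be sorted ascending")
    systems = [
        _ResponseSystem(t, gene, cs, cfg) for t in tasks for gene in t.gene_ids
    ]
    current = NetworkCoefficients.zeros(tasks)
    path: list[NetworkCoefficients] = []
    for lam_s in grid:
        for sys_ in systems:
            sys_.factor(lam_s)
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            nxt = current.copy()
            for sys_ in systems:
                sol = sys_.solve(lam_s, current)
                nxt.betas[sys_.source].loc[sys_.tf_ids, sys_.gene] = sol
            delta = nxt.max_abs_diff(current)
            current = nxt
            if delta < cfg.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"iterative fused solver did not converge at lambda_s={lam_s} "
                f"after {cfg.max_iter} iterations",
                RuntimeWarning,
            )
        snap = current.copy()
        snap.converged = converged
        snap.n_iter = it
        path.append(snap)
    return path


def _iterative_fixed_lambda(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
    restrict: set[Response] | None = None,
    init: NetworkCoefficients | None = None,
) -> NetworkCoefficients:
    """Single-lambda iterative solve, optionally restricted to a set of responses."""
    systems = [
        _ResponseSystem(t, gene, cs, cfg)
        for t in tasks
        for gene in t.gene_ids
        if restrict is None or (t.source_id, gene) in restrict
    ]
    for sys_ in systems:
        sys_.factor(cfg.lambda_s)
    current = init.copy() if init is not None else NetworkCoefficients.zeros(tasks)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        nxt = current.copy()
        for sys_ in systems:
            nxt.betas[sys_.source].loc[sys_.tf_ids, sys_.gene] = sys_.solve(cfg.lambda_s, current)
        delta = nxt.max_abs_diff(current)
        current = nxt
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn("iterative fused solver did not converge", RuntimeWarning)
    current.converged = converged
    current.n_iter = it
    return current


def fused_objective(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
    networks: NetworkCoefficients,
) -> float:
    """Value of the fused ridge objective at the given networks (test oracle)."""
    total = 0.0
    for t in tasks:
        B = networks.betas[t.source_id]
        Bv = B.loc[t.tf_ids, t.gene_ids].to_numpy()
        resid = t.X @ Bv - t.Y
        total += float(np.sum(resid**2))
        if cfg.prior_edges:
            for j, tf in enumerate(t.tf_ids):
                for k, gene in enumerate(t.gene_ids):
                    total += cfg.ridge_for((t.source_id, tf, gene)) * Bv[j, k] ** 2
        else:
            total += cfg.lambda_r * float(np.sum(Bv**2))
    for c in cs:
        d = networks.get(c.left) - networks.get(c.right)
        total += cfg.lambda_s * c.weight * d**2
    return total
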
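"""Adaptive fusion: a saturating (MCP-like) penalty on fused-coefficient differences.

The L2 fusion penalty biases genuinely divergent interactions toward each
other. Adaptive fusion replaces it with a saturating penalty p(theta) on the
absolute difference theta between fused coefficients: quadratic near the
origin, tapering from theta = a/2, and constant for theta >= a. Beyond the
plateau the derivative is zero, so sufficiently different pairs are
effectively "unfused" and incur no further penalty — which doubles as a
read-out of non-conserved (e.g. neofunctionalized) interactions.

Written in terms of its derivative,

    p'(theta) = lam * theta          for 0 <= theta <= a/2
              = lam * (a - theta)    for a/2 <  theta <= a
              = 0                    for theta > a

The non-convex objective is optimized by iterated local quadratic
approximation (LQA): at each step every constraint's effective quadratic
weight is p'(theta)/(2 theta) evaluated at the current difference, and the
resulting fused-L2 problem is solved exactly. Because p'(theta)/theta is
non-increasing, the quadratic surrogate majorizes the penalty and the true
objective is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .constraints import ConstraintSet, FusionConstraint
from .data_model import RegressionTask
from .solver import NetworkCoefficients, SolverConfig, fused_objective, solve_fused_direct

__all__ = [
    "SaturatingPenalty",
    "AdaptiveResult",
    "penalty_derivative",
    "penalty_value",
    "lqa_weight",
    "select_a",
    "solve_adaptive",
]


@dataclass(frozen=True)
class SaturatingPenalty:
    """Saturating fusion penalty with base scale `lam` and saturation point `a`.

    In the quadratic region the LQA weight is lam/2, so lam = 2 * lambda_S
    makes adaptive fusion at small differences coincide with fused-L2 at the
    user's lambda_S.
    """

    lam: float
    a: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not self.a > 0:
            raise ValueError("saturation point a must be > 0")


def penalty_derivative(theta: float, pen: SaturatingPenalty) -> float:
    """p'(theta): lam*theta up to a/2, tapering linearly to 0 at theta = a."""
    if theta < 0:
        raise ValueError("theta is an absolute difference and must be >= 0")
    if theta <= pen.a / 2:
        return pen.lam * theta
    if theta <= pen.a:
        return pen.lam * (pen.a - theta)
    return 0.0


def penalty_value(theta: float, pen: SaturatingPenalty) -> float:
    """p(theta), the integral of p'; constant lam*a^2/4 for theta >= a."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    a, lam = pen.a, pen.lam
    if theta <= a / 2:
        return 0.5 * lam * theta**2
    if theta <= a:
        return lam * a**2 / 8 + lam * (a * theta - theta**2 / 2) - lam * (a**2 / 2 - a**2 / 8)
    return lam * a**2 / 4


def lqa_weight(theta: float, pen: SaturatingPenalty) -> float:
    """LQA quadratic weight p'(theta) / (2 theta); lam/2 at theta = 0, 0 for theta >= a."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        return pen.lam / 2
    if theta >= pen.a:
        return 0.0
    return penalty_derivative(theta, pen) / (2 * theta)


def select_a(
    networks_independent: NetworkCoefficients,
    cs: ConstraintSet,
    percentile: float = 60.0,
) -> float:
    """Saturation point from the distribution of independent-fit differences.

    Takes the requested percentile (numpy linear-interpolation convention) of
    {|beta_left - beta_right|} over all constraints, computed from networks fit
    with lambda_S = 0. The percentile encodes the working hypothesis for the
    fraction of constraints that should stay fused; constraints whose initial
    difference exceeds `a` start in the saturated (unfused) zone.
    """
    if len(cs) == 0:
        raise ValueError("cannot select a from an empty constraint set")
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    diffs = np.array(
        [abs(networks_independent.get(c.left) - networks_independent.get(c.right)) for c in cs]
    )
    return float(np.percentile(diffs, percentile))


@dataclass
class AdaptiveResult:
    """Outcome of the LQA loop: networks, final per-constraint weights, unfused list."""

    networks: NetworkCoefficients
    constraint_weights: list[float]
    unfused: list[FusionConstraint]
    thetas: list[float]
    iterations: int
    converged: bool
    objective: float


def solve_adaptive(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
    pen: SaturatingPenalty,
) -> AdaptiveResult:
    """Iterated LQA for the saturating fusion penalty.

    Starting from theta = 0 for every constraint (so the first pass is
    fused-L2 at weight lam/2), alternates: recompute theta per constraint from
    the current networks, set each constraint's effective quadratic weight via
    :func:`lqa_weight`, re-solve the fused-L2 problem. Stops when the maximum
    coefficient change falls below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    Constraints whose final effective weight is zero are reported as unfused.
    """
    thetas = [0.0] * len(cs)
    networks: NetworkCoefficients | None = None
    converged = False
    it = 0
    weights = [c.weight * lqa_weight(t, pen) for c, t in zip(cs, thetas)]
    for it in range(1, cfg.max_iter + 1):
        weighted = cs.with_weights(weights)
        # effective per-constraint lambda is carried in the weights; the
        # solver's global lambda_s stays 1
        sub_cfg = dc_replace(cfg, lambda_s=1.0)
        nxt = solve_fused_direct(tasks, weighted, sub_cfg)
        if networks is not None and nxt.max_abs_diff(networks) < cfg.tol:
            networks = nxt
            converged = True
            break
        networks = nxt
        thetas = [abs(networks.get(c.left) - networks.get(c.right)) for c in cs]
        weights = [c.weight * lqa_weight(t, pen) for c, t in zip(cs, thetas)]

    assert networks is not None
    thetas = [abs(networks.get(c.left) - networks.get(c.right)) for c in cs]
    final_weights = [c.weight * lqa_weight(t, pen) for c, t in zip(cs, thetas)]
    unfused = [c for c, w in zip(cs, final_weights) if w == 0.0]
    obj = adaptive_objective(tasks, cs, cfg, pen, networks)
    return AdaptiveResult(
        networks=networks,
        constraint_weights=final_weights,
        unfused=unfused,
        thetas=thetas,
        iterations=it,
        converged=converged,
        objective=obj,
    )


def adaptive_objective(
    tasks: list[RegressionTask],
    cs: ConstraintSet,
    cfg: SolverConfig,
    pen: SaturatingPenalty,
    networks: NetworkCoefficients,
) -> float:
    """Residual + ridge + saturating fusion penalty (the true non-convex objective)."""
    base_cfg = dc_replace(cfg, lambda_s=0.0)
    total = fused_objective(tasks, ConstraintSet([]), base_cfg, networks)
    for c in cs:
        theta = abs(networks.get(c.left) - networks.get(c.right))
        total += c.weight * penalty_value(theta, pen)
    return total
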
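"""Confidence scoring of regulatory hypotheses, rank combination, and PR/ROC evaluation.

Raw regression weights are rescaled into confidence scores S in (0, 1]: for
predictor (TF) i and gene j,

    S_ij = sigma2_full_j / (sigma2_full_j + beta_ij^2 * var(TF_i))

(the default "approximation" variant), where sigma2_full_j is the residual
variance of gene j's full model. Smaller S means more variance explained by
the interaction, hence higher confidence; the public ranking reports
confidence = 1 - S so that larger is better. A "full_refit" variant instead
refits the model without predictor i and takes the ratio of residual
variances — but refitting against the data alone disregards information
gained through fusion, so the approximation is the supported default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from .data_model import RegressionTask
from .solver import NetworkCoefficients, SolverConfig
from .tfa import PriorNetwork

__all__ = ["ConfidenceMatrix", "PRResult", "confidence_scores", "rank_combine", "evaluate_pr"]

_SIGMA_FLOOR = 1e-12


@dataclass
class ConfidenceMatrix:
    """Score matrix S (TFs x genes) in (0, 1]; S = 1 iff beta = 0."""

    S: pd.DataFrame
    source_id: str = ""
    flagged: bool = False  # set when a zero-residual response needed the sigma^2 floor

    @property
    def confidence(self) -> pd.DataFrame:
        return 1.0 - self.S

    def ranking(self, universe: list[tuple[str, str]] | None = None) -> list[tuple[str, str]]:
        """Edges ordered best-first: ascending S, ties broken lexicographically."""
        if universe is None:
            universe = [
                (tf, g) for tf in self.S.index for g in self.S.columns if tf != g
            ]
        return sorted(universe, key=lambda e: (float(self.S.at[e[0], e[1]]), e))

    def edge_scores(self, universe: list[tuple[str, str]]) -> np.ndarray:
        return np.array([float(self.S.at[tf, g]) for tf, g in universe])


def confidence_scores(
    task: RegressionTask,
    network: NetworkCoefficients,
    variant: str = "approximation",
    cfg: SolverConfig | None = None,
) -> ConfidenceMatrix:
    """Rescale a fitted network's betas into confidence scores for one source.

    ``variant="approximation"`` (default) uses the residual-variance identity
    above. ``variant="full_refit"`` refits gene j's ridge model without
    predictor i (requires ``cfg``) and scores S_ij =
    sigma2_full / sigma2_without_i; it ignores fusion and is provided for
    comparison only.
    """
    B = network.betas[task.source_id].loc[task.tf_ids, task.gene_ids].to_numpy()
    resid = task.X @ B - task.Y
    n = task.n_rows
    sigma2_full = (resid**2).mean(axis=0)  # per gene
    flagged = False

    if variant == "approximation":
        var_tf = task.X.var(axis=0, ddof=1)
        sigma2 = sigma2_full.copy()
        needs_floor = (sigma2 <= 0) & (np.abs(B).max(axis=0) > 0)
        if needs_floor.any():
            flagged = True
            sigma2 = np.maximum(sigma2, _SIGMA_FLOOR)
        S = sigma2[None, :] / (sigma2[None, :] + B**2 * var_tf[:, None])
    elif variant == "full_refit":
        if cfg is None:
            raise ValueError("full_refit variant requires the solver config used for the fit")
        S = np.ones_like(B)
        for k, gene in enumerate(task.gene_ids):
            pred = [j for j, tf in enumerate(task.tf_ids) if tf != gene]
            y = task.Y[:, k]
            for j in pred:
                others = [m for m in pred if m != j]
                Xo = task.X[:, others]
                A = np.vstack([Xo, np.sqrt(cfg.lambda_r) * np.eye(len(others))])
                b = np.concatenate([y, np.zeros(len(others))])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                sigma2_wo = float(np.mean((Xo @ sol - y) ** 2))
                if sigma2_wo <= 0:
                    flagged = True
                    sigma2_wo = _SIGMA_FLOOR
                S[j, k] = min(1.0, max(sigma2_full[k], _SIGMA_FLOOR) / sigma2_wo)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    S_df = pd.DataFrame(S, index=task.tf_ids, columns=task.gene_ids)
    return ConfidenceMatrix(S=S_df, source_id=task.source_id, flagged=flagged)


def rank_combine(matrices: list[ConfidenceMatrix]) -> pd.DataFrame:
    """Combine rankings from several networks over a common edge set.

    Each score matrix is converted to ranks (rank 1 = most confident, average
    ranks for ties), ranks are averaged per edge, and edges are re-ranked by
    mean rank. Returns a DataFrame (tf, gene, mean_rank) sorted best-first
    with lexicographic tie-breaking.
    """
    if not matrices:
        raise ValueError("need at least one confidence matrix")
    ref = matrices[0].S
    edges = [(tf, g) for tf in ref.index for g in ref.columns]
    for m in matrices[1:]:
        if list(m.S.index) != list(ref.index) or list(m.S.columns) != list(ref.columns):
            raise ValueError("confidence matrices must share the same edge set")
    ranks = np.zeros((len(matrices), len(edges)))
    for i, m in enumerate(matrices):
        scores = np.array([m.S.at[tf, g] for tf, g in edges])
        ranks[i] = rankdata(scores, method="average")
    mean_rank = ranks.mean(axis=0)
    out = pd.DataFrame({"tf": [e[0] for e in edges], "gene": [e[1] for e in edges], "mean_rank": mean_rank})
    return out.sort_values(["mean_rank", "tf", "gene"], kind="mergesort").reset_index(drop=True)


@dataclass
class PRResult:
    """Precision-recall and ROC summaries of a ranked edge list against a gold standard."""

    recall: np.ndarray
    precision: np.ndarray
    aupr: float
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_positives: int
    n_edges: int


def evaluate_pr(
    ranking: list[tuple[str, str]],
    gold: PriorNetwork,
    universe: list[tuple[str, str]],
) -> PRResult:
    """Evaluate a best-first edge ranking against an (unsigned) gold standard.

    Gold edges are the positives; the eligible `universe` defines which edges
    are scored (e.g. the constrained or non-constrained subnetwork). The area
    under the precision-recall curve uses the step-interpolation convention
    AUPR = sum_k (r_k - r_{k-1}) p_k (identical to average precision).
    """
    gold_edges = gold.unsigned_edges()
    uni = set(universe)
    if not gold_edges:
        raise ValueError("empty gold standard")
    missing = gold_edges - uni
    if missing:
        raise ValueError(f"gold edges outside the eligible universe, e.g. {sorted(missing)[:3]}")
    ranked = [e for e in ranking if e in uni]
    if set(ranked) != uni:
        raise ValueError("ranking does not cover the eligible universe")

    y_true = np.array([1 if e in gold_edges else 0 for e in ranked])
    # best-first order: score by descending position
    y_score = -np.arange(len(ranked), dtype=float)
    aupr = float(average_precision_score(y_true, y_score))
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    if y_true.min() == y_true.max():
        fpr = tpr = np.array([0.0, 1.0])
        auroc = float("nan")
    else:
        fpr, tpr, _ = roc_curve(y_true, y_score)
        auroc = float(roc_auc_score(y_true, y_score))
    # precision_recall_curve returns points from high threshold to low; flip to ascending recall
    return PRResult(
        recall=recall[::-1],
        precision=precision[::-1],
        aupr=aupr,
        fpr=fpr,
        tpr=tpr,
        auroc=auroc,
        n_positives=int(y_true.sum()),
        n_edges=len(ranked),
    )
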
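"""Expression data containers and conversion to the dynamics regression problem.

Gene expression dynamics are modeled as

    dx_i/dt = -alpha * x_i + sum_j beta_ij * x_j        (j over TFs, j != i)

where alpha is a global mRNA decay rate. Time-series condition pairs
approximate the derivative by a finite difference; steady-state conditions
are treated as having derivative zero. Rearranging gives one regression row
per usable condition with response

    y = (x(t_{k+1}) - x(t_k)) / dt + alpha * x(t_k)     (time series)
    y = alpha * x(t_k)                                  (steady state)

and TF expression at t_k (the earlier timepoint) as predictors, i.e. the
multi-output linear model Y = X beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConditionMeta",
    "ExpressionDataset",
    "RegressionTask",
    "build_response_design",
    "standardize_predictors",
]

#: decay rate corresponding to the default 10-minute mRNA half-life time constant
DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class ConditionMeta:
    """Metadata for one experimental condition (one expression column)."""

    condition: str
    is_time_series: bool = False
    predecessor: str | None = None
    delta_t: float | None = None  # minutes; present iff predecessor is set


@dataclass
class ExpressionDataset:
    """One source's expression matrix (genes x conditions) plus condition metadata.

    Parameters
    ----------
    source_id
        Label for the data source (species, platform, strain).
    values
        DataFrame of expression, index = gene ids, columns = condition ids.
    tf_ids
        Subset of the gene ids declared as transcription factors.
    condition_meta
        One :class:`ConditionMeta` per condition, distinguishing steady-state
        samples from time-series samples and linking the latter to their
        predecessor condition.
    """

    source_id: str
    values: pd.DataFrame
    tf_ids: list[str]
    condition_meta: list[ConditionMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = list(self.values.index)
        conds = list(self.values.columns)
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene ids in source {self.source_id!r}")
        if len(set(conds)) != len(conds):
            raise ValueError(f"duplicate condition ids in source {self.source_id!r}")
        missing_tfs = set(self.tf_ids) - set(genes)
        if missing_tfs:
            raise ValueError(f"TF ids not present among genes: {sorted(missing_tfs)}")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValueError("duplicate TF ids")
        if not self.condition_meta:
            self.condition_meta = [ConditionMeta(c) for c in conds]
        meta_ids = [m.condition for m in self.condition_meta]
        if sorted(meta_ids) != sorted(conds):
            raise ValueError("condition metadata does not match expression columns")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values; imputation is not supported")
        by_id = {m.condition: m for m in self.condition_meta}
        for m in self.condition_meta:
            if m.predecessor is not None:
                if not m.is_time_series:
                    raise ValueError(f"condition {m.condition!r} has a predecessor but is not time-series")
                if m.predecessor not in by_id:
                    raise ValueError(f"predecessor {m.predecessor!r} of condition {m.condition!r} not found")
                if m.delta_t is None or not m.delta_t > 0:
                    raise ValueError(f"condition {m.condition!r} needs delta_t > 0, got {m.delta_t!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class RegressionTask:
    """Per-source regression problem: predictors X (TF space) and responses Y.

    ``X`` rows are TF expression (or activity) at the earlier timepoint of each
    usable condition; ``Y`` rows are the dynamics-derived responses for every
    gene. Standardization parameters (``x_means``/``x_sds``) are recorded so
    coefficients can be mapped back to the raw expression scale.
    """

    source_id: str
    X: np.ndarray  # (n_rows, n_tfs)
    Y: np.ndarray  # (n_rows, n_genes)
    alpha: float
    tf_ids: list[str]
    gene_ids: list[str]
    x_means: np.ndarray | None = None
    x_sds: np.ndarray | None = None
    constant_columns: np.ndarray | None = None  # bool flags, set by standardize_predictors

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.X.shape[1] != len(self.tf_ids):
            raise ValueError("X column count does not match tf_ids")
        if self.Y.shape[1] != len(self.gene_ids):
            raise ValueError("Y column count does not match gene_ids")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def tf_index(self, tf: str) -> int:
        return self.tf_ids.index(tf)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)


def build_response_design(
    ds: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    *,
    allow_zero_alpha: bool = False,
    predictors: pd.DataFrame | None = None,
) -> RegressionTask:
    """Convert an expression dataset into the Y = X beta regression problem.

    Each steady-state condition contributes a row with response
    ``alpha * x`` and TF expression at that condition as predictors. Each
    time-series condition with a predecessor contributes a row with the
    finite-difference response ``(x_next - x_prev)/dt + alpha * x_prev`` and TF
    expression at the predecessor. Time-series conditions without a
    predecessor (chain starts) contribute no row.

    ``alpha`` must be positive; ``allow_zero_alpha=True`` admits the
    decay-free convention used by the synthetic-data generator.

    ``predictors`` optionally substitutes a TFs x conditions matrix (e.g.
    estimated TF activities) for TF expression on the predictor side only;
    responses always come from the measured expression.
    """
    if alpha < 0 or (alpha == 0 and not allow_zero_alpha):
        raise ValueError("alpha must be > 0 (pass allow_zero_alpha=True for decay-free simulated data)")

    if predictors is not None:
        if list(predictors.index) != list(ds.tf_ids) or set(predictors.columns) != set(ds.values.columns):
            raise ValueError("predictor matrix must be indexed by tf_ids x condition ids")
        tf_rows = predictors
    else:
        tf_rows = ds.values.loc[ds.tf_ids]
    x_rows: list[np.ndarray] = []
    y_rows: list[np.ndarray] = []
    for m in ds.condition_meta:
        x_now = ds.values[m.condition].to_numpy(dtype=float)
        if not m.is_time_series:
            y_rows.append(alpha * x_now)
            x_rows.append(tf_rows[m.condition].to_numpy(dtype=float))
        elif m.predecessor is not None:
            x_prev = ds.values[m.predecessor].to_numpy(dtype=float)
            y_rows.append((x_now - x_prev) / m.delta_t + alpha * x_prev)
            x_rows.append(tf_rows[m.predecessor].to_numpy(dtype=float))
    if not y_rows:
        raise ValueError("zero usable conditions: no steady-state rows and no time-series pairs")
    return RegressionTask(
        source_id=ds.source_id,
        X=np.vstack(x_rows),
        Y=np.vstack(y_rows),
        alpha=alpha,
        tf_ids=list(ds.tf_ids),
        gene_ids=ds.gene_ids,
    )


def standardize_predictors(task: RegressionTask) -> RegressionTask:
    """Center each predictor column and scale non-constant columns to unit variance.

    Uses the population (ddof=0) standard deviation, so a two-row column
    (1, 3) maps to (-1, 1) with recorded mean 2 and sd 1. Constant columns are
    centered only and flagged; their recorded sd is 1 so de-standardization is
    a no-op.
    """
    if task.n_rows < 2:
        raise ValueError("standardization requires at least 2 rows")
    means = task.X.mean(axis=0)
    sds = task.X.std(axis=0, ddof=0)
    constant = sds <= 1e-12 * (1.0 + np.abs(means))
    safe_sds = np.where(constant, 1.0, sds)
    X = (task.X - means) / safe_sds
    return replace(task, X=X, x_means=means, x_sds=safe_sds, constant_columns=constant)
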
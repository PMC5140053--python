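"""Shared fixtures: small seeded regression instances and constraint sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fusenet.constraints import ConstraintSet, FusionConstraint
from fusenet.data_model import ConditionMeta, ExpressionDataset, RegressionTask, standardize_predictors


def make_random_instance(seed: int, n_tfs: int = 3, n_genes: int = 5, n_rows: int = 8, n_constraints: int = 4):
    """Two-source random regression pair with cross-source fusion constraints.

    TF and gene ids are disjoint (responses are non-TF genes), so every
    TF x gene coefficient exists in both sources and constraints can pair any
    coefficient across sources.
    """
    rng = np.random.default_rng(seed)
    tfs = [f"t{i}" for i in range(n_tfs)]
    genes = [f"g{i}" for i in range(n_genes)]
    tasks = []
    for s in ("s1", "s2"):
        X = rng.normal(size=(n_rows, n_tfs))
        Y = rng.normal(size=(n_rows, n_genes))
        tasks.append(standardize_predictors(RegressionTask(s, X, Y, 0.1, tfs, genes)))
    cons = []
    for _ in range(n_constraints):
        tf_a, tf_b = rng.choice(tfs, 2)
        g_a, g_b = rng.choice(genes, 2)
        cons.append(FusionConstraint(("s1", tf_a, g_a), ("s2", tf_b, g_b)))
    return tasks, ConstraintSet(cons)


@pytest.fixture
def small_instance():
    return make_random_instance(seed=42)


@pytest.fixture
def steady_state_dataset():
    """4 genes (2 TFs) x 5 steady-state conditions."""
    rng = np.random.default_rng(0)
    genes = ["tfA", "tfB", "g1", "g2"]
    values = pd.DataFrame(
        rng.normal(size=(4, 5)), index=genes, columns=[f"c{i}" for i in range(5)]
    )
    return ExpressionDataset("s1", values, ["tfA", "tfB"], [ConditionMeta(c) for c in values.columns])
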
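"""Transcription factor activity (TFA) estimation via network component analysis.

A TF's mRNA abundance is often a poor proxy for its regulatory activity
(dimerization, post-translational control, cofactor availability). Given a
prior connectivity P (target genes x TFs, entries +/-1 for known activation /
repression), latent activities A are estimated from the targets' expression E
by the minimum-norm least-squares solution of P A ~ E, i.e. A = pinv(P) E.
TFs with no prior targets fall back to their own expression, so an identity
prior reproduces the expression-based pipeline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset

__all__ = ["PriorNetwork", "estimate_tfa"]


@dataclass
class PriorNetwork:
    """Signed known interactions (tf, gene, sign in {+1, -1}) for one source."""

    edges: list[tuple[str, str, int]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for tf, gene, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"sign for edge ({tf!r}, {gene!r}) must be +1 or -1, got {sign!r}")
            if (tf, gene) in seen:
                raise ValueError(f"duplicate prior edge ({tf!r}, {gene!r})")
            seen.add((tf, gene))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> list[str]:
        out: list[str] = []
        for tf, _, _ in self.edges:
            if tf not in out:
                out.append(tf)
        return out

    def unsigned_edges(self) -> set[tuple[str, str]]:
        return {(tf, gene) for tf, gene, _ in self.edges}

    def split(self, seed: int) -> tuple["PriorNetwork", "PriorNetwork"]:
        """Seeded random half-split into (prior half, evaluation half)."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.edges))
        half = len(self.edges) // 2
        first = [self.edges[i] for i in sorted(order[:half])]
        second = [self.edges[i] for i in sorted(order[half:])]
        return PriorNetwork(first, self.source_id), PriorNetwork(second, self.source_id)


def estimate_tfa(ds: ExpressionDataset, prior: PriorNetwork) -> pd.DataFrame:
    """Estimate TF activities (TFs x conditions) from a signed prior network.

    Activities of TFs with prior targets solve the least-squares system
    (sign matrix over prior-target genes) @ activities ~ (target expression),
    via the Moore-Penrose pseudoinverse; TFs without prior targets keep their
    own expression as activity.
    """
    if not ds.tf_ids and not prior.edges:
        raise ValueError("no TFs and no prior interactions: nothing to estimate")
    for tf, gene, _ in prior.edges:
        if tf not in ds.tf_ids:
            raise ValueError(f"prior TF {tf!r} is not a declared TF in source {ds.source_id!r}")
        if gene not in ds.gene_ids:
            raise ValueError(f"prior target {gene!r} absent from source {ds.source_id!r}")

    activities = ds.values.loc[ds.tf_ids].copy()  # fallback: own expression
    prior_tfs = [tf for tf in ds.tf_ids if any(e[0] == tf for e in prior.edges)]
    if prior_tfs:
        target_genes = sorted({gene for _, gene, _ in prior.edges})
        P = pd.DataFrame(0.0, index=target_genes, columns=prior_tfs)
        for tf, gene, sign in prior.edges:
            if tf in prior_tfs:
                P.at[gene, tf] = float(sign)
        E = ds.values.loc[target_genes].to_numpy()
        A = np.linalg.pinv(P.to_numpy()) @ E
        activities.loc[prior_tfs] = A
    return activities
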
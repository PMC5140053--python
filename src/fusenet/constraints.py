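"""Fusion-constraint generation from orthology or operon membership.

A fusion constraint couples two regulatory coefficients — (source, TF, gene)
triples — that are expected a priori to be similar: the coefficient of an
orthologous TF on an orthologous gene in another species, or the coefficients
of one TF on two genes in the same operon. The constraint graph over response
variables (source, gene) decomposes the joint fused regression into
independently solvable connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .data_model import RegressionTask

__all__ = [
    "Coefficient",
    "OrthologyMap",
    "FusionConstraint",
    "ConstraintSet",
    "constraints_from_orthology",
    "constraints_from_operons",
    "constraint_components",
]

# a coefficient is identified by (source_id, tf_id, gene_id)
Coefficient = tuple[str, str, str]
# a response variable is one gene's regression problem in one source
Response = tuple[str, str]


@dataclass
class OrthologyMap:
    """Pairwise gene correspondences between (or within) sources.

    Pairs are stored canonically (lexicographically ordered endpoints) and
    deduplicated. Optional truth labels mark simulated pairs as genuine or
    injected false orthologs.
    """

    pairs: list[tuple[str, str, str, str]] = field(default_factory=list)
    truth: dict[tuple[str, str, str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        new_truth: dict[tuple[str, str, str, str], bool] = {}
        for sa, ga, sb, gb in self.pairs:
            key = (sa, ga, sb, gb)
            if (sb, gb) < (sa, ga):
                key = (sb, gb, sa, ga)
            if (key[0], key[1]) == (key[2], key[3]):
                raise ValueError(f"self-orthology pair {key}")
            if key in seen:
                continue
            seen.add(key)
            canon.append(key)
            if (sa, ga, sb, gb) in self.truth:
                new_truth[key] = self.truth[(sa, ga, sb, gb)]
            elif key in self.truth:
                new_truth[key] = self.truth[key]
        self.pairs = canon
        self.truth = new_truth

    def __len__(self) -> int:
        return len(self.pairs)

    def partners(self, source: str, gene: str) -> list[tuple[str, str]]:
        out = []
        for sa, ga, sb, gb in self.pairs:
            if (sa, ga) == (source, gene):
                out.append((sb, gb))
            elif (sb, gb) == (source, gene):
                out.append((sa, ga))
        return out


@dataclass(frozen=True)
class FusionConstraint:
    """Penalty term w * lambda_S * (beta[left] - beta[right])^2."""

    left: Coefficient
    right: Coefficient
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("fusion constraint endpoints must differ")
        if self.weight < 0:
            raise ValueError("constraint weight must be >= 0")
        if self.right < self.left:  # canonical endpoint order
            left, right = self.left, self.right
            object.__setattr__(self, "left", right)
            object.__setattr__(self, "right", left)

    @property
    def responses(self) -> tuple[Response, Response]:
        return (self.left[0], self.left[2]), (self.right[0], self.right[2])


@dataclass
class ConstraintSet:
    """A deduplicated collection of fusion constraints with a response index."""

    constraints: list[FusionConstraint] = field(default_factory=list)
    truth: dict[tuple[Coefficient, Coefficient], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[Coefficient, Coefficient], int] = {}
        unique: list[FusionConstraint] = []
        for c in self.constraints:
            key = (c.left, c.right)
            if key not in seen:
                seen[key] = len(unique)
                unique.append(c)
        self.constraints = unique
        self._by_response: dict[Response, list[int]] = {}
        for i, c in enumerate(self.constraints):
            for r in c.responses:
                self._by_response.setdefault(r, []).append(i)

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def for_response(self, response: Response) -> list[FusionConstraint]:
        return [self.constraints[i] for i in self._by_response.get(response, [])]

    def with_weights(self, weights: Iterable[float]) -> "ConstraintSet":
        """Return a copy with per-constraint weights replaced (same order)."""
        weights = list(weights)
        if len(weights) != len(self.constraints):
            raise ValueError("weight count does not match constraint count")
        return ConstraintSet(
            [FusionConstraint(c.left, c.right, w) for c, w in zip(self.constraints, weights)],
            truth=dict(self.truth),
        )


def _split_orthology(tasks: list[RegressionTask], orth: OrthologyMap):
    """Partition ortholog pairs into TF-TF and gene-gene pairs, validating ids."""
    by_source = {t.source_id: t for t in tasks}
    tf_pairs, gene_pairs = [], []
    for sa, ga, sb, gb in orth.pairs:
        for s, g in ((sa, ga), (sb, gb)):
            if s not in by_source:
                raise ValueError(f"orthology references unknown source {s!r}")
            if g not in by_source[s].gene_ids and g not in by_source[s].tf_ids:
                raise ValueError(f"ortholog id {g!r} absent from source {s!r}")
        a_is_tf = ga in by_source[sa].tf_ids
        b_is_tf = gb in by_source[sb].tf_ids
        # a pair is usable as a regulator pair only if both members are TFs,
        # and as a target pair only if both are response genes (a TF can be both)
        if a_is_tf and b_is_tf:
            tf_pairs.append((sa, ga, sb, gb))
        if ga in by_source[sa].gene_ids and gb in by_source[sb].gene_ids:
            gene_pairs.append((sa, ga, sb, gb))
    return tf_pairs, gene_pairs


def constraints_from_orthology(tasks: list[RegressionTask], orth: OrthologyMap) -> ConstraintSet:
    """One fusion constraint per (orthologous TF pair) x (orthologous gene pair).

    A coefficient beta[s, t, g] is fused to beta[s', t', g'] whenever (t, t')
    are orthologous TFs and (g, g') are orthologous genes between sources s
    and s'. Self-regulatory coefficients (TF on itself) are structurally zero
    and generate no constraints. With more than two sources, constraints are
    enumerated over all source pairs present in the orthology map.

    Truth labels, when present on the orthology pairs, propagate to the
    constraints: a constraint is genuine only if both its TF pair and gene
    pair are genuine.
    """
    tf_pairs, gene_pairs = _split_orthology(tasks, orth)
    out: list[FusionConstraint] = []
    truth: dict[tuple[Coefficient, Coefficient], bool] = {}
    for sta, ta, stb, tb in tf_pairs:
        for sga, ga, sgb, gb in gene_pairs:
            # orient the gene pair to the TF pair's source ordering
            if (sga, sgb) == (sta, stb):
                pass
            elif (sgb, sga) == (sta, stb):
                sga, ga, sgb, gb = sgb, gb, sga, ga
            else:
                continue  # pairs spanning a different source pair
            if ta == ga or tb == gb:
                continue  # self-regulation is masked
            c = FusionConstraint((sta, ta, ga), (stb, tb, gb))
            out.append(c)
            if orth.truth:
                t_true = orth.truth.get(_canon_pair(sta, ta, stb, tb), True)
                g_true = orth.truth.get(_canon_pair(sga, ga, sgb, gb), True)
                truth[(c.left, c.right)] = t_true and g_true
    return ConstraintSet(out, truth=truth)


def _canon_pair(sa: str, ga: str, sb: str, gb: str) -> tuple[str, str, str, str]:
    return (sa, ga, sb, gb) if (sa, ga) <= (sb, gb) else (sb, gb, sa, ga)


def constraints_from_operons(task: RegressionTask, operons: Mapping[str, str]) -> ConstraintSet:
    """Within-source constraints: a TF's coefficients on co-operonic genes are fused.

    For each TF t and each unordered pair of distinct genes (i, j) sharing an
    operon id, the coefficients (t -> i) and (t -> j) are fused. Genes without
    an operon assignment generate nothing; self-regulatory coefficients are
    skipped.
    """
    unknown = set(operons) - set(task.gene_ids)
    if unknown:
        raise ValueError(f"operon genes absent from task: {sorted(unknown)}")
    members: dict[str, list[str]] = {}
    for gene in task.gene_ids:  # deterministic task order
        op = operons.get(gene)
        if op is not None:
            members.setdefault(op, []).append(gene)
    out: list[FusionConstraint] = []
    s = task.source_id
    for genes in members.values():
        for a_idx in range(len(genes)):
            for b_idx in range(a_idx + 1, len(genes)):
                gi, gj = genes[a_idx], genes[b_idx]
                for tf in task.tf_ids:
                    if tf in (gi, gj):
                        continue
                    out.append(FusionConstraint((s, tf, gi), (s, tf, gj)))
    return ConstraintSet(out)


def constraint_components(cs: ConstraintSet, tasks: list[RegressionTask]) -> list[set[Response]]:
    """Connected components of the response graph induced by fusion constraints.

    Nodes are response variables (source, gene); an edge joins two responses
    whenever any fusion constraint couples their coefficients. Unconstrained
    responses are singleton components. Components are returned in a
    deterministic order (sorted by their smallest member).
    """
    g: nx.Graph = nx.Graph()
    valid: set[Response] = set()
    for t in tasks:
        for gene in t.gene_ids:
            node = (t.source_id, gene)
            valid.add(node)
            g.add_node(node)
    for c in cs:
        ra, rb = c.responses
        for r in (ra, rb):
            if r not in valid:
                raise ValueError(f"constraint references unknown response {r}")
        if ra != rb:
            g.add_edge(ra, rb)
    comps = [set(comp) for comp in nx.connected_components(g)]
    comps.sort(key=lambda comp: min(comp))
    return comps
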
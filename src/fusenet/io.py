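"""Readers and writers for the TSV formats and the run configuration.

All files are tab-separated UTF-8 with a header row; lines starting with '#'
are comments. Edge lists carry explicit source columns so multi-source files
are unambiguous. Formats:

* expression: first column ``gene``, remaining columns condition ids
* condition metadata: columns ``condition``, ``isTs`` (TRUE/FALSE),
  ``prevCond`` (condition id or NA), ``del.t`` (minutes or NA)
* TF list: one id per line (no header)
* orthology: columns ``source_a``, ``gene_a``, ``source_b``, ``gene_b``
  (+ optional ``is_true`` for simulated fixtures)
* operons: columns ``gene``, ``operon_id``
* prior / gold standard: columns ``tf``, ``gene``, ``sign`` with sign in
  {1, -1, activation, repression}
* network: columns ``source``, ``tf``, ``gene``, ``beta``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .constraints import OrthologyMap
from .data_model import ConditionMeta, ExpressionDataset
from .tfa import PriorNetwork

__all__ = [
    "RunConfig",
    "read_expression",
    "read_orthology",
    "read_operons",
    "read_prior",
    "read_inputs",
    "write_expression",
    "write_condition_meta",
    "write_tf_list",
    "write_orthology",
    "write_prior",
    "write_network",
    "gold_from_network",
    "write_outputs",
]

_TSV = dict(sep="\t", comment="#")


@dataclass
class SourceFiles:
    """File paths for one expression source."""

    source_id: str
    expression: str
    condition_meta: str | None = None
    tf_list: str = ""
    gold: str | None = None
    operons: str | None = None


@dataclass
class RunConfig:
    """Validated options for one inference run (see docs for the YAML schema)."""

    sources: list[SourceFiles]
    orthology: str | None = None
    output_dir: str = "fusenet_out"
    alpha: float = 0.1
    allow_zero_alpha: bool = False
    lambda_r: float | None = None  # None -> cross-validated
    lambda_s: float | None = None
    prior_relax: float = 0.1
    tol: float = 1e-6
    max_iter: int = 50
    solver: str = "direct"  # direct | iterative
    folds: int = 5
    seed: int = 0
    use_tfa: bool = False
    adaptive: bool = False
    a_percentile: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sources = [SourceFiles(**s) for s in raw.pop("sources")]
        cfg = cls(sources=sources, **raw)
        if cfg.solver not in ("direct", "iterative"):
            raise ValueError(f"unknown solver {cfg.solver!r}")
        if cfg.folds < 2:
            raise ValueError("folds must be >= 2 (cannot cross-validate with 1 fold)")
        return cfg


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_expression(
    expression: str | Path,
    tf_list: str | Path,
    condition_meta: str | Path | None = None,
    source_id: str = "s1",
) -> ExpressionDataset:
    """Load one source's expression matrix, TF list and condition metadata."""
    values = pd.read_csv(_require(expression), index_col=0, **_TSV)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    tfs = [
        line.strip()
        for line in _require(tf_list).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    meta: list[ConditionMeta] = []
    if condition_meta is not None:
        mdf = pd.read_csv(_require(condition_meta), **_TSV)
        expected = {"condition", "isTs", "prevCond", "del.t"}
        if not expected <= set(mdf.columns):
            raise ValueError(f"condition metadata must have columns {sorted(expected)}")
        for i, row in mdf.iterrows():
            is_ts = str(row["isTs"]).strip().upper() == "TRUE"
            prev = None if pd.isna(row["prevCond"]) else str(row["prevCond"])
            dt = None if pd.isna(row["del.t"]) else float(row["del.t"])
            if prev is not None and dt is not None and dt <= 0:
                raise ValueError(f"{condition_meta}, line {i + 2}: del.t must be > 0")
            meta.append(ConditionMeta(str(row["condition"]), is_ts, prev, dt))
    return ExpressionDataset(source_id=source_id, values=values, tf_ids=tfs, condition_meta=meta)


def read_orthology(path: str | Path) -> OrthologyMap:
    df = pd.read_csv(_require(path), dtype=str, **_TSV)
    required = {"source_a", "gene_a", "source_b", "gene_b"}
    if not required <= set(df.columns):
        raise ValueError(f"orthology file must have columns {sorted(required)}")
    pairs = list(zip(df["source_a"], df["gene_a"], df["source_b"], df["gene_b"]))
    truth = {}
    if "is_true" in df.columns:
        for p, flag in zip(pairs, df["is_true"]):
            truth[p] = str(flag).strip().upper() == "TRUE"
    return OrthologyMap(pairs, truth=truth)


def read_operons(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(_require(path), dtype=str, **_TSV)
    if not {"gene", "operon_id"} <= set(df.columns):
        raise ValueError("operon file must have columns gene, operon_id")
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate operon assignment for gene {df['gene'][dup].iloc[0]!r}")
    return dict(zip(df["gene"], df["operon_id"]))


_SIGN_WORDS = {"1": 1, "+1": 1, "-1": -1, "activation": 1, "repression": -1}


def read_prior(path: str | Path, source_id: str = "") -> PriorNetwork:
    df = pd.read_csv(_require(path), dtype=str, **_TSV)
    if not {"tf", "gene", "sign"} <= set(df.columns):
        raise ValueError("prior/gold file must have columns tf, gene, sign")
    edges = []
    for i, row in df.iterrows():
        raw = str(row["sign"]).strip().lower()
        if raw not in _SIGN_WORDS:
            raise ValueError(
                f"{path}, line {i + 2}: sign must be one of +1/-1/activation/repression, got {row['sign']!r}"
            )
        edges.append((str(row["tf"]), str(row["gene"]), _SIGN_WORDS[raw]))
    return PriorNetwork(edges, source_id)


def read_inputs(cfg: RunConfig):
    """Load and cross-validate all inputs of a run.

    Returns (datasets, orthology, priors, operons) keyed consistently by
    source id; raises with the offending id on any cross-file inconsistency.
    """
    datasets: dict[str, ExpressionDataset] = {}
    priors: dict[str, PriorNetwork] = {}
    operons: dict[str, dict[str, str]] = {}
    for sf in cfg.sources:
        ds = read_expression(sf.expression, sf.tf_list, sf.condition_meta, sf.source_id)
        datasets[sf.source_id] = ds
        if sf.gold:
            prior = read_prior(sf.gold, sf.source_id)
            for tf, gene, _ in prior.edges:
                if tf not in ds.tf_ids:
                    raise ValueError(f"gold TF {tf!r} not a declared TF in source {sf.source_id!r}")
                if gene not in ds.gene_ids:
                    raise ValueError(f"gold gene {gene!r} absent from source {sf.source_id!r}")
            priors[sf.source_id] = prior
        if sf.operons:
            ops = read_operons(sf.operons)
            unknown = set(ops) - set(ds.gene_ids)
            if unknown:
                raise ValueError(f"operon genes absent from source {sf.source_id!r}: {sorted(unknown)[:3]}")
            operons[sf.source_id] = ops
    orth = OrthologyMap([])
    if cfg.orthology:
        orth = read_orthology(cfg.orthology)
        for sa, ga, sb, gb in orth.pairs:
            for s, g in ((sa, ga), (sb, gb)):
                if s not in datasets:
                    raise ValueError(f"orthology references unknown source {s!r}")
                if g not in datasets[s].gene_ids:
                    raise ValueError(f"ortholog {g!r} absent from source {s!r}")
    return datasets, orth, priors, operons


# ---------------------------------------------------------------- writers


def write_expression(ds: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    ds.values.to_csv(path, sep="\t", index_label="gene")
    return path


def write_condition_meta(ds: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "condition": m.condition,
            "isTs": "TRUE" if m.is_time_series else "FALSE",
            "prevCond": m.predecessor if m.predecessor is not None else "NA",
            "del.t": m.delta_t if m.delta_t is not None else "NA",
        }
        for m in ds.condition_meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_tf_list(tf_ids: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(tf_ids) + "\n")
    return path


def write_orthology(orth: OrthologyMap, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for p in orth.pairs:
        row = {"source_a": p[0], "gene_a": p[1], "source_b": p[2], "gene_b": p[3]}
        if orth.truth:
            row["is_true"] = "TRUE" if orth.truth.get(p, True) else "FALSE"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_prior(prior: PriorNetwork, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(prior.edges, columns=["tf", "gene", "sign"]).to_csv(path, sep="\t", index=False)
    return path


def write_network(betas: dict[str, pd.DataFrame], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in sorted(betas):
        b = betas[s]
        for tf in b.index:
            for gene in b.columns:
                rows.append((s, tf, gene, float(b.at[tf, gene])))
    pd.DataFrame(rows, columns=["source", "tf", "gene", "beta"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def gold_from_network(beta: pd.DataFrame, source_id: str, threshold: float = 0.0) -> PriorNetwork:
    """Signed edge list of a (true) network's entries with |beta| > threshold."""
    edges = []
    for tf in beta.index:
        for gene in beta.columns:
            v = float(beta.at[tf, gene])
            if abs(v) > threshold:
                edges.append((tf, gene, 1 if v > 0 else -1))
    return PriorNetwork(edges, source_id)


def write_outputs(result, outdir: str | Path) -> dict[str, Path]:
    """Write a workflow result: ranked network, PR/ROC curves, manifest, unfused list.

    Output ordering is deterministic (ties broken lexicographically) for
    diffability. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranked = result.ranked_edges
    if ranked is None or ranked.empty:
        raise ValueError("nothing to write: empty ranking")
    paths["ranked_network"] = outdir / "ranked_network.tsv"
    ranked.to_csv(paths["ranked_network"], sep="\t", index=False, float_format="%.10g")

    if result.pr_curve is not None:
        paths["pr_curve"] = outdir / "pr_curve.tsv"
        result.pr_curve.to_csv(paths["pr_curve"], sep="\t", index=False, float_format="%.10g")
    if result.roc_curve is not None:
        paths["roc_curve"] = outdir / "roc_curve.tsv"
        result.roc_curve.to_csv(paths["roc_curve"], sep="\t", index=False, float_format="%.10g")
    if result.unfused is not None:
        paths["unfused_constraints"] = outdir / "unfused_constraints.tsv"
        result.unfused.to_csv(paths["unfused_constraints"], sep="\t", index=False, float_format="%.10g")

    paths["networks"] = write_network(result.networks.betas, outdir / "network.tsv")
    paths["manifest"] = outdir / "manifest.yaml"
    paths["manifest"].write_text(yaml.safe_dump(result.manifest, sort_keys=True))
    return paths
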
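"""Synthetic fused-network studies: paired networks, expression, corrupted orthology.

The generator emulates two related regulatory networks observed through
two-timepoint expression:

1. a random one-to-one orthology pairs a fraction of TFs and of non-TF genes
   across the two sources (TFs are never paired with non-TFs);
2. network coefficients are drawn groupwise: each fused group is zero with
   probability `sparsity`, otherwise a shared value v ~ N(0, 1) plus
   independent N(0, sigma_f^2) divergence noise per member — so nonzero
   coefficients are N(0, 1 + sigma_f^2) and fused pairs differ by
   N(0, 2 sigma_f^2);
3. expression: first-timepoint profiles Y_T1 ~ N(0, I); with decay treated as
   zero, Y_T2 = Y_T1 + X_T1 @ beta + eps, eps ~ N(0, noise_sd^2), emitted as
   paired time-series conditions with delta_t = 1;
4. orthology corruption removes a fraction of true pairs (false negatives)
   and injects false pairs among unpaired genes, with the false-positive rate
   expressed in units of the number of true pairs.

All randomness flows from one seed through named substreams, so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import OrthologyMap
from .data_model import ConditionMeta, ExpressionDataset
from .solver import NetworkCoefficients

__all__ = [
    "SimulationConfig",
    "generate_orthology",
    "generate_fused_networks",
    "simulate_expression",
    "corrupt_orthology",
    "generate_study",
]

# substream tags for the named-seed scheme
_STREAM_ORTH = 1
_STREAM_NET = 2
_STREAM_CORRUPT = 3
_STREAM_EXPR = 10  # + source index


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-source study.

    ``n_genes`` counts all genes including the ``n_tfs`` transcription
    factors. ``n_samples`` may be one integer (both sources) or a pair.
    ``sparsity`` is the probability that a fused coefficient group is zero;
    ``sigma_f`` the divergence noise sd between fused coefficients;
    ``fp_rate`` is expressed in units of the number of true ortholog pairs.
    """

    n_tfs: int = 10
    n_genes: int = 200
    n_sources: int = 2
    ortho_frac_tf: float = 0.75
    ortho_frac_gene: float = 0.75
    sparsity: float = 0.75
    sigma_f: float = 0.1
    n_samples: int | tuple[int, int] = 20
    noise_sd: float = 0.1
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources != 2:
            raise ValueError("the generator supports exactly two sources")
        if not (0 < self.n_tfs < self.n_genes):
            raise ValueError("need 0 < n_tfs < n_genes (n_genes counts TFs)")
        for name in ("ortho_frac_tf", "ortho_frac_gene", "sparsity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_f < 0 or self.noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.fp_rate < 0 or not (0 <= self.fn_rate <= 1):
            raise ValueError("fp_rate >= 0 and 0 <= fn_rate <= 1 required")

    @property
    def source_ids(self) -> tuple[str, str]:
        return ("s1", "s2")

    @property
    def tf_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        nontf = [f"G{i:04d}" for i in range(1, self.n_genes - self.n_tfs + 1)]
        return self.tf_ids + nontf

    def samples_for(self, source_index: int) -> int:
        if isinstance(self.n_samples, int):
            return self.n_samples
        return self.n_samples[source_index]


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _pair_pool(rng: np.random.Generator, pool: list[str], frac: float) -> list[tuple[str, str]]:
    """One-to-one random pairing of floor(frac * len(pool)) members across two sources."""
    k = int(np.floor(frac * len(pool)))
    left = list(rng.choice(pool, size=k, replace=False))
    right = list(rng.choice(pool, size=k, replace=False))
    return list(zip(left, right))


def generate_orthology(cfg: SimulationConfig) -> OrthologyMap:
    """Random one-to-one orthology covering the configured fractions of TFs and genes."""
    rng = _rng(cfg, _STREAM_ORTH)
    s1, s2 = cfg.source_ids
    nontf = [g for g in cfg.gene_ids if g not in cfg.tf_ids]
    pairs = []
    for ga, gb in _pair_pool(rng, cfg.tf_ids, cfg.ortho_frac_tf):
        pairs.append((s1, ga, s2, gb))
    for ga, gb in _pair_pool(rng, nontf, cfg.ortho_frac_gene):
        pairs.append((s1, ga, s2, gb))
    return OrthologyMap(pairs, truth={p if (p[0], p[1]) <= (p[2], p[3]) else (p[2], p[3], p[0], p[1]): True for p in pairs})


def generate_fused_networks(cfg: SimulationConfig, orth: OrthologyMap) -> NetworkCoefficients:
    """Draw the pair of true networks groupwise from the (true) orthology.

    Only genuinely orthologous pairs shape the networks; injected false pairs
    (see :func:`corrupt_orthology`) are a property of the *observed* orthology
    and leave the true coefficients untouched. Self-regulatory entries are
    structurally zero.
    """
    rng = _rng(cfg, _STREAM_NET)
    s1, s2 = cfg.source_ids
    tf_map: dict[tuple[str, str], tuple[str, str]] = {}
    gene_map: dict[tuple[str, str], tuple[str, str]] = {}
    for sa, ga, sb, gb in orth.pairs:
        if not orth.truth.get((sa, ga, sb, gb), True):
            continue
        m = tf_map if ga in cfg.tf_ids else gene_map
        m[(sa, ga)] = (sb, gb)
        m[(sb, gb)] = (sa, ga)

    betas = {
        s: pd.DataFrame(np.zeros((cfg.n_tfs, cfg.n_genes)), index=cfg.tf_ids, columns=cfg.gene_ids)
        for s in cfg.source_ids
    }
    filled: set[tuple[str, str, str]] = set()
    for s in cfg.source_ids:
        for tf in cfg.tf_ids:
            for gene in cfg.gene_ids:
                if tf == gene or (s, tf, gene) in filled:
                    continue
                group = [(s, tf, gene)]
                tf_partner = tf_map.get((s, tf))
                gene_partner = gene_map.get((s, gene)) if gene not in cfg.tf_ids else tf_map.get((s, gene))
                if tf_partner and gene_partner and tf_partner[0] == gene_partner[0]:
                    so, tfo = tf_partner
                    _, geneo = gene_partner
                    if tfo != geneo:
                        group.append((so, tfo, geneo))
                if rng.random() < cfg.sparsity:
                    values = [0.0] * len(group)
                else:
                    v = rng.normal(0.0, 1.0)
                    values = [v + rng.normal(0.0, cfg.sigma_f) for _ in group]
                for (gs, gtf, gg), val in zip(group, values):
                    betas[gs].at[gtf, gg] = val
                    filled.add((gs, gtf, gg))
    return NetworkCoefficients(betas)


def simulate_expression(
    network: pd.DataFrame, cfg: SimulationConfig, source_index: int
) -> ExpressionDataset:
    """Two-timepoint expression for one source under the decay-free dynamics.

    `network` is that source's true TF x gene weight matrix. Returns an
    :class:`ExpressionDataset` with paired time-series conditions
    (c{i}_t1 -> c{i}_t2, delta_t = 1); the design builder should be called
    with alpha = 0 (decay treated as zero).
    """
    rng = _rng(cfg, _STREAM_EXPR + source_index)
    n = cfg.samples_for(source_index)
    genes = cfg.gene_ids
    beta = network.loc[cfg.tf_ids, genes].to_numpy()
    y1 = rng.normal(size=(n, len(genes)))
    x1 = y1[:, [genes.index(t) for t in cfg.tf_ids]]
    y2 = y1 + x1 @ beta + rng.normal(0.0, cfg.noise_sd, size=y1.shape) if cfg.noise_sd > 0 else y1 + x1 @ beta
    values = np.empty((len(genes), 2 * n))
    meta = []
    cols = []
    for i in range(n):
        values[:, 2 * i] = y1[i]
        values[:, 2 * i + 1] = y2[i]
        c1, c2 = f"c{i:03d}_t1", f"c{i:03d}_t2"
        cols += [c1, c2]
        meta.append(ConditionMeta(c1, is_time_series=True))
        meta.append(ConditionMeta(c2, is_time_series=True, predecessor=c1, delta_t=1.0))
    df = pd.DataFrame(values, index=genes, columns=cols)
    return ExpressionDataset(
        source_id=cfg.source_ids[source_index], values=df, tf_ids=list(cfg.tf_ids), condition_meta=meta
    )


def corrupt_orthology(orth: OrthologyMap, cfg: SimulationConfig) -> OrthologyMap:
    """Apply false-negative removal and false-positive injection, keeping truth labels.

    Removes floor(fn_rate * n_true) true pairs uniformly at random, then adds
    round(fp_rate * n_true) false pairs per pool (TF-TF and gene-gene
    separately, rates in units of each pool's true-pair count) by randomly
    pairing currently unpaired members. False pairs never duplicate true ones.
    """
    rng = _rng(cfg, _STREAM_CORRUPT)
    s1, s2 = cfg.source_ids
    tf_set = set(cfg.tf_ids)
    pools = {
        "tf": [p for p in orth.pairs if p[1] in tf_set],
        "gene": [p for p in orth.pairs if p[1] not in tf_set],
    }
    kept: list[tuple[str, str, str, str]] = []
    truth: dict[tuple[str, str, str, str], bool] = {}
    new_pairs: list[tuple[str, str, str, str]] = []
    for pool_name, pairs in pools.items():
        n_true = len(pairs)
        n_remove = int(np.floor(cfg.fn_rate * n_true + 1e-9))
        remove_idx = set(rng.choice(n_true, size=n_remove, replace=False)) if n_remove else set()
        pool_kept = [p for i, p in enumerate(pairs) if i not in remove_idx]
        kept.extend(pool_kept)
        for p in pool_kept:
            truth[p] = True

        n_fp = int(round(cfg.fp_rate * n_true))
        if n_fp:
            members = cfg.tf_ids if pool_name == "tf" else [g for g in cfg.gene_ids if g not in tf_set]
            paired_1 = {p[1] for p in pool_kept if p[0] == s1} | {p[3] for p in pool_kept if p[2] == s1}
            paired_2 = {p[3] for p in pool_kept if p[2] == s2} | {p[1] for p in pool_kept if p[0] == s2}
            free_1 = [g for g in members if g not in paired_1]
            free_2 = [g for g in members if g not in paired_2]
            if n_fp > min(len(free_1), len(free_2)):
                raise ValueError(
                    f"cannot inject {n_fp} false {pool_name} pairs: only "
                    f"{min(len(free_1), len(free_2))} unpaired members available"
                )
            true_keys = {(p[1], p[3]) for p in pairs}
            left = list(rng.choice(free_1, size=n_fp, replace=False))
            right = list(rng.choice(free_2, size=n_fp, replace=False))
            for ga, gb in zip(left, right):
                if (ga, gb) in true_keys:  # resample collisions deterministically
                    alternatives = [g for g in free_2 if (ga, g) not in true_keys and g not in right]
                    if not alternatives:
                        raise ValueError("cannot place a false pair without duplicating a true pair")
                    gb = alternatives[int(rng.integers(len(alternatives)))]
                p = (s1, ga, s2, gb)
                new_pairs.append(p)
                truth[p] = False
    return OrthologyMap(kept + new_pairs, truth=truth)


def generate_study(cfg: SimulationConfig, outdir: str | Path, force: bool = False) -> dict[str, Path]:
    """Write a complete on-disk study fixture in the TSV formats the CLI consumes.

    Emits per-source expression, condition metadata, TF list and gold standard
    (the true network's nonzero signed edges), the (possibly corrupted)
    orthology with truth labels, the true networks, and a JSON manifest of all
    parameters. Returns the written paths.
    """
    from . import io as fio  # local import: io depends on the typed containers only

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    orth_true = generate_orthology(cfg)
    networks = generate_fused_networks(cfg, orth_true)
    orth = corrupt_orthology(orth_true, cfg) if (cfg.fp_rate > 0 or cfg.fn_rate > 0) else orth_true

    paths: dict[str, Path] = {}
    for i, s in enumerate(cfg.source_ids):
        ds = simulate_expression(networks.betas[s], cfg, i)
        paths[f"expression_{s}"] = fio.write_expression(ds, outdir / f"expression_{s}.tsv")
        paths[f"meta_{s}"] = fio.write_condition_meta(ds, outdir / f"meta_{s}.tsv")
        paths[f"tfs_{s}"] = fio.write_tf_list(ds.tf_ids, outdir / f"tfs_{s}.txt")
        gold = fio.gold_from_network(networks.betas[s], s)
        paths[f"gold_{s}"] = fio.write_prior(gold, outdir / f"gold_{s}.tsv")
        paths[f"true_network_{s}"] = fio.write_network(
            {s: networks.betas[s]}, outdir / f"true_network_{s}.tsv"
        )
    paths["orthology"] = fio.write_orthology(orth, outdir / "orthology.tsv")
    manifest = {"generator": "fusenet.simulate.generate_study", "config": asdict(cfg)}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = mpath
    return paths
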
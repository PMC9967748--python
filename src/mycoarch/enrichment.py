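"""Continuous-phenotype gene-set enrichment (weighted-KS GSEA).

Genes are ranked by the correlation of their expression with a continuous
phenotype — here, a microbe's CLR abundance across samples.  For each gene
set, a weighted Kolmogorov–Smirnov running sum walks the ranked list,
stepping up by the set gene's weighted metric mass at hits and down by
1/(N - N_hits) at misses; the enrichment score (ES) is the signed maximum
deviation from zero.  Significance comes from phenotype permutation: the
ranking and ES are recomputed under random phenotype relabelings, the
p-value is the same-sign tail fraction (+1 smoothed), NES normalizes ES by
the same-sign null mean magnitude, and the FDR q-value follows the
NES-based convention (pooled null NES vs observed NES tail ratio).  A
signature passes the reporting filter when p < 0.05 and FDR q < 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneExpressionTable, GeneSetCollection

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene_set", "n_genes", "ES", "NES", "p_perm", "fdr_q",
                  "n_perm", "seed", "pass_filter"]


@dataclass
class RankedList:
    """Genes ordered by non-increasing ranking metric."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be non-increasing")


def _correlations(z_expr: np.ndarray, z_pheno: np.ndarray) -> np.ndarray:
    """Pearson correlation of each standardized expression row with the
    standardized phenotype."""
    return z_expr @ z_pheno / z_pheno.size


def _standardize_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    safe = np.where(sd == 0, 1.0, sd)
    return (matrix - mean) / safe, flat


def rank_genes_by_phenotype(
    expr: GeneExpressionTable,
    phenotype: Sequence[float],
    metric: str = "pearson",
) -> RankedList:
    """Rank genes by correlation with a continuous phenotype.

    ``metric`` is ``pearson`` (default) or ``spearman``.  Zero-variance
    genes get metric 0 (logged); a zero-variance phenotype is an error.
    Ties break by gene symbol, ascending, so the ordering is deterministic.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.size != len(expr.samples):
        raise ValueError("phenotype length must match expression samples")
    if phenotype.size < 3:
        raise ValueError("at least 3 samples required")
    if np.std(phenotype) == 0:
        raise ValueError("phenotype has zero variance")

    values = expr.values.to_numpy(dtype=float)
    if metric == "spearman":
        values = stats.rankdata(values, axis=1)
        phenotype = stats.rankdata(phenotype)
    elif metric != "pearson":
        raise ValueError(f"unknown ranking metric {metric!r}")

    z_expr, flat = _standardize_rows(values)
    if flat.any():
        logger.info("%d zero-variance genes assigned metric 0", int(flat.sum()))
    z_pheno = (phenotype - phenotype.mean()) / phenotype.std()
    corr = _correlations(z_expr, z_pheno)
    corr[flat] = 0.0

    genes = np.array(expr.genes)
    symbol_rank = np.argsort(np.argsort(genes))
    order = np.lexsort((symbol_rank, -corr))
    return RankedList(genes=list(genes[order]), metric=corr[order])


def enrichment_score(
    ranked: RankedList,
    gene_set: Sequence[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running-sum profile.

    Hits step the running sum up by |metric|^weight normalized over hit
    genes; misses step down by 1/(N - N_hits).  ES is the running-sum value
    of largest magnitude.  Errors: gene set disjoint from the ranked list,
    or covering the whole list.
    """
    members = {g.upper() for g in gene_set}
    hits = np.array([g.upper() in members for g in ranked.genes])
    n = hits.size
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")

    hit_mass = np.abs(ranked.metric) ** weight
    hit_mass = np.where(hits, hit_mass, 0.0)
    denom = hit_mass.sum()
    if denom == 0:  # all hit metrics zero: fall back to equal hit mass
        hit_mass = hits / n_hits
        denom = 1.0
    steps = hit_mass / denom - (~hits) / (n - n_hits)
    running = np.cumsum(steps)
    es = float(np.clip(running[np.argmax(np.abs(running))], -1.0, 1.0))
    return es, running


def _es_for_order(
    order_metric: np.ndarray,
    hits: np.ndarray,
    weight: float,
) -> float:
    """ES from a hit mask aligned to an already-ordered metric vector."""
    n = hits.size
    n_hits = int(hits.sum())
    hit_mass = np.where(hits, np.abs(order_metric) ** weight, 0.0)
    denom = hit_mass.sum()
    if denom == 0:
        hit_mass = hits / n_hits
        denom = 1.0
    steps = hit_mass / denom - (~hits) / (n - n_hits)
    running = np.cumsum(steps)
    return float(np.clip(running[np.argmax(np.abs(running))], -1.0, 1.0))


def _signed_nes(es: float, null_es: np.ndarray) -> float:
    same = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
    scale = np.abs(same).mean() if same.size else np.nan
    if not np.isfinite(scale) or scale == 0:
        return np.nan
    return es / scale


def permutation_significance(
    expr: GeneExpressionTable,
    phenotype: Sequence[float],
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    metric: str = "pearson",
    alpha: float = 0.05,
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """Phenotype-permutation significance for every gene set.

    The null recomputes the full ranking and ES under ``n_perm`` random
    phenotype permutations (``n_perm`` >= 100).  Per set: one-sided
    same-sign tail p with +1 smoothing, NES = ES / mean(|null ES| of the
    same sign), and an NES-based FDR q pooling null NES across sets.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    phenotype = np.asarray(phenotype, dtype=float)

    values = expr.values.to_numpy(dtype=float)
    pheno = phenotype
    if metric == "spearman":
        values = stats.rankdata(values, axis=1)
        pheno = stats.rankdata(pheno)
    elif metric != "pearson":
        raise ValueError(f"unknown ranking metric {metric!r}")
    if np.std(pheno) == 0:
        raise ValueError("phenotype has zero variance")

    z_expr, flat = _standardize_rows(values)
    genes = np.array(expr.genes)
    symbol_rank = np.argsort(np.argsort(genes))
    set_names = list(gene_sets.sets)
    masks = {}
    n = genes.size
    for name in set_names:
        members = set(gene_sets.sets[name])
        mask = np.array([g in members for g in genes])
        if not mask.any():
            raise ValueError(f"gene set {name!r} shares no genes with expression")
        if mask.all():
            raise ValueError(f"gene set {name!r} covers the entire gene universe")
        masks[name] = mask

    def ranked_es(z_pheno: np.ndarray) -> dict[str, float]:
        corr = _correlations(z_expr, z_pheno)
        corr[flat] = 0.0
        order = np.lexsort((symbol_rank, -corr))
        ordered_metric = corr[order]
        return {
            name: _es_for_order(ordered_metric, masks[name][order], weight)
            for name in set_names
        }

    z_obs = (pheno - pheno.mean()) / pheno.std()
    observed = ranked_es(z_obs)

    null_es = {name: np.empty(n_perm) for name in set_names}
    for i in range(n_perm):
        perm = rng.permutation(pheno)
        z_perm = (perm - perm.mean()) / perm.std()
        es_i = ranked_es(z_perm)
        for name in set_names:
            null_es[name][i] = es_i[name]

    obs_nes = {name: _signed_nes(observed[name], null_es[name])
               for name in set_names}
    pooled_null_nes = np.concatenate([
        np.array([_signed_nes(e, null_es[name]) for e in null_es[name]])
        for name in set_names
    ])
    pooled_null_nes = pooled_null_nes[np.isfinite(pooled_null_nes)]
    obs_nes_values = np.array([obs_nes[name] for name in set_names])

    rows = []
    for name in set_names:
        es = observed[name]
        nulls = null_es[name]
        if es >= 0:
            same = nulls[nulls >= 0]
            p = (1.0 + (same >= es).sum()) / (1.0 + same.size)
        else:
            same = nulls[nulls < 0]
            p = (1.0 + (same <= es).sum()) / (1.0 + same.size)
        nes = obs_nes[name]
        q = _fdr_q(nes, obs_nes_values, pooled_null_nes)
        rows.append({
            "gene_set": name,
            "n_genes": int(masks[name].sum()),
            "ES": es,
            "NES": nes,
            "p_perm": p,
            "fdr_q": q,
            "n_perm": n_perm,
            "seed": seed,
            "pass_filter": bool(p < alpha and q < fdr_threshold),
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _fdr_q(nes: float, obs_nes: np.ndarray, null_nes: np.ndarray) -> float:
    """NES-based FDR: tail fraction of pooled null NES over tail fraction of
    observed NES, same sign as the score, capped at 1."""
    if not np.isfinite(nes):
        return np.nan
    obs = obs_nes[np.isfinite(obs_nes)]
    if nes >= 0:
        null_tail_den = (null_nes >= 0).sum()
        null_tail = (null_nes >= nes).sum() / null_tail_den if null_tail_den else 1.0
        obs_tail_den = (obs >= 0).sum()
        obs_tail = (obs >= nes).sum() / obs_tail_den if obs_tail_den else 1.0
    else:
        null_tail_den = (null_nes < 0).sum()
        null_tail = (null_nes <= nes).sum() / null_tail_den if null_tail_den else 1.0
        obs_tail_den = (obs < 0).sum()
        obs_tail = (obs <= nes).sum() / obs_tail_den if obs_tail_den else 1.0
    if obs_tail == 0:
        return 1.0
    return float(min(1.0, null_tail / obs_tail))
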
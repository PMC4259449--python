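"""Preranked gene-set enrichment analysis (GSEA).

Given a gene -> score ranking (e.g. per-gene t statistics from a two-group
comparison), the enrichment score (ES) of a gene set is the signed extremum
of a weighted running sum walked down the ranking: hits increment by
|score|^p normalized over the set, misses decrement uniformly. Significance
comes from a gene-label permutation null (random sets of matching size),
with a normalized-ES (NES) pooling FDR in the style of the original method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    n_genes: int
    leading_edge: list[str] = field(default_factory=list)


def _running_sum_es(order_scores: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, int]:
    """ES and extremum position for genes already sorted by decreasing score."""
    w = np.abs(order_scores) ** weight * hit
    wsum = w.sum()
    n = hit.size
    n_miss = n - int(hit.sum())
    if wsum == 0 or n_miss == 0:
        return 0.0, 0
    step = w / wsum - (~hit.astype(bool)) / n_miss
    walk = np.cumsum(step)
    i_max, i_min = int(np.argmax(walk)), int(np.argmin(walk))
    if walk[i_max] >= -walk[i_min]:
        return float(walk[i_max]), i_max
    return float(walk[i_min]), i_min


def preranked_gsea(ranking: pd.Series, sets: list[GeneSet], weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 17) -> list[EnrichmentResult]:
    """Run preranked GSEA for each gene set against a gene -> score ranking.

    Sets overlapping the ranking by fewer than 2 genes are skipped with a
    warning. The null permutes gene labels (draws random same-size gene
    sets); p is one-sided on the sign of the observed ES; FDR pools
    normalized ES over all sets and permutations.
    """
    ranking = pd.Series(ranking).dropna()
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break by gene symbol
    order = order.iloc[np.lexsort((order.index.astype(str), -order.to_numpy()))]
    genes = order.index.astype(str).str.strip().str.lower().to_numpy()
    scores = order.to_numpy(dtype=float)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[GeneSet, np.ndarray]] = []
    for s in sets:
        idx = sorted({pos_of[g.strip().lower()] for g in s.genes if g.strip().lower() in pos_of})
        if len(idx) < 2:
            warnings.warn(f"set {s.name!r} overlaps the ranking by {len(idx)} gene(s); skipped")
            continue
        kept.append((s, np.asarray(idx)))

    results: list[EnrichmentResult] = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: list[float] = []
    n = genes.size
    for s, idx in kept:
        hit = np.zeros(n)
        hit[idx] = 1.0
        es, extremum = _running_sum_es(scores, hit, weight)
        m = idx.size
        null = np.empty(n_perm)
        for b in range(n_perm):
            ridx = rng.choice(n, size=m, replace=False)
            rhit = np.zeros(n)
            rhit[ridx] = 1.0
            null[b], _ = _running_sum_es(scores, rhit, weight)
        same_sign = null[null * np.sign(es) > 0] if es != 0 else null
        if es == 0:
            p = 1.0
        else:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        null_nes = np.where(null >= 0,
                            null / pos_mean if np.isfinite(pos_mean) else 0.0,
                            null / neg_mean if np.isfinite(neg_mean) else 0.0)
        null_nes_pool.append(null_nes)
        obs_nes.append(nes)

        if es >= 0:
            le_pos = idx[idx <= extremum]
        else:
            le_pos = idx[idx >= extremum]
        leading = [str(order.index[i]) for i in le_pos]
        results.append(EnrichmentResult(s.name, es, nes, float(p), np.nan, m, leading))

    # FDR: fraction of pooled null NES at least as extreme vs fraction of
    # observed NES at least as extreme, capped at 1
    if results:
        pool = np.concatenate(null_nes_pool)
        obs = np.asarray(obs_nes)
        for r_i, res in enumerate(results):
            nes = obs[r_i]
            if nes >= 0:
                num_pool = np.mean(pool >= nes) if (pool >= 0).any() else 0.0
                num_obs = np.mean(obs >= nes)
            else:
                num_pool = np.mean(pool <= nes)
                num_obs = np.mean(obs <= nes)
            res.fdr = float(min(1.0, num_pool / num_obs)) if num_obs > 0 else 1.0
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p for r in results],
            "FDR": [r.fdr for r in results],
            "n_genes": [r.n_genes for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
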
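"""Preranked gene-set enrichment and decile-count analysis.

Weighted Kolmogorov-Smirnov running-sum enrichment over a z-ranked gene
list, with a gene-sampling permutation null for NES/p/q, plus per-decile
membership counts against a simulated random-set confidence band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from imgtx._utils import rng_from
from imgtx.connectivity_stats import bh_fdr
from imgtx.types import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "gsea_preranked",
    "decile_counts",
    "decile_null_ci",
]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: list
    sign: str  # '+' or '-'
    size: int


def _prepare_ranking(ranked: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sort by descending score (gene_id tiebreak) and return (genes, scores)."""
    df = ranked.sort_values(["z", "gene_id"], ascending=[False, True], kind="stable")
    scores = df["z"].to_numpy(float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    return df["gene_id"].to_numpy(object), scores


def _es_from_positions(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float):
    """Signed-extremum ES and the running sum for a boolean hit mask."""
    weights = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit_mask, weights, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~hit_mask).sum()
    if total_hit == 0 or n_miss == 0:
        raise ValueError("gene set must be a nonempty proper subset of the universe")
    steps = hit_w / total_hit - (~hit_mask) / n_miss
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    es = float(np.clip(es, -1.0, 1.0))
    return es, running, i_max, i_min


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list]:
    """Weighted KS enrichment score for one gene set.

    ``ranked`` needs columns gene_id and z. Hits increment the running sum
    proportionally to |z|**weight_exponent, misses decrement uniformly; ES is
    the extremum of larger magnitude (positive preferred on exact ties).
    Returns (ES, running curve, leading-edge gene ids).
    """
    genes, scores = _prepare_ranking(ranked)
    members = set(gene_set)
    hit = np.isin(genes, list(members & set(genes)))
    if not hit.any():
        raise ValueError("gene set does not intersect the ranked universe")
    es, running, i_max, i_min = _es_from_positions(scores, hit, weight_exponent)
    if es >= 0:
        leading = genes[: i_max + 1][hit[: i_max + 1]].tolist()
    else:
        leading = genes[i_min:][hit[i_min:]].tolist()
    return es, running, leading


def gsea_preranked(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Preranked enrichment across a collection with a gene-sampling null.

    Null ES per set size comes from random same-size gene draws; NES divides
    the observed ES by the mean |null ES| of matching sign; p uses the +1
    rule on the matching tail; q is BH across eligible sets.
    """
    genes, scores = _prepare_ranking(ranked)
    eligible, excluded = collection.filtered(genes, min_size, max_size)
    if excluded:
        logger.info("excluded %d sets outside [%d, %d] after universe filtering", len(excluded), min_size, max_size)
    if len(eligible) == 0:
        raise ValueError("no eligible gene sets")
    rng = rng_from(seed)
    G = len(genes)

    # one null per distinct set size, shared across same-size sets
    sizes = sorted({len(m) for _, m in eligible})
    null_es: dict[int, np.ndarray] = {}
    for size in sizes:
        es_null = np.empty(n_perm)
        for k in range(n_perm):
            hit = np.zeros(G, dtype=bool)
            hit[rng.choice(G, size=size, replace=False)] = True
            es_null[k], *_ = _es_from_positions(scores, hit, weight_exponent)
        null_es[size] = es_null

    results = []
    p_raw = []
    for name, members in eligible:
        es, _running, leading = enrichment_score(ranked, members, weight_exponent)
        null = null_es[len(members)]
        # p and NES are both computed against the same-sign null subset so
        # that null p-values stay uniform conditional on the observed sign
        if es >= 0:
            same = null[null >= 0]
            p = (1 + np.sum(same >= es)) / (1 + same.size)
        else:
            same = null[null < 0]
            p = (1 + np.sum(same <= es)) / (1 + same.size)
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        results.append(
            EnrichmentResult(
                set_name=name,
                es=float(es),
                nes=float(nes),
                p_value=float(p),
                q_value=np.nan,
                leading_edge=leading,
                sign="+" if es >= 0 else "-",
                size=len(members),
            )
        )
        p_raw.append(p)
    q, _ = bh_fdr(np.array(p_raw))
    for res, qv in zip(results, q):
        res.q_value = float(max(qv, res.p_value))
    return results


def decile_counts(ranked: pd.DataFrame, gene_set) -> np.ndarray:
    """Members of a gene set per rank decile of the ranked list (10 counts)."""
    genes, _scores = _prepare_ranking(ranked)
    G = len(genes)
    if G < 10:
        raise ValueError("need at least 10 ranked genes")
    decile_of = np.minimum(np.arange(G) * 10 // G, 9)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=G)
    return np.bincount(decile_of[hit], minlength=10)


def decile_null_ci(
    G: int, set_size: int, n_sim: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """95% band of per-decile counts for random size-matched gene sets.

    Simulates ``n_sim`` uniform draws and reports the 2.5th and 97.5th
    percentiles per decile. Returns (lower, upper) arrays of length 10.
    """
    if set_size > G:
        raise ValueError("set_size cannot exceed the universe size")
    rng = rng_from(seed)
    decile_of = np.minimum(np.arange(G) * 10 // G, 9)
    counts = np.empty((n_sim, 10))
    for k in range(n_sim):
        members = rng.choice(G, size=set_size, replace=False)
        counts[k] = np.bincount(decile_of[members], minlength=10)
    lower = np.percentile(counts, 2.5, axis=0)
    upper = np.percentile(counts, 97.5, axis=0)
    return lower, upper
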
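"""Competitive gene-set enrichment on a ranked gene list.

The statistic is a weighted running-sum (Kolmogorov-Smirnov-like) walk down
the genome-wide ranking: hitting a set member adds its weight share
``r_j^w / sum_hits r^w``; a miss subtracts ``1/(N - N_H)``. The enrichment
score ES is the maximum value the walk attains (one-sided, top-of-list
enrichment; the walk ends at exactly zero by construction, so ES >= 0).

The null is competitive: random same-size gene subsets of the ranking,
equivalent to permuting gene labels. FDR q-values follow the GSEA-style
normalised-ES ratio estimator. Empirical validation re-runs the analysis on
many random size-matched sets and asks whether the observed P and q beat a
stated fraction of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from gwaspath.types import EnrichmentConfig, GeneSetCollection, rng_for

#: chunk size (elements) for vectorised permutation sampling
_CHUNK_ELEMS = 20_000_000


@dataclass
class EnrichmentResult:
    """One gene set's enrichment outcome."""

    set_name: str
    n_genes_in_ranking: int
    es: float
    p_perm: float
    nes: float = np.nan
    fdr_q: float = np.nan
    frac_random_p: Optional[float] = None
    frac_random_fdr: Optional[float] = None
    validated: Optional[bool] = None
    removed_gene: Optional[str] = None
    n_dropped: int = 0
    null_es: Optional[np.ndarray] = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "set": self.set_name,
            "n_genes": self.n_genes_in_ranking,
            "es": self.es,
            "nes": self.nes,
            "p": self.p_perm,
            "fdr_q": self.fdr_q,
            "frac_random_p": self.frac_random_p,
            "frac_random_fdr": self.frac_random_fdr,
            "validated": self.validated,
        }


def _prepare_ranking(ranked: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    weights = ranked["weight"].to_numpy(dtype=float)
    if (np.diff(weights) > 1e-12).any():
        raise ValueError("ranking weights must be non-increasing")
    if (weights < 0).any():
        raise ValueError("ranking weights must be non-negative")
    index = {g: i for i, g in enumerate(ranked["gene_id"])}
    if len(index) != len(ranked):
        raise ValueError("duplicate gene ids in ranking")
    return weights, index


def _hit_positions(
    ranked: pd.DataFrame, gene_set: list[str]
) -> tuple[np.ndarray, int, dict[str, int]]:
    _, index = _prepare_ranking(ranked)
    hits = sorted(index[g] for g in gene_set if g in index)
    n_dropped = len(set(gene_set)) - len(hits)
    return np.asarray(hits, dtype=int), n_dropped, index

def _es_many(
    weights: np.ndarray, hit_pos: np.ndarray, w: float
) -> np.ndarray:
    """ES for each row of ``hit_pos`` (sorted 0-based hit ranks).

    The walk's maximum is attained immediately after a hit, so only hit
    positions need evaluating: after the (j+1)-th hit at rank p_j the walk
    equals cumw_j / W - (p_j - j) / (N - k). Rows whose hit weights sum to
    zero fall back to unit increments (the w=0 statistic).
    """
    if hit_pos.ndim == 1:
        hit_pos = hit_pos[None, :]
    N = weights.size
    k = hit_pos.shape[1]
    if not (1 <= k < N):
        raise ValueError("need 1 <= |set ∩ ranking| < N")
    rw = weights**w if w != 0 else np.ones_like(weights)
    hit_w = rw[hit_pos]
    cumw = np.cumsum(hit_w, axis=1)
    denom = cumw[:, -1:]
    zero = denom[:, 0] <= 0.0
    if zero.any():
        cumw[zero] = np.arange(1, k + 1)[None, :]
        denom = np.where(denom <= 0, float(k), denom)
    misses_before = hit_pos - np.arange(k)[None, :]
    running = cumw / denom - misses_before / (N - k)
    return running.max(axis=1)


def enrichment_score(
    ranked: pd.DataFrame,
    gene_set: list[str],
    w: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Observed ES and the full running-sum profile.

    ``ranked`` is the rank_genes frame (gene_id, p, weight). Set members
    absent from the ranking are dropped. The profile has one value per
    ranking position; its last entry is 0 to within rounding.
    """
    hits, n_dropped, index = _hit_positions(ranked, gene_set)
    weights, _ = _prepare_ranking(ranked)
    N = weights.size
    k = hits.size
    if k == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if k == N:
        raise ValueError("gene set covers the entire ranking")
    rw = weights**w if w != 0 else np.ones_like(weights)
    hit_mask = np.zeros(N, dtype=bool)
    hit_mask[hits] = True
    denom = rw[hits].sum()
    steps = np.where(hit_mask, (rw / denom if denom > 0 else 1.0 / k),
                     -1.0 / (N - k))
    profile = np.cumsum(steps)
    es = float(_es_many(weights, hits, w)[0])
    return es, profile


def _random_hit_positions(
    rng: np.random.Generator, n_draws: int, N: int, k: int
) -> np.ndarray:
    """``n_draws`` sorted size-k subsets of range(N), drawn uniformly."""
    out = np.empty((n_draws, k), dtype=int)
    rows_per_chunk = max(1, _CHUNK_ELEMS // N)
    for start in range(0, n_draws, rows_per_chunk):
        b = min(rows_per_chunk, n_draws - start)
        keys = rng.random((b, N))
        part = np.argpartition(keys, k, axis=1)[:, :k]
        out[start:start + b] = np.sort(part, axis=1)
    return out


def permutation_p(
    ranked: pd.DataFrame,
    set_size: int,
    observed_es: float,
    config: EnrichmentConfig,
    context: str = "perm",
) -> tuple[float, np.ndarray]:
    """Permutation P-value of an observed ES against random same-size sets.

    Draws ``config.n_perm`` uniform size-matched gene subsets, scores each,
    and returns p = (1 + #{ES* >= ES}) / (n_perm + 1) plus the null ES
    sample (used downstream for NES/FDR).
    """
    weights, _ = _prepare_ranking(ranked)
    N = weights.size
    if not (1 <= set_size < N):
        raise ValueError("set_size must satisfy 1 <= set_size < N")
    rng = rng_for(config.seed, "enrichment", context, set_size)
    hit_pos = _random_hit_positions(rng, config.n_perm, N, set_size)
    null_es = _es_many(weights, hit_pos, config.weight_exponent)
    p = (1 + int(np.count_nonzero(null_es >= observed_es))) / (config.n_perm + 1)
    return p, null_es


def fdr_q(
    es_values: np.ndarray,
    null_samples: list[np.ndarray],
    p_perms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """GSEA-style FDR q-values across a family of sets.

    Each set's ES and null sample are normalised by the mean positive null
    ES of that set's size (NES); q(set) is the pooled-null exceedance
    fraction over the observed exceedance fraction at the set's NES,
    clipped to [0, 1] and monotonised so a higher NES never has a larger q.
    With a single set the estimator collapses to its permutation P.

    Returns (nes, q).
    """
    es_values = np.asarray(es_values, dtype=float)
    m = es_values.size
    if m == 0 or len(null_samples) != m:
        raise ValueError("need one null sample per set")
    norms = np.empty(m)
    for i, null in enumerate(null_samples):
        positive = null[null > 0]
        if positive.size == 0:
            raise ValueError("no positive null ES; q undefined")
        norms[i] = positive.mean()
    nes = es_values / norms
    if m == 1:
        return nes, np.asarray([p_perms[0]], dtype=float)
    null_nes = np.concatenate([null / c for null, c in zip(null_samples, norms)])
    q = np.empty(m)
    for i in range(m):
        tail_null = np.mean(null_nes >= nes[i])
        tail_obs = np.mean(nes >= nes[i])
        q[i] = tail_null / tail_obs if tail_obs > 0 else 1.0
    q = np.clip(q, 0.0, 1.0)
    order = np.argsort(-nes, kind="mergesort")
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = q_sorted
    return nes, q


def gsea(
    ranked: pd.DataFrame,
    collections: GeneSetCollection | dict[str, list[str]],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Run the enrichment test for every candidate set and attach FDR q.

    Sets disjoint from the ranking or covering it entirely are rejected.
    """
    config = config or EnrichmentConfig()
    items = collections.items() if hasattr(collections, "items") else collections
    results: list[EnrichmentResult] = []
    for name, members in dict(items).items():
        hits, n_dropped, _ = _hit_positions(ranked, members)
        es, _ = enrichment_score(ranked, members, config.weight_exponent)
        p, null_es = permutation_p(ranked, hits.size, es, config, context=name)
        results.append(
            EnrichmentResult(
                set_name=name,
                n_genes_in_ranking=hits.size,
                es=es,
                p_perm=p,
                n_dropped=n_dropped,
                null_es=null_es,
            )
        )
    nes, q = fdr_q(
        np.array([r.es for r in results]),
        [r.null_es for r in results],
        np.array([r.p_perm for r in results]),
    )
    for r, nes_i, q_i in zip(results, nes, q):
        r.nes = float(nes_i)
        r.fdr_q = float(q_i)
    return results


@dataclass
class ValidationResult:
    fraction_exceeding_p: float
    fraction_exceeding_fdr: float
    validated: bool


def empirical_validation(
    ranked: pd.DataFrame,
    gene_set: list[str],
    observed: EnrichmentResult,
    config: EnrichmentConfig | None = None,
) -> ValidationResult:
    """Empirical check of an enrichment call against random gene sets.

    Draws ``config.n_random_sets`` random sets of the observed intersection
    size, analyses each with ``config.n_perm_validation`` permutations, and
    computes family-wise q-values across the random sets. The observed set
    validates when its P and q are smaller than those of at least
    ``config.empirical_criterion`` of the random sets.
    """
    config = config or EnrichmentConfig()
    weights, _ = _prepare_ranking(ranked)
    N = weights.size
    hits, _, _ = _hit_positions(ranked, gene_set)
    k = hits.size
    if not (1 <= k < N):
        raise ValueError("observed set must intersect the ranking properly")
    rng = rng_for(config.seed, "validation", observed.set_name, k)
    w = config.weight_exponent

    rand_pos = _random_hit_positions(rng, config.n_random_sets, N, k)
    rand_es = _es_many(weights, rand_pos, w)
    rand_p = np.empty(config.n_random_sets)
    null_samples: list[np.ndarray] = []
    for i in range(config.n_random_sets):
        perm_pos = _random_hit_positions(rng, config.n_perm_validation, N, k)
        null = _es_many(weights, perm_pos, w)
        rand_p[i] = (1 + int(np.count_nonzero(null >= rand_es[i]))) / (
            config.n_perm_validation + 1
        )
        null_samples.append(null)
    _, rand_q = fdr_q(rand_es, null_samples, rand_p)

    frac_p = float(np.mean(rand_p > observed.p_perm))
    q_obs = observed.fdr_q if np.isfinite(observed.fdr_q) else observed.p_perm
    frac_q = float(np.mean(rand_q > q_obs))
    return ValidationResult(
        fraction_exceeding_p=frac_p,
        fraction_exceeding_fdr=frac_q,
        validated=(frac_p >= config.empirical_criterion)
        and (frac_q >= config.empirical_criterion),
    )


def leave_one_out(
    ranked: pd.DataFrame,
    gene_set: list[str],
    config: EnrichmentConfig | None = None,
    set_name: str = "loo",
) -> EnrichmentResult:
    """Drop the set's top-ranked member and re-test the remainder.

    Guards against a single extreme gene driving an enrichment call: if the
    signal is spread over the set, the permutation P should survive removal
    of the best gene.
    """
    config = config or EnrichmentConfig()
    hits, n_dropped, index = _hit_positions(ranked, gene_set)
    if hits.size < 2:
        raise ValueError("need at least 2 set members in the ranking")
    rank_to_gene = {i: g for g, i in index.items()}
    removed = rank_to_gene[int(hits[0])]  # smallest rank = largest weight
    reduced = [g for g in gene_set if g != removed]
    es, _ = enrichment_score(ranked, reduced, config.weight_exponent)
    p, null_es = permutation_p(
        ranked, hits.size - 1, es, config, context=f"{set_name}_loo"
    )
    return EnrichmentResult(
        set_name=set_name,
        n_genes_in_ranking=hits.size - 1,
        es=es,
        p_perm=p,
        removed_gene=removed,
        n_dropped=n_dropped,
        null_es=null_es,
    )
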
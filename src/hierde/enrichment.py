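"""Gene-set enrichment: over-representation, pre-ranked GSEA, set similarity.

Over-representation analysis (ORA) is the hypergeometric upper-tail test of
the overlap between a selected gene list and each annotation set within a
gene universe, Bonferroni-corrected over the number of sets tested.

Pre-ranked GSEA walks a ranked gene list and accumulates a weighted
running sum: at position i,

    P_hit(i)  = Σ_{j≤i, j∈S} |r_j|^p / Σ_{j∈S} |r_j|^p
    P_miss(i) = #{j≤i, j∉S} / (N − N_S)

and the enrichment score ES is the value of P_hit − P_miss with maximal
absolute value. Significance comes from size-matched random gene sets
(gene-set permutation — phenotype permutation is unavailable for a
pre-ranked list): NES is ES divided by the mean |null ES| of matching sign,
the permutation p-value is the add-one-smoothed same-sign tail fraction,
and the FDR compares each observed NES against the pooled normalized null
NES distribution.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneSetCollection

__all__ = [
    "ora_test",
    "enrichment_score",
    "gsea_preranked",
    "set_similarity",
    "similarity_edges",
]


def ora_test(
    selected: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation test for each gene set.

    ``p_raw = P(X ≥ k)`` for X ~ Hypergeometric(N, K, n) with N the universe
    size, K the set size within the universe, n the selection size, and k
    the observed overlap. Selected genes outside the universe are dropped
    with a warning.
    """
    universe_set = dict.fromkeys(universe)  # dedup, keep order
    N = len(universe_set)
    if N == 0:
        raise ValueError("empty universe")
    sel = [g for g in dict.fromkeys(selected) if g in universe_set]
    dropped = len(set(selected)) - len(sel)
    if dropped:
        warnings.warn(f"{dropped} selected genes outside the universe were dropped",
                      stacklevel=2)
    if not sel:
        raise ValueError("no selected genes inside the universe")
    n = len(sel)
    sel_set = set(sel)
    T = len(sets)
    rows = []
    for name, members in sets.sets.items():
        in_universe = [g for g in members if g in universe_set]
        K = len(in_universe)
        k = len(sel_set.intersection(in_universe))
        # upper tail P(X >= k); survival function is P(X > k-1)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        p_raw = min(p_raw, 1.0)
        rows.append({
            "set": name, "universe_size": N, "set_size": K,
            "selected": n, "overlap": k, "p_raw": p_raw,
            "p_bonf": min(1.0, T * p_raw),
        })
    return pd.DataFrame(rows)


def _running_sum(order_scores: np.ndarray, hit: np.ndarray, exponent: float
                 ) -> np.ndarray:
    """P_hit − P_miss along an already-ranked list (boolean hit mask)."""
    N = order_scores.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == N:
        raise ValueError("gene set must hit some but not all of the ranked list")
    weight = np.abs(order_scores) ** exponent
    w_hit = np.where(hit, weight, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        # all hit scores are zero: fall back to unweighted steps
        w_hit = hit.astype(float)
        denom = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom
    p_miss = np.cumsum(~hit) / (N - n_hit)
    return p_hit - p_miss


def _select_es(running: np.ndarray) -> float:
    """Running-sum value of maximal |deviation|; exact/near ties (within
    1e-12) between the positive and negative extremum resolve positive."""
    mx = float(running.max())
    mn = float(running.min())
    return mx if mx + mn >= -1e-12 else mn


def enrichment_score(
    ranked_metric: pd.Series | Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov–Smirnov-like enrichment score for one gene set.

    ``ranked_metric`` is a gene → score mapping already ordered from the
    top of the ranking to the bottom (e.g. decreasing moderated t). Returns
    ``(ES, running_sum)`` where ES is the running-sum value of maximal
    absolute magnitude.
    """
    if isinstance(ranked_metric, pd.Series):
        genes = np.asarray(ranked_metric.index, dtype=object)
        scores = ranked_metric.to_numpy(dtype=float)
    else:
        genes = np.asarray([g for g, _ in ranked_metric], dtype=object)
        scores = np.asarray([s for _, s in ranked_metric], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking metric must be finite")
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=genes.size)
    running = _running_sum(scores, hit, exponent)
    return _select_es(running), running


def _null_es(scores: np.ndarray, set_size: int, n_perm: int, exponent: float,
             rng: np.random.Generator) -> np.ndarray:
    """ES distribution over random same-size gene sets, vectorized."""
    N = scores.size
    weight = np.abs(scores) ** exponent
    hits = np.zeros((n_perm, N), dtype=bool)
    for b in range(n_perm):  # sampling without replacement per permutation
        hits[b, rng.choice(N, size=set_size, replace=False)] = True
    w_hit = np.where(hits, weight[None, :], 0.0)
    denom = w_hit.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w_hit[zero] = hits[zero].astype(float)
        denom = w_hit.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(w_hit, axis=1) / denom
    p_miss = np.cumsum(~hits, axis=1) / (N - set_size)
    running = p_hit - p_miss
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx + mn >= -1e-12, mx, mn)


def gsea_preranked(
    ranked_metric: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    p_thresh: float = 0.01,
    fdr_thresh: float = 0.02,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection.

    ``ranked_metric`` maps gene → score; genes are ranked by decreasing
    score with ties broken by gene ID for determinism. Sets whose mapped
    size falls outside ``[min_size, max_size]`` are skipped. The returned
    table carries ES, NES, the permutation p-value, the pooled-null FDR q,
    and a ``significant`` flag at (p_thresh, fdr_thresh).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    metric = ranked_metric.astype(float)
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    scores = metric.loc[order].to_numpy()
    genes = np.asarray(order, dtype=object)
    n_tied = len(scores) - len(np.unique(scores))
    if n_tied > 0.5 * len(scores):
        warnings.warn("more than half the ranking metric is tied; ranks unstable",
                      stacklevel=2)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    records = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in sets.sets.items():
        mapped = [g for g in members if g in gene_pos]
        size = len(mapped)
        if size < min_size or size > max_size or size == len(genes):
            continue
        hit = np.zeros(len(genes), dtype=bool)
        hit[[gene_pos[g] for g in mapped]] = True
        running = _running_sum(scores, hit, exponent)
        es = _select_es(running)
        if size not in null_by_size:
            null_by_size[size] = _null_es(scores, size, n_perm, exponent, rng)
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes = np.nan
            p_perm = 1.0 / (1.0 + n_perm)
            null_norm = np.array([])
        else:
            mean_mag = np.abs(same_sign).mean()
            nes = es / mean_mag
            p_perm = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
            null_norm = same_sign / mean_mag
        records.append({"set": name, "size": size, "ES": es, "NES": nes,
                        "p_perm": p_perm, "_null_norm": null_norm})

    if not records:
        return pd.DataFrame(columns=["set", "size", "ES", "NES", "p_perm",
                                     "FDR", "significant"])

    # FDR per the pooled-null convention: for each observed NES compare the
    # fraction of pooled same-sign null NES at least as extreme with the
    # fraction of observed same-sign NES at least as extreme.
    pooled = np.concatenate([r["_null_norm"] for r in records]) \
        if any(r["_null_norm"].size for r in records) else np.array([])
    obs = np.array([r["NES"] for r in records])
    fdrs = []
    for r in records:
        nes = r["NES"]
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            null_side = pooled[pooled >= 0]
            obs_side = obs[np.isfinite(obs) & (obs >= 0)]
            tail_null = np.mean(null_side >= nes) if null_side.size else 0.0
            tail_obs = np.mean(obs_side >= nes)
        else:
            null_side = pooled[pooled < 0]
            obs_side = obs[np.isfinite(obs) & (obs < 0)]
            tail_null = np.mean(null_side <= nes) if null_side.size else 0.0
            tail_obs = np.mean(obs_side <= nes)
        fdrs.append(min(1.0, tail_null / tail_obs) if tail_obs > 0 else np.nan)

    out = pd.DataFrame([{k: v for k, v in r.items() if k != "_null_norm"}
                        for r in records])
    out["FDR"] = fdrs
    out["significant"] = (out["p_perm"] <= p_thresh) & (out["FDR"] <= fdr_thresh)
    return out


def set_similarity(set_a: Iterable[str], set_b: Iterable[str]
                   ) -> tuple[float, float, float]:
    """Jaccard, overlap and combined coefficients between two gene sets.

    combined = (jaccard + overlap) / 2 — the edge weight used for
    enrichment-map style graphs.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("sets must be non-empty")
    inter = len(a & b)
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return jaccard, overlap, 0.5 * jaccard + 0.5 * overlap


def similarity_edges(sets: GeneSetCollection, threshold: float = 0.375
                     ) -> pd.DataFrame:
    """Pairwise combined-similarity edges above a threshold (for graph tools)."""
    names = list(sets.sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            jac, ovl, comb = set_similarity(sets[a], sets[b])
            if comb >= threshold:
                rows.append({"set_a": a, "set_b": b, "jaccard": jac,
                             "overlap": ovl, "combined": comb})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard", "overlap",
                                       "combined"])
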
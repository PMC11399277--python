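"""Preranked gene-set enrichment on interaction p-value rankings.

Genes are scored by the largest -log10 interaction p over their assigned
CpGs (for eQTLs, by the gene's own interaction p) and ranked descending.
The enrichment score of a set is the signed maximal deviation of a weighted
Kolmogorov-Smirnov-like running sum: hits advance by |score|^w normalized
over in-set scores, misses retreat by 1/(N - |S|). Set-level p-values come
from random same-size gene-set permutations; NES normalizes by the mean
|null ES| of matching sign, and FDR q follows the sign-stratified
null-vs-observed NES ratio procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rank_genes", "enrichment_score", "gsea_permutation", "read_gmt"]


def rank_genes(assignments: pd.DataFrame, p_values: pd.Series | dict) -> pd.DataFrame:
    """Gene ranking from CpG-level interaction p-values.

    ``assignments`` has columns ``cpg_id`` and ``gene_id`` (a CpG may map
    to several genes; CpGs with no gene are dropped and counted).
    ``p_values`` maps cpg_id -> interaction p in (0, 1]. Returns a frame
    with ``gene_id`` and ``score`` (max -log10 p), sorted by descending
    score with ties broken by gene id.
    """
    p = pd.Series(p_values, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    df = assignments.dropna(subset=["gene_id"]).copy()
    n_dropped = len(assignments) - len(df)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("dropped %d CpG(s) with no assigned gene", n_dropped)
    df = df[df["cpg_id"].isin(p.index)]
    df["score"] = -np.log10(p.loc[df["cpg_id"]].to_numpy())
    ranked = (
        df.groupby("gene_id", as_index=False)["score"]
        .max()
        .sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return ranked


def enrichment_score(ranked: pd.DataFrame, gene_set, weight: float = 1.0):
    """Weighted KS-like enrichment score and the running-sum profile.

    ``ranked`` must be sorted by descending score. Returns ``(ES, profile)``
    where ES is the running-sum value of maximal absolute deviation from 0
    (keeping its sign).
    """
    genes = ranked["gene_id"].to_numpy()
    scores = np.abs(ranked["score"].to_numpy(dtype=float))
    hit = np.isin(genes, list(gene_set))
    if not hit.any():
        raise ValueError("gene set is disjoint from the ranked list")
    return _es_from_arrays(scores, hit, weight)


def _es_from_arrays(abs_scores: np.ndarray, hit: np.ndarray, weight: float):
    N = abs_scores.size
    n_hit = int(hit.sum())
    w = abs_scores[hit] ** weight
    denom = w.sum()
    steps = np.zeros(N)
    if denom > 0:
        steps[hit] = (abs_scores[hit] ** weight) / denom
    else:  # all in-set scores zero: equal hit steps
        steps[hit] = 1.0 / n_hit
    if N > n_hit:
        steps[~hit] = -1.0 / (N - n_hit)
    profile = np.cumsum(steps)
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i]), profile


def _es_only(abs_scores, hit_idx_sorted, weight, n):
    """ES from sorted hit positions without materializing the full profile."""
    w = abs_scores[hit_idx_sorted] ** weight
    denom = w.sum()
    n_hit = hit_idx_sorted.size
    if denom > 0:
        hit_cum = np.cumsum(w) / denom
    else:
        hit_cum = np.arange(1, n_hit + 1) / n_hit
    n_miss = n - n_hit
    miss_step = 1.0 / n_miss if n_miss else 0.0
    # value right after each hit, and the trough just before each hit
    misses_before = hit_idx_sorted - np.arange(n_hit)
    peak = hit_cum - misses_before * miss_step
    trough = np.concatenate(([0.0], hit_cum[:-1])) - misses_before * miss_step
    candidates = np.concatenate([peak, trough])
    i = int(np.argmax(np.abs(candidates)))
    return float(candidates[i])


def gsea_permutation(
    ranked: pd.DataFrame,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation p, NES and FDR q for every eligible gene set.

    Sets are restricted to ``min_size``-``max_size`` genes after
    intersection with the ranked universe. The null for each set size is
    the ES of ``n_perm`` random same-size gene sets drawn from the
    universe; ``p_perm = (1 + #{null ES of matching sign with |null| >=
    |ES|}) / (n_perm + 1)``. NES divides ES by the mean |null ES| of the
    same sign, and q applies the sign-stratified ratio FDR.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    genes = ranked["gene_id"].to_numpy()
    abs_scores = np.abs(ranked["score"].to_numpy(dtype=float))
    N = genes.size
    index = pd.Index(genes)

    rows = []
    null_nes_all: list[np.ndarray] = []
    for set_id in sorted(gene_sets):
        members = index.get_indexer([g for g in gene_sets[set_id] if g in index])
        members = np.unique(members[members >= 0])
        size = members.size
        if not (min_size <= size <= max_size):
            continue
        es = _es_only(abs_scores, np.sort(members), weight, N)
        null = np.empty(n_perm)
        for b in range(n_perm):
            idx = np.sort(rng.choice(N, size=size, replace=False))
            null[b] = _es_only(abs_scores, idx, weight, N)
        same_sign = null * np.sign(es) >= 0 if es != 0 else np.ones(n_perm, bool)
        extreme = same_sign & (np.abs(null) >= abs(es))
        p_perm = (1 + int(extreme.sum())) / (n_perm + 1)
        mean_same = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        null_nes = np.where(
            null >= 0,
            null / (np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan),
            null / (np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan),
        )
        null_nes_all.append(null_nes)
        rows.append({"set_id": set_id, "size": size, "ES": es, "NES": nes, "p_perm": p_perm})

    if not rows:
        return pd.DataFrame(columns=["set_id", "size", "ES", "NES", "p_perm", "q"])
    res = pd.DataFrame(rows)
    pooled_null = np.concatenate(null_nes_all)
    obs = res["NES"].to_numpy()
    q = np.empty(len(res))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = np.nan
            continue
        if nes >= 0:
            null_frac = np.mean(pooled_null[pooled_null >= 0] >= nes) if (pooled_null >= 0).any() else 0.0
            obs_frac = np.mean(obs[obs >= 0] >= nes)
        else:
            null_frac = np.mean(pooled_null[pooled_null < 0] <= nes) if (pooled_null < 0).any() else 0.0
            obs_frac = np.mean(obs[obs < 0] <= nes)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    res["q"] = q
    res["flag_fdr10"] = res["q"] < 0.10
    return res


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file: set_id <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
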
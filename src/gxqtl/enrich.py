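"""GWAS-variant QTL enrichment against a matched background.

Workflow: LD-prune the target variants, build a matched background 10x the
target size (MAF within +/-0.05 and matching quantile bins of any further
annotation properties, sampled without replacement), collapse each
variant's QTL p-values to the per-variant minimum, and compare the target
and background min-p distributions with a two-sided Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .stats import ks_two_sample

__all__ = ["ld_prune", "match_variants", "collapse_min_p", "enrichment_test"]


def ld_prune(geno: GenotypeMatrix, r2_threshold: float = 0.2, window: int = 500_000) -> list[str]:
    """Greedy LD pruning in position order.

    A variant is kept iff its genotype r^2 with every previously kept
    variant within ``window`` bp on the same chromosome is below
    ``r2_threshold``.
    """
    variants = geno.variants
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    G = geno.dosages
    mu = np.nanmean(G, axis=1, keepdims=True)
    Gi = np.where(np.isnan(G), mu, G)
    Gi = Gi - Gi.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Gi, Gi))

    kept: list[int] = []
    for i in order:
        ok = True
        for j in reversed(kept):
            if variants.at[j, "chrom"] != variants.at[i, "chrom"]:
                break
            if variants.at[i, "pos"] - variants.at[j, "pos"] > window:
                break
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = (Gi[i] @ Gi[j]) / (norms[i] * norms[j])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return [variants.at[i, "variant_id"] for i in kept]


def _bin_quintiles(values: np.ndarray) -> np.ndarray:
    qs = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(qs, values, side="right")


def match_variants(
    target_ids,
    pool: pd.DataFrame,
    properties: pd.DataFrame,
    n_per: int = 10,
    maf_tol: float = 0.05,
    seed: int = 0,
) -> list[str]:
    """Matched background set of exactly ``n_per * len(target_ids)`` variants.

    ``properties`` must contain ``variant_id`` and ``maf`` plus optional
    further annotation columns (e.g. gene proximity); ``pool`` is the frame
    of candidate variant_ids (disjoint from the targets). For each target,
    ``n_per`` candidates are sampled without replacement across the whole
    background whose MAF is within ``maf_tol`` absolute and whose other
    properties fall in the same quintile bin. Candidates with exactly equal
    properties are preferred. Raises if any target cannot be filled,
    naming the variant.
    """
    target_ids = list(target_ids)
    rng = np.random.default_rng(seed)
    props = properties.set_index("variant_id")
    pool_ids = [v for v in pool["variant_id"] if v not in set(target_ids)]
    if len(set(pool_ids)) != len(pool_ids):
        raise ValueError("pool contains duplicate variant ids")

    extra_cols = [c for c in props.columns if c != "maf"]
    bins = {}
    all_ids = list(target_ids) + pool_ids
    for c in extra_cols:
        vals = props.loc[all_ids, c].to_numpy(dtype=float)
        binned = _bin_quintiles(vals)
        bins[c] = dict(zip(all_ids, binned))

    pool_maf = props.loc[pool_ids, "maf"].to_numpy(dtype=float)
    available = dict.fromkeys(pool_ids, True)
    background: list[str] = []
    for t in target_ids:
        t_maf = float(props.at[t, "maf"])
        eligible, exact = [], []
        for pid, m in zip(pool_ids, pool_maf):
            if not available[pid]:
                continue
            if abs(m - t_maf) > maf_tol:
                continue
            if any(bins[c][pid] != bins[c][t] for c in extra_cols):
                continue
            eligible.append(pid)
            if m == t_maf and all(props.at[pid, c] == props.at[t, c] for c in extra_cols):
                exact.append(pid)
        chosen: list[str] = []
        if len(exact) >= n_per:
            chosen = list(rng.choice(exact, size=n_per, replace=False))
        else:
            chosen = list(exact)
            rest = [e for e in eligible if e not in set(exact)]
            need = n_per - len(chosen)
            if len(rest) < need:
                raise ValueError(
                    f"insufficient eligible pool for target {t!r} "
                    f"(maf={t_maf:.3f}): need {need}, have {len(rest)}"
                )
            chosen += list(rng.choice(rest, size=need, replace=False))
        for pid in chosen:
            available[pid] = False
        background.extend(chosen)
    assert len(background) == n_per * len(target_ids)
    return background


def collapse_min_p(results: pd.DataFrame, p_col: str = "p_2df") -> pd.Series:
    """Per-variant minimum p over all its QTL tests (indexed by variant_id)."""
    return results.groupby("variant_id")[p_col].min()


def enrichment_test(target_p, background_p) -> dict:
    """KS comparison of target vs background min-p distributions.

    Returns D, the two-sided p, and the median -log10 p of each set.
    """
    x = np.asarray(target_p, dtype=float)
    y = np.asarray(background_p, dtype=float)
    D, p = ks_two_sample(x, y)
    return {
        "D": D,
        "p": p,
        "n_target": x.size,
        "n_background": y.size,
        "median_neglog10_target": float(np.median(-np.log10(x))),
        "median_neglog10_background": float(np.median(-np.log10(y))),
    }
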
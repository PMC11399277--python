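"""Two-stage multiple-testing correction for cis-QTL maps.

Stage 1 corrects each feature's nominal p-values by the effective number of
independent cis variants, estimated from the eigenvalue spectrum of the
variant-variant genotype correlation matrix in consecutive position-ordered
windows (<= 200 variants each): the per-window effective count is the
smallest number of leading eigenvalues explaining >= 99% of the variance.
Stage 2 multiplies by the number of features tested. The final adjusted p
is capped by the plain Bonferroni correction over all pairs, so the
two-stage procedure is never more stringent than family-wise Bonferroni.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["effective_tests", "two_stage_adjust", "interaction_bonferroni", "format_threshold"]


def effective_tests(
    G: np.ndarray,
    positions: np.ndarray | None = None,
    var_threshold: float = 0.99,
    window_size: int = 200,
) -> int:
    """Effective number of independent tests for one feature's cis window.

    ``G`` is the variants x samples genotype submatrix (NaN allowed;
    mean-imputed for the correlation). Variants are ordered by position,
    split into consecutive windows of at most ``window_size``, and each
    window contributes the smallest k whose top-k eigenvalues of the
    correlation matrix reach ``var_threshold`` of the total. Constant
    variants are dropped (each contributes nothing to the correlation).
    Always returns a value in [1, M].
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 1:
        raise ValueError("need a variants x samples matrix with >= 1 variant")
    if positions is not None:
        order = np.argsort(np.asarray(positions), kind="stable")
        G = G[order]
    mu = np.nanmean(G, axis=1, keepdims=True)
    G = np.where(np.isnan(G), mu, G)
    sd = G.std(axis=1)
    keep = sd > 0
    G = G[keep]
    if G.shape[0] == 0:
        return 1
    m_eff = 0
    for s in range(0, G.shape[0], window_size):
        W = G[s : s + window_size]
        if W.shape[0] == 1:
            m_eff += 1
            continue
        R = np.corrcoef(W)
        lam = np.linalg.eigvalsh(R)[::-1]
        lam = np.clip(lam, 0.0, None)
        frac = np.cumsum(lam) / lam.sum()
        m_eff += int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    return max(1, min(m_eff, G.shape[0]))


def two_stage_adjust(
    results: pd.DataFrame,
    m_eff: dict,
    n_features: int,
    t_total: int,
    p_col: str = "p_2df",
) -> pd.DataFrame:
    """Two-stage adjusted p-values with the Bonferroni cap.

    ``results`` must carry ``feature_id`` and the nominal p column;
    ``m_eff`` maps feature_id -> effective test count. Adds columns
    p_stage1 (p * M_eff), p_stage2 (p_stage1 * n_features), p_bonf
    (p * t_total), p_final = min(p_stage2, p_bonf) and a ``significant``
    flag at final p < 0.05. All products are capped at 1.
    """
    if t_total < len(results):
        raise ValueError("t_total cannot be smaller than the number of supplied pairs")
    missing = set(results["feature_id"]) - set(m_eff)
    if missing:
        raise ValueError(f"no M_eff for features: {sorted(missing)[:5]}")
    out = results.copy()
    M = out["feature_id"].map(m_eff).to_numpy(dtype=float)
    p = out[p_col].to_numpy(dtype=float)
    out["m_eff"] = M
    out["p_stage1"] = np.minimum(1.0, p * M)
    out["p_stage2"] = np.minimum(1.0, out["p_stage1"] * n_features)
    out["p_bonf"] = np.minimum(1.0, p * t_total)
    out["p_final"] = np.minimum(out["p_stage2"], out["p_bonf"])
    out["cap_bound"] = out["p_bonf"] < out["p_stage2"]
    out["significant"] = out["p_final"] < 0.05
    return out


def interaction_bonferroni(n_significant_features: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold for interaction tests across significant features."""
    if n_significant_features < 1:
        raise ValueError("feature count must be >= 1")
    return alpha / n_significant_features


def format_threshold(x: float) -> float:
    """Round to 2 significant figures (the convention used in summaries)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    d = floor(log10(abs(x)))
    return round(x, -d + 1)
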
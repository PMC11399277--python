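"""Approximate-Bayes-factor colocalization.

Per-variant log approximate Bayes factors (lABFs) are computed from summary
statistics under a single-causal-variant-per-trait model: with z = beta/se,
V = se^2, prior effect variance W and shrinkage r = W/(V+W),

    lABF = 0.5 * (log(1 - r) + r * z^2).

Pairwise colocalization enumerates five hypotheses over a region of Q
shared variants -- H0 no association, H1/H2 one trait only, H3 two distinct
causal variants, H4 one shared causal variant -- with per-variant priors
p1, p2, p12. The three-trait extension enumerates every sharing
configuration (each trait null or causal at one variant, causal traits
grouped by shared variant) and reports in particular the posterior that
all three traits share a single causal variant. All sums are computed in
log space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "wakefield_abf",
    "coloc_pairwise",
    "coloc_multitrait",
    "call_significant_coloc",
    "W_QUANTITATIVE",
    "W_CASE_CONTROL",
]

W_QUANTITATIVE = 0.15**2
W_CASE_CONTROL = 0.2**2


def wakefield_abf(beta, se, trait_type: str = "quantitative", W: float | None = None) -> np.ndarray:
    """Per-variant log approximate Bayes factor(s) for association.

    ``W`` defaults to 0.15^2 for quantitative traits and 0.2^2 for
    case-control traits. Returns an array of lABFs (scalar input allowed).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    if W is None:
        W = {"quantitative": W_QUANTITATIVE, "case_control": W_CASE_CONTROL}[trait_type]
    V = se**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def _log_diff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, clipped at -inf when a ~ b."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pairwise(
    labf1, labf2, p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5
) -> dict:
    """Posterior probabilities PP.H0..PP.H4 over a region of shared variants.

    ``labf1``/``labf2`` must be aligned to the same Q >= 2 variants.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("lABF vectors must align to the same variant set")
    Q = l1.size
    if Q < 2:
        raise ValueError("need at least two variants")

    lS1 = logsumexp(l1)
    lS2 = logsumexp(l2)
    lS12 = logsumexp(l1 + l2)

    lw = {
        "H0": 0.0,
        "H1": np.log(p1) + lS1,
        "H2": np.log(p2) + lS2,
        "H3": np.log(p1) + np.log(p2) + _log_diff(lS1 + lS2, lS12),
        "H4": np.log(p12) + lS12,
    }
    keys = list(lw)
    arr = np.array([lw[k] for k in keys])
    pp = np.exp(arr - logsumexp(arr))
    return {f"PP.{k}": float(v) for k, v in zip(keys, pp)}


def coloc_multitrait(
    labf1,
    labf2,
    labf3,
    p_single: float = 1e-4,
    p_pair: float = 1e-5,
    p_triple: float = 1e-6,
) -> dict:
    """Posterior over all sharing configurations for three traits.

    Each trait is either null or causal at exactly one variant; causal
    traits sharing a variant are grouped. Configuration priors are
    per-variant: ``p_single`` for each trait-specific causal variant,
    ``p_pair`` for a variant shared by exactly two traits, ``p_triple``
    for a variant shared by all three. Returns the posterior mass of each
    configuration class, in particular ``PP.full_share`` (all three traits
    share one causal variant).
    """
    L = [np.asarray(x, dtype=float) for x in (labf1, labf2, labf3)]
    if not (L[0].shape == L[1].shape == L[2].shape):
        raise ValueError("lABF vectors must align to the same variant set")

    def S(idx):
        return logsumexp(sum(L[i] for i in idx))

    lp_s, lp_p, lp_t = np.log(p_single), np.log(p_pair), np.log(p_triple)
    terms: dict[str, float] = {"null": 0.0}
    # exactly one causal trait
    for t in range(3):
        terms[f"single_{t+1}"] = lp_s + S([t])
    pairs = [(0, 1), (0, 2), (1, 2)]
    # exactly two causal traits: shared or distinct variants
    for a, b in pairs:
        terms[f"pair_shared_{a+1}{b+1}"] = lp_p + S([a, b])
        terms[f"pair_distinct_{a+1}{b+1}"] = 2 * lp_s + _log_diff(S([a]) + S([b]), S([a, b]))
    # all three causal
    # one pair shared + third distinct (three choices of the pair)
    for a, b in pairs:
        c = ({0, 1, 2} - {a, b}).pop()
        terms[f"pair_{a+1}{b+1}_plus_{c+1}"] = lp_p + lp_s + _log_diff(
            S([a, b]) + S([c]), S([0, 1, 2])
        )
    # all distinct: sum over ordered distinct triples via inclusion-exclusion
    s1, s2, s3 = S([0]), S([1]), S([2])
    s12, s13, s23 = S([0, 1]), S([0, 2]), S([1, 2])
    s123 = S([0, 1, 2])
    pos = logsumexp([s1 + s2 + s3, np.log(2.0) + s123])
    neg = logsumexp([s12 + s3, s13 + s2, s23 + s1])
    terms["all_distinct"] = 3 * lp_s + _log_diff(pos, neg)
    # all three share one variant
    terms["full_share"] = lp_t + s123

    keys = list(terms)
    arr = np.array([terms[k] for k in keys])
    pp = np.exp(arr - logsumexp(arr))
    return {f"PP.{k}": float(v) for k, v in zip(keys, pp)}


def call_significant_coloc(
    coloc_results: pd.DataFrame,
    adjusted: pd.DataFrame,
    pp_col: str = "PP.H4",
    pp_cut: float = 0.8,
    adj_p_col: str = "p_final",
    adj_cut: float = 0.05,
) -> pd.DataFrame:
    """Flag colocalized loci passing both decision rules.

    A locus is flagged iff its posterior (``PP.H4`` pairwise, or the
    full-sharing posterior for triplets) strictly exceeds ``pp_cut`` AND
    its feature's baseline two-stage adjusted p is below ``adj_cut``.
    Joined on ``feature_id``.
    """
    if "feature_id" not in coloc_results.columns:
        raise KeyError("coloc results need a feature_id column to join on")
    best = adjusted.groupby("feature_id")[adj_p_col].min()
    missing = set(coloc_results["feature_id"]) - set(best.index)
    if missing:
        raise KeyError(f"no adjusted QTL result for features: {sorted(missing)[:5]}")
    out = coloc_results.copy()
    out["adj_p"] = out["feature_id"].map(best)
    out["flagged"] = (out[pp_col] > pp_cut) & (out["adj_p"] < adj_cut)
    return out
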
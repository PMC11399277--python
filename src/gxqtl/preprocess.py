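"""Normalization and filtering ahead of QTL mapping.

* ``rint`` — rank-based inverse normal transform with the Blom offset
  (c = 3/8), applied to CpG beta-values and to normalized expression.
* ``median_of_ratios`` — size-factor normalization of count matrices
  (the DESeq estimator).
* ``filter_low_expression`` — removes genes with ``count <= 10`` or
  ``TPM <= 1`` in at least 90% of samples.
* ``filter_variants`` — pooled-MAF filter for mapping (strict > 0.05) and
  a stricter per-ancestry MAF/missingness filter for post hoc robustness.

Each filter can emit a TSV audit table (id, statistic, decision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureMatrix, GenotypeMatrix

__all__ = [
    "rint",
    "median_of_ratios",
    "filter_low_expression",
    "filter_variants",
]

BLOM_C = 3.0 / 8.0


def rint(values) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset c = 3/8).

    ``out_i = Phi^{-1}((rank_i - c) / (n - 2c + 1))`` with average ranks for
    ties. Raises if all values are identical (the transform is undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rint expects a 1-d vector")
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    xs = x[finite]
    if np.all(xs == xs[0]):
        raise ValueError("all values identical; RINT undefined")
    n = xs.size
    ranks = sps.rankdata(xs, method="average")
    out = np.full_like(x, np.nan)
    out[finite] = sps.norm.ppf((ranks - BLOM_C) / (n - 2 * BLOM_C + 1))
    return out


def rint_rows(matrix: np.ndarray) -> np.ndarray:
    """Apply ``rint`` to every row of a feature x sample matrix."""
    return np.vstack([rint(row) for row in matrix])


def median_of_ratios(counts) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors and the normalized count matrix.

    For gene i, sample j: the pseudo-reference is the geometric mean of
    gene i across samples (over genes with all-positive counts); the size
    factor ``s_j`` is the median over those genes of ``k_ij / ref_i``;
    normalized values are ``k_ij / s_j``.
    """
    k = np.asarray(counts, dtype=float)
    if k.ndim != 2:
        raise ValueError("counts must be a gene x sample matrix")
    all_pos = np.all(k > 0, axis=1)
    if not all_pos.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logs = np.log(k[all_pos])
    log_ref = logs.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logs - log_ref, axis=0))
    return size_factors, k / size_factors


def filter_low_expression(
    counts, tpm, *, count_max: float = 10.0, tpm_max: float = 1.0, frac: float = 0.90
) -> tuple[np.ndarray, pd.DataFrame]:
    """Boolean keep-mask for genes plus an audit table.

    A gene is removed iff the fraction of samples with ``count <= count_max``
    is >= ``frac`` OR the fraction with ``TPM <= tpm_max`` is >= ``frac``
    (all thresholds inclusive).
    """
    counts = np.asarray(counts, dtype=float)
    tpm = np.asarray(tpm, dtype=float)
    if counts.shape != tpm.shape:
        raise ValueError("counts and TPM matrices must share shape")
    frac_low_count = (counts <= count_max).mean(axis=1)
    frac_low_tpm = (tpm <= tpm_max).mean(axis=1)
    remove = (frac_low_count >= frac) | (frac_low_tpm >= frac)
    audit = pd.DataFrame(
        {
            "frac_low_count": frac_low_count,
            "frac_low_tpm": frac_low_tpm,
            "decision": np.where(remove, "remove", "keep"),
        }
    )
    return ~remove, audit


def filter_variants(
    geno: GenotypeMatrix,
    ancestry,
    *,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
    mode: str = "mapping",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Variant keep-mask under the mapping or robust filtering rule.

    mapping: pooled MAF strictly greater than ``maf_min``.
    robust:  within every ancestry stratum, MAF >= ``maf_min`` AND
             missingness <= ``miss_max`` (both inclusive).
    """
    ancestry = np.asarray(ancestry)
    if len(ancestry) != geno.n_samples:
        raise ValueError("ancestry labels must match sample count")
    if mode not in ("mapping", "robust"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "mapping":
        maf = geno.maf()
        keep = maf > maf_min
        audit = pd.DataFrame(
            {
                "variant_id": geno.variants["variant_id"],
                "pooled_maf": maf,
                "decision": np.where(keep, "keep", "remove"),
            }
        )
        return keep, audit

    keep = np.ones(geno.n_variants, dtype=bool)
    cols = {"variant_id": geno.variants["variant_id"]}
    for label in pd.unique(ancestry):
        sel = ancestry == label
        if sel.sum() < 2:
            raise ValueError(f"ancestry stratum {label!r} has fewer than 2 samples")
        sub = geno.dosages[:, sel]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            af = np.nanmean(sub, axis=1) / 2.0
        maf = np.minimum(af, 1 - af)
        maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing stratum fails
        miss = np.isnan(sub).mean(axis=1)
        keep &= (maf >= maf_min) & (miss <= miss_max)
        cols[f"maf_{label}"] = maf
        cols[f"miss_{label}"] = miss
    audit = pd.DataFrame(cols)
    audit["decision"] = np.where(keep, "keep", "remove")
    return keep, audit


def tpm_from_counts(counts, lengths_bp) -> np.ndarray:
    """Transcripts-per-million from counts and gene lengths in bp."""
    k = np.asarray(counts, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)[:, None] / 1e3
    rate = k / L
    return rate / rate.sum(axis=0, keepdims=True) * 1e6
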
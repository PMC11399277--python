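"""Cis-pair enumeration and the four per-pair regression models.

For every variant-feature pair inside the 500 kb cis window, four ordinary
least squares models are fit on the RINT-transformed feature values:

1. baseline      y ~ g + covariates          (cases and controls pooled)
2. cases-only    y ~ g + covariates          (within smoking cases)
3. controls-only y ~ g + covariates          (within controls)
4. interaction   y ~ g + s + g:s + covariates

Wald t statistics use the residual-df t reference distribution. The
cases/controls fits feed the stratified 2DF joint test. Genotypes are coded
additively 0/1/2; missing calls are mean-imputed inside the design matrix
only. A rank-deficient design (e.g. a monomorphic variant within a stratum)
flags the fit as failed; p-values are set missing, never fabricated.

``map_qtls`` runs all pairs feature-by-feature with the covariates
residualized out once per feature (Frisch-Waugh-Lovell), which is
algebraically identical to the per-pair fits but orders of magnitude
faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureMatrix, GenotypeMatrix, SampleTable
from .stats import stratified_2df

__all__ = ["CisPair", "QtlFit", "enumerate_cis_pairs", "fit_qtl_models", "map_qtls"]

CIS_WINDOW = 500_000

MEQTL_COVARIATES = ["age", "sex", "cell_prop", "array_pc1", "pc1", "pc2"]
EQTL_COVARIATES = [
    "age", "sex", "exon_map_rate", "rrna_rate", "pc1", "pc2",
    "latent1", "latent2", "latent3", "latent4",
]


@dataclass(frozen=True)
class CisPair:
    variant_id: str
    feature_id: str
    distance: int  # bp; 0 if the variant lies inside the feature span


def enumerate_cis_pairs(
    geno: GenotypeMatrix,
    features: FeatureMatrix,
    window: int = CIS_WINDOW,
    anchor: str = "variant",
) -> list[CisPair]:
    """All variant-feature pairs within ``window`` bp (inclusive).

    ``anchor='variant'`` (meQTL): the CpG position (1-based) must satisfy
    |cpg_pos - variant_pos| <= window. ``anchor='gene_body'`` (eQTL): the
    minimum distance from the variant to the gene span must be <= window,
    0 when the variant lies inside the gene body. Pairs are returned sorted
    by (chrom, variant pos, feature id).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if anchor not in ("variant", "gene_body"):
        raise ValueError(f"unknown anchor {anchor!r}")
    pairs = []
    feats = features.features
    for chrom, fgrp in feats.groupby("chrom", sort=False):
        vmask = geno.variants["chrom"] == chrom
        vgrp = geno.variants[vmask]
        if len(vgrp) == 0:
            continue
        vpos = vgrp["pos"].to_numpy()
        vids = vgrp["variant_id"].to_numpy()
        f_start1 = fgrp["start"].to_numpy() + 1  # 1-based first bp
        f_end1 = fgrp["end"].to_numpy()  # 1-based last bp
        fids = fgrp["feature_id"].to_numpy()
        if anchor == "variant":
            # single-bp features: use the 1-based position of the feature
            d = np.abs(vpos[:, None] - f_start1[None, :])
        else:
            below = f_start1[None, :] - vpos[:, None]
            above = vpos[:, None] - f_end1[None, :]
            d = np.maximum(0, np.maximum(below, above))
        vi, fi = np.nonzero(d <= window)
        for a, b in zip(vi, fi):
            pairs.append((chrom, vpos[a], str(fids[b]), str(vids[a]), int(d[a, b])))
    pairs.sort(key=lambda r: (r[0], r[1], r[2]))
    return [CisPair(v, f, dist) for _, _, f, v, dist in pairs]


@dataclass
class ModelFit:
    beta: float = np.nan
    se: float = np.nan
    t: float = np.nan
    p: float = np.nan
    n: int = 0
    ok: bool = False


@dataclass
class QtlFit:
    """Per-pair results of the four models plus the stratified 2DF test."""

    variant_id: str
    feature_id: str
    baseline: ModelFit
    cases: ModelFit
    controls: ModelFit
    # interaction model: genotype main term and product term
    interaction_main: ModelFit
    interaction: ModelFit
    t_2df: float = np.nan
    p_2df: float = np.nan


def _impute_mean(g: np.ndarray) -> np.ndarray:
    m = np.isnan(g)
    if m.any():
        mu = np.nanmean(g)
        g = np.where(m, mu, g)
    return g


def _ols_term(y, X, col):
    """OLS of y on X; Wald stats for column ``col``. Returns ModelFit."""
    n, k = X.shape
    if n <= k:
        return ModelFit(n=n)
    q, r = np.linalg.qr(X)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        return ModelFit(n=n)  # rank deficient
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - k
    s2 = resid @ resid / df
    rinv = np.linalg.inv(r)
    cov = s2 * (rinv @ rinv.T)
    se = np.sqrt(cov[col, col])
    if not np.isfinite(se) or se <= 0:
        return ModelFit(n=n)
    t = coef[col] / se
    p = max(2 * sps.t.sf(abs(t), df), np.finfo(float).tiny)
    return ModelFit(float(coef[col]), float(se), float(t), float(p), n, True)


def _drop_constant(cols: np.ndarray) -> np.ndarray:
    keep = [j for j in range(cols.shape[1]) if np.ptp(cols[:, j]) > 0]
    return cols[:, keep]


def fit_qtl_models(
    g: np.ndarray,
    y: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    feature_id: str = "",
) -> QtlFit:
    """Fit the four models for one variant-feature pair.

    ``g`` may contain NaN (mean-imputed in the design only); ``y`` must be
    the RINT-transformed feature vector; ``status`` the 0/1 exposure.
    Covariates constant within a stratum are dropped from that stratum's
    model.
    """
    g = _impute_mean(np.asarray(g, dtype=float))
    y = np.asarray(y, dtype=float)
    s = np.asarray(status, dtype=float)
    C = np.empty((len(y), 0)) if covariates is None else np.asarray(covariates, dtype=float)

    ones = np.ones((len(y), 1))
    baseline = _ols_term(y, np.column_stack([ones, g[:, None], C]), 1)

    strata = {}
    for name, mask in (("cases", s == 1), ("controls", s == 0)):
        if mask.sum() < 3:
            strata[name] = ModelFit(n=int(mask.sum()))
            continue
        Cs = _drop_constant(C[mask]) if C.size else C[mask] if C.shape[1] else np.empty((mask.sum(), 0))
        gs = g[mask]
        if np.ptp(gs) == 0:
            strata[name] = ModelFit(n=int(mask.sum()))
            continue
        strata[name] = _ols_term(y[mask], np.column_stack([np.ones(mask.sum()), gs[:, None], Cs]), 1)

    Xint = np.column_stack([ones, g[:, None], s[:, None], (g * s)[:, None], C])
    inter_main = _ols_term(y, Xint, 1)
    inter = _ols_term(y, Xint, 3)

    fit = QtlFit(variant_id, feature_id, baseline, strata["cases"], strata["controls"], inter_main, inter)
    if strata["cases"].ok and strata["controls"].ok:
        r = stratified_2df(strata["cases"].beta, strata["cases"].se, strata["controls"].beta, strata["controls"].se)
        fit.t_2df, fit.p_2df = r.T, r.p_2df
    return fit


# ---------------------------------------------------------------------------
# vectorized mapping over all cis pairs
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on X (with intercept in X)."""
    q, _ = np.linalg.qr(X)
    return M - q @ (q.T @ M)


def _batch_slope(Gr: np.ndarray, yr: np.ndarray, df: int):
    """Per-variant slope/SE/t/p of yr on each row of Gr (all residualized)."""
    sxx = np.einsum("ij,ij->i", Gr, Gr)
    bad = sxx <= 1e-12
    sxx_safe = np.where(bad, 1.0, sxx)
    sxy = Gr @ yr
    beta = sxy / sxx_safe
    syy = yr @ yr
    s2 = np.maximum(syy - beta * sxy, 0.0) / df
    se = np.sqrt(s2 / sxx_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    for arr in (beta, se, t, p):
        arr[bad] = np.nan
    return beta, se, t, p


def map_qtls(
    geno: GenotypeMatrix,
    features: FeatureMatrix,
    samples: SampleTable,
    covariate_names: list[str],
    window: int = CIS_WINDOW,
    anchor: str = "variant",
    values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit all four models for every cis pair; one output row per pair.

    ``values`` overrides ``features.values`` (e.g. RINT-transformed); the
    matrix must be features x samples aligned with ``features``. Sample ids
    must agree across inputs. Returns the mapping table with per-model
    beta/se/t/p/n columns, interaction-model main and product terms, and
    the stratified 2DF statistic and p-value.
    """
    if list(geno.sample_id) != list(samples.sample_id) or list(features.sample_id) != list(samples.sample_id):
        g_extra = sorted(set(geno.sample_id) ^ set(samples.sample_id))
        f_extra = sorted(set(features.sample_id) ^ set(samples.sample_id))
        raise ValueError(
            f"sample ids are not harmonized; offending ids: genotype^samples={g_extra[:5]}, "
            f"features^samples={f_extra[:5]}"
        )
    Y = features.values if values is None else np.asarray(values, dtype=float)
    pairs = enumerate_cis_pairs(geno, features, window, anchor)
    if not pairs:
        return pd.DataFrame()

    vindex = pd.Index(geno.variants["variant_id"])
    findex = pd.Index(features.features["feature_id"])
    s = samples.status.astype(float)
    C = samples.covariates[covariate_names].to_numpy(dtype=float)
    n = len(s)
    ones = np.ones((n, 1))

    # group pairs by feature
    by_feat: dict[str, list[CisPair]] = {}
    for p_ in pairs:
        by_feat.setdefault(p_.feature_id, []).append(p_)

    G = geno.dosages
    mu_v = np.nanmean(G, axis=1, keepdims=True)
    G_imp = np.where(np.isnan(G), mu_v, G)

    masks = {"cases": s == 1, "controls": s == 0}
    X_base = np.column_stack([ones, C])
    X_int = np.column_stack([ones, C, s[:, None]])
    X_strat = {}
    for name, m in masks.items():
        Cs = _drop_constant(C[m]) if C.size else np.empty((int(m.sum()), 0))
        X_strat[name] = np.column_stack([np.ones(int(m.sum())), Cs])

    rows = []
    for fid, fpairs in by_feat.items():
        fi = findex.get_loc(fid)
        y = Y[fi]
        vidx = vindex.get_indexer([p_.variant_id for p_ in fpairs])
        Gf = G_imp[vidx]
        dist = [p_.distance for p_ in fpairs]

        out = {
            "variant_id": [p_.variant_id for p_ in fpairs],
            "feature_id": fid,
            "distance": dist,
        }

        # baseline
        yr = _residualize(y[:, None], X_base)[:, 0]
        Gr = _residualize(Gf.T, X_base).T
        b, se_, t, p = _batch_slope(Gr, yr, n - X_base.shape[1] - 1)
        out.update(beta_baseline=b, se_baseline=se_, t_baseline=t, p_baseline=p, n_baseline=n)

        # strata
        for name, m in masks.items():
            nm = int(m.sum())
            Xs = X_strat[name]
            ys = _residualize(y[m][:, None], Xs)[:, 0]
            Gs = Gf[:, m]
            const = np.ptp(Gs, axis=1) == 0
            Gsr = _residualize(Gs.T, Xs).T
            b, se_, t, p = _batch_slope(Gsr, ys, nm - Xs.shape[1] - 1)
            for arr in (b, se_, t, p):
                arr[const] = np.nan
            key = "cases" if name == "cases" else "controls"
            out.update(
                {f"beta_{key}": b, f"se_{key}": se_, f"t_{key}": t, f"p_{key}": p, f"n_{key}": nm}
            )

        # interaction model: two variant-specific columns g and g*s
        yr_i = _residualize(y[:, None], X_int)[:, 0]
        Gr_i = _residualize(Gf.T, X_int).T
        GSr_i = _residualize((Gf * s).T, X_int).T
        a11 = np.einsum("ij,ij->i", Gr_i, Gr_i)
        a12 = np.einsum("ij,ij->i", Gr_i, GSr_i)
        a22 = np.einsum("ij,ij->i", GSr_i, GSr_i)
        b1 = Gr_i @ yr_i
        b2 = GSr_i @ yr_i
        det = a11 * a22 - a12**2
        bad = det <= 1e-12 * np.maximum(a11 * a22, 1e-300)
        det_safe = np.where(bad, 1.0, det)
        cg = (a22 * b1 - a12 * b2) / det_safe
        cgs = (a11 * b2 - a12 * b1) / det_safe
        df_i = n - X_int.shape[1] - 2
        rss = np.maximum(yr_i @ yr_i - cg * b1 - cgs * b2, 0.0)
        s2 = rss / df_i
        se_g = np.sqrt(s2 * a22 / det_safe)
        se_gs = np.sqrt(s2 * a11 / det_safe)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_g, t_gs = cg / se_g, cgs / se_gs
        p_g = np.clip(2 * sps.t.sf(np.abs(t_g), df_i), np.finfo(float).tiny, 1.0)
        p_gs = np.clip(2 * sps.t.sf(np.abs(t_gs), df_i), np.finfo(float).tiny, 1.0)
        for arr in (cg, cgs, se_g, se_gs, t_g, t_gs, p_g, p_gs):
            arr[bad] = np.nan
        out.update(
            beta_g=cg, se_g=se_g, p_main=p_g,
            beta_gx=cgs, se_gx=se_gs, p_interaction=p_gs,
        )
        rows.append(pd.DataFrame(out))

    res = pd.concat(rows, ignore_index=True)
    T, p2 = stratified_2df(
        res["beta_cases"].to_numpy(), res["se_cases"].to_numpy(),
        res["beta_controls"].to_numpy(), res["se_controls"].to_numpy(),
    )
    res["t_2df"] = T
    res["p_2df"] = p2
    # keep deterministic pair order (chrom, variant pos, feature id)
    order = {(p_.variant_id, p_.feature_id): i for i, p_ in enumerate(pairs)}
    res["_ord"] = [order[(v, f)] for v, f in zip(res["variant_id"], res["feature_id"])]
    return res.sort_values("_ord").drop(columns="_ord").reset_index(drop=True)
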
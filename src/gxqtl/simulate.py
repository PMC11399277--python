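"""Synthetic cohorts with the statistical structure the QTL analysis assumes.

The generator emulates a postmortem brain cohort: two ancestry strata,
roughly one quarter smoking cases (case status derived from a simulated
cotinine biomarker against a 12 ng/mL threshold), LD-blocked biallelic
variants, CpG methylation beta-values and negative-binomial gene counts
with cis genetic effects within 500 kb, optional genotype-by-smoking
interaction effects, and GWAS summary statistics whose causal variant is
shared with, distinct from, or absent at a QTL locus.

LD is generated with a Gaussian copula: within a block, latent gametes are
multivariate normal with exchangeable correlation and are thresholded to
alleles at the ancestry-specific MAF quantile. Every generator is a pure
function of (config, seed); truth tables record each planted (variant,
feature, beta_g, beta_gx) so downstream power and calibration can be
computed without re-reading configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from .io import FeatureMatrix, GenotypeMatrix, GwasSumstats, SampleTable

__all__ = [
    "SimConfig",
    "SimulatedGenotypes",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_gwas",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Cohort composition follows the study design being emulated: 223 samples
    with ~23% smoking cases (52/223) and two ancestry strata at 46.6%/53.4%
    (104/119). Cotinine threshold 12 ng/mL separates active from passive
    smoking in the case definition.
    """

    seed: int
    n_samples: int = 223
    case_fraction: float = 52 / 223
    ancestry_fractions: tuple = (("AA", 104 / 223), ("EA", 119 / 223))
    n_variants: int = 500
    ld_block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    n_features: int = 50
    cis_effect: float = 0.5  # beta_g on the latent scale
    interaction_effect: float = 0.5  # beta_gx on the latent scale
    noise_sd: float = 1.0
    nb_dispersion: float = 0.1
    cotinine_threshold: float = 12.0  # ng/mL
    gwas_n: int = 10_000
    gwas_effect: float = 0.15
    # plumbing defaults (not study parameters)
    n_chromosomes: int = 1
    spacing_bp: int = 10_000
    missing_rate: float = 0.02
    prop_causal: float = 0.3
    prop_interaction: float = 0.1
    exposure_genotype_corr: float = 0.0  # optional gene-exposure correlation

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for _, f in self.ancestry_fractions:
            if not (0 < f < 1):
                raise ValueError("ancestry fractions must be in (0,1)")


@dataclass
class SimulatedGenotypes:
    """Genotypes plus the generative metadata later stages reuse."""

    geno: GenotypeMatrix
    ancestry: np.ndarray
    mafs: dict  # ancestry label -> per-variant MAF
    blocks: np.ndarray  # per-variant block id


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _variant_layout(cfg: SimConfig, rng) -> pd.DataFrame:
    per_chrom = int(np.ceil(cfg.n_variants / cfg.n_chromosomes))
    chroms, pos = [], []
    for c in range(cfg.n_chromosomes):
        n_c = min(per_chrom, cfg.n_variants - c * per_chrom)
        if n_c <= 0:
            continue
        jitter = rng.integers(1, max(2, cfg.spacing_bp // 2), size=n_c)
        p = 10_000 + np.arange(n_c) * cfg.spacing_bp + jitter
        chroms += [str(c + 1)] * n_c
        pos.append(p)
    pos = np.concatenate(pos)
    ids = [f"rs{c}_{p}" for c, p in zip(chroms, pos)]
    return pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": pos, "ref": "A", "alt": "G"}
    )


def simulate_genotypes(cfg: SimConfig) -> SimulatedGenotypes:
    """Draw LD-blocked hard-call genotypes for a two-ancestry cohort."""
    rng = _rng(cfg, 1)
    variants = _variant_layout(cfg, rng)
    m, n = cfg.n_variants, cfg.n_samples

    labels = [a for a, _ in cfg.ancestry_fractions]
    probs = np.array([f for _, f in cfg.ancestry_fractions], dtype=float)
    probs = probs / probs.sum()
    ancestry = rng.choice(labels, size=n, p=probs)

    # per-ancestry MAFs drawn independently per variant
    lo, hi = cfg.maf_range
    mafs = {a: rng.uniform(lo, hi, size=m) for a in labels}

    # block ids: consecutive runs of ld_block_size, cut at chromosome bounds
    blocks = np.zeros(m, dtype=int)
    b = 0
    i = 0
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for s in range(0, len(idx), cfg.ld_block_size):
            blocks[idx[s : s + cfg.ld_block_size]] = b
            b += 1

    r = cfg.within_block_r
    dosages = np.empty((m, n), dtype=float)
    for a in labels:
        cols = np.flatnonzero(ancestry == a)
        if cols.size == 0:
            continue
        thresh = sps.norm.ppf(mafs[a])[:, None]  # m x 1
        alleles = np.zeros((m, cols.size), dtype=float)
        for _gamete in range(2):
            u = rng.standard_normal((blocks.max() + 1, cols.size))
            e = rng.standard_normal((m, cols.size))
            z = np.sqrt(r) * u[blocks] + np.sqrt(1.0 - r) * e
            alleles += (z < thresh).astype(float)
        dosages[:, cols] = alleles

    if cfg.missing_rate > 0:
        mask = rng.random((m, n)) < cfg.missing_rate
        dosages[mask] = np.nan

    sample_id = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    geno = GenotypeMatrix(variants, sample_id, dosages)
    return SimulatedGenotypes(geno, ancestry, mafs, blocks)


def _covariates(cfg: SimConfig, sim: SimulatedGenotypes, rng) -> pd.DataFrame:
    n = sim.geno.n_samples
    cov = pd.DataFrame(
        {
            "age": rng.normal(46.0, 14.0, n),
            "sex": rng.binomial(1, 0.26, n).astype(float),  # 1 = female
            "cell_prop": rng.uniform(0.1, 0.5, n),
            "array_pc1": rng.standard_normal(n),
            "exon_map_rate": rng.normal(0.85, 0.02, n),
            "rrna_rate": rng.normal(0.01, 0.003, n).clip(1e-4),
        }
    )
    for k in range(1, 5):
        cov[f"latent{k}"] = rng.standard_normal(n)
    # genotype PCs from the simulated matrix itself
    X = sim.geno.dosages.copy()
    mu = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), mu, X) - mu
    sd = X.std(axis=1, keepdims=True)
    X = X / np.where(sd == 0, 1.0, sd)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    cov["pc1"] = vt[0] * np.sqrt(n)
    cov["pc2"] = vt[1] * np.sqrt(n)
    return cov


def simulate_phenotypes(
    sim: SimulatedGenotypes, cfg: SimConfig
) -> tuple[SampleTable, FeatureMatrix, FeatureMatrix, pd.DataFrame]:
    """Samples, methylation beta-values, gene counts, and the truth table.

    Methylation: latent ``y = b0 + beta_g*g + beta_gx*g*s + covariates +
    N(0, noise_sd)`` mapped through the inverse logit so beta-values lie in
    [0, 1]. Counts: negative binomial with the same terms in the log mean.
    The truth table lists every planted (variant, feature, beta_g, beta_gx).
    """
    rng = _rng(cfg, 2)
    geno = sim.geno
    n = geno.n_samples

    # exposure via the cotinine emulation
    p_case = np.full(n, cfg.case_fraction)
    if cfg.exposure_genotype_corr != 0.0:
        g0 = np.nan_to_num(geno.dosages[0], nan=1.0)
        p_case = np.clip(p_case + cfg.exposure_genotype_corr * (g0 - g0.mean()), 0.02, 0.98)
    smoker = rng.random(n) < p_case
    cotinine = np.where(
        smoker,
        np.exp(rng.normal(np.log(200.0), 0.6, n)),
        np.exp(rng.normal(0.0, 0.8, n)),
    )
    status = (cotinine > cfg.cotinine_threshold).astype(int)

    cov = _covariates(cfg, sim, rng)
    samples = SampleTable(geno.sample_id, status, sim.ancestry, cov)

    # feature placement: causal features sit within 500 kb of their variant
    n_feat = cfg.n_features
    n_causal = int(round(cfg.prop_causal * n_feat))
    n_inter = int(round(cfg.prop_interaction * n_feat))
    causal_feat = rng.choice(n_feat, size=n_causal, replace=False)
    inter_feat = set(rng.choice(causal_feat, size=min(n_inter, n_causal), replace=False))

    vpos = geno.variants["pos"].to_numpy()
    vchrom = geno.variants["chrom"].to_numpy()
    feat_chrom = np.empty(n_feat, dtype=object)
    feat_pos = np.empty(n_feat, dtype=int)
    causal_variant = np.full(n_feat, -1, dtype=int)
    for f in range(n_feat):
        if f in set(causal_feat):
            v = rng.integers(geno.n_variants)
            causal_variant[f] = v
            feat_chrom[f] = vchrom[v]
            feat_pos[f] = max(1, vpos[v] + rng.integers(-400_000, 400_000))
        else:
            v = rng.integers(geno.n_variants)
            feat_chrom[f] = vchrom[v]
            feat_pos[f] = max(1, vpos[v] + rng.integers(-400_000, 400_000))

    G = geno.dosages
    mu_v = np.nanmean(G, axis=1, keepdims=True)
    G_imp = np.where(np.isnan(G), mu_v, G)
    s = status.astype(float)

    age_z = (cov["age"] - cov["age"].mean()).to_numpy() / cov["age"].std()
    cov_basis = np.vstack([age_z, cov["sex"], (cov["cell_prop"] - 0.3) * 2, cov["array_pc1"]])
    cov_coef = rng.normal(0.0, 0.2, size=(n_feat, cov_basis.shape[0]))
    cov_term = cov_coef @ cov_basis

    truth_rows = []
    beta_g = np.zeros(n_feat)
    beta_gx = np.zeros(n_feat)
    for f in causal_feat:
        beta_g[f] = cfg.cis_effect
        beta_gx[f] = cfg.interaction_effect if f in inter_feat else 0.0
        truth_rows.append(
            {
                "variant_id": geno.variants["variant_id"].iloc[causal_variant[f]],
                "feature_id": None,  # filled below once ids exist
                "feature_index": int(f),
                "beta_g": beta_g[f],
                "beta_gx": beta_gx[f],
            }
        )

    gen_term = np.zeros((n_feat, n))
    for f in causal_feat:
        g = G_imp[causal_variant[f]]
        gen_term[f] = beta_g[f] * g + beta_gx[f] * g * s

    # methylation
    intercept_m = rng.uniform(-1.5, 1.5, n_feat)[:, None]
    latent = intercept_m + gen_term + cov_term + rng.normal(0, cfg.noise_sd, (n_feat, n))
    beta_values = expit(latent)
    cpg_ids = [f"cg{f:06d}" for f in range(n_feat)]
    meth_features = pd.DataFrame(
        {
            "feature_id": cpg_ids,
            "chrom": feat_chrom,
            "start": feat_pos - 1,  # BED 0-based for a single-bp CpG
            "end": feat_pos,
            "kind": "cpg",
        }
    )
    meth = FeatureMatrix(meth_features, geno.sample_id, beta_values, "beta")

    # gene counts: same genetic terms in the log mean, NB noise, library sizes
    base = np.exp(rng.uniform(np.log(50.0), np.log(500.0), n_feat))[:, None]
    libsize = np.exp(rng.normal(0.0, 0.2, n))[None, :]
    mu = base * libsize * np.exp(0.5 * gen_term + 0.3 * cov_term)
    r_nb = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu)).astype(float)
    gene_ids = [f"gene{f:05d}" for f in range(n_feat)]
    span = 20_000
    gene_features = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "chrom": feat_chrom,
            "start": np.maximum(0, feat_pos - 1),
            "end": feat_pos - 1 + span,
            "kind": "gene",
        }
    )
    genes = FeatureMatrix(gene_features, geno.sample_id, counts, "count")

    truth = pd.DataFrame(truth_rows)
    if len(truth):
        truth["cpg_id"] = [cpg_ids[i] for i in truth["feature_index"]]
        truth["gene_id"] = [gene_ids[i] for i in truth["feature_index"]]
        truth["feature_id"] = truth["cpg_id"]
        truth = truth[["variant_id", "feature_id", "cpg_id", "gene_id", "beta_g", "beta_gx"]]
    else:
        truth = pd.DataFrame(
            columns=["variant_id", "feature_id", "cpg_id", "gene_id", "beta_g", "beta_gx"]
        )
    return samples, meth, genes, truth


def simulate_gwas(
    sim: SimulatedGenotypes,
    scenario: str,
    causal_ids,
    cfg: SimConfig,
    trait: str = "smoking_initiation",
) -> GwasSumstats:
    """Per-variant GWAS summary statistics under a sharing scenario.

    A GWAS cohort of ``cfg.gwas_n`` individuals is drawn from the same LD
    model (pooled MAFs), a quantitative trait is generated from the
    scenario's causal variant(s), and each panel variant is regressed on
    the trait, so association decays with LD as in real summary statistics.
    ``scenario`` is one of 'shared' / 'distinct' / 'null'; for the first
    two, ``causal_ids`` name the causal variant(s) in the panel.
    """
    if scenario not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = _rng(cfg, 3)
    geno = sim.geno
    m = geno.n_variants
    n = cfg.gwas_n

    causal_idx = []
    if scenario != "null":
        vindex = pd.Index(geno.variants["variant_id"])
        for vid in causal_ids:
            i = vindex.get_indexer([vid])[0]
            if i < 0:
                raise ValueError(f"causal variant {vid!r} absent from panel")
            causal_idx.append(int(i))

    maf = np.mean(np.vstack([sim.mafs[a] for a in sim.mafs]), axis=0)
    thresh = sps.norm.ppf(maf)[:, None]
    r = cfg.within_block_r
    blocks = sim.blocks
    Gg = np.zeros((m, n), dtype=float)
    for _gamete in range(2):
        u = rng.standard_normal((blocks.max() + 1, n))
        e = rng.standard_normal((m, n))
        z = np.sqrt(r) * u[blocks] + np.sqrt(1.0 - r) * e
        Gg += (z < thresh).astype(float)

    y = rng.standard_normal(n)
    for i in causal_idx:
        y = y + cfg.gwas_effect * Gg[i]

    Gc = Gg - Gg.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", Gc, Gc)
    sxx = np.where(sxx == 0, np.nan, sxx)
    sxy = Gc @ yc
    beta = sxy / sxx
    syy = yc @ yc
    s2 = (syy - beta * sxy) / (n - 2)
    se = np.sqrt(s2 / sxx)
    tstat = beta / se
    p = 2 * sps.t.sf(np.abs(tstat), n - 2)
    table = pd.DataFrame(
        {
            "variant_id": geno.variants["variant_id"],
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "n": n,
        }
    ).dropna(subset=["beta", "se"])
    return GwasSumstats(trait, table.reset_index(drop=True))
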
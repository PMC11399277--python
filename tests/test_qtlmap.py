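"""Cis-pair enumeration and the four regression models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gxqtl.io import FeatureMatrix, GenotypeMatrix, SampleTable
from gxqtl.qtlmap import enumerate_cis_pairs, fit_qtl_models, map_qtls
from gxqtl.preprocess import rint_rows


def _features(rows, kind="cpg", n_samples=4):
    feats = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])
    feats["kind"] = kind
    vals = np.tile(np.linspace(0.2, 0.8, n_samples), (len(feats), 1))
    return FeatureMatrix(feats, np.array([f"s{i}" for i in range(n_samples)], dtype=object), vals, "beta")


class TestEnumerate:
    def test_window_boundary_inclusive(self, tiny_genotypes):
        # variant at 1,000,000; CpG 1-based position 1,500,000 -> paired
        fm = _features([("cpgA", "1", 1_499_999, 1_500_000)])
        pairs = enumerate_cis_pairs(tiny_genotypes, fm, anchor="variant")
        assert ("v1", "cpgA") in {(p.variant_id, p.feature_id) for p in pairs}
        d = {p.variant_id: p.distance for p in pairs if p.feature_id == "cpgA"}
        assert d["v1"] == 500_000

    def test_one_bp_past_window_excluded(self, tiny_genotypes):
        fm = _features([("cpgB", "1", 1_500_000, 1_500_001)])  # pos 1,500,001
        pairs = enumerate_cis_pairs(tiny_genotypes, fm, anchor="variant")
        assert all(not (p.variant_id == "v1" and p.feature_id == "cpgB") for p in pairs)

    def test_variant_inside_gene_body_distance_zero(self, tiny_genotypes):
        fm = _features([("geneA", "1", 900_000, 1_100_000)], kind="gene")
        pairs = enumerate_cis_pairs(tiny_genotypes, fm, anchor="gene_body")
        d = {p.variant_id: p.distance for p in pairs}
        assert d["v1"] == 0

    def test_nonpositive_window_rejected(self, tiny_genotypes):
        fm = _features([("cpgA", "1", 10, 11)])
        with pytest.raises(ValueError):
            enumerate_cis_pairs(tiny_genotypes, fm, window=0)

    def test_sorted_by_chrom_pos_feature(self, small_cohort):
        sim = small_cohort["sim"]
        pairs = enumerate_cis_pairs(sim.geno, small_cohort["meth"])
        pos = {v: p for v, p in zip(sim.geno.variants["variant_id"], sim.geno.variants["pos"])}
        keys = [(pos[p.variant_id], p.feature_id) for p in pairs]
        assert keys == sorted(keys)


class TestFitModels:
    def test_closed_form_slope(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0.1, -0.1, 1.1, 0.9, 2.1, 1.9])
        s = np.array([0, 1, 0, 1, 0, 1])
        fit = fit_qtl_models(g, y, s)
        assert fit.baseline.beta == pytest.approx(1.0)

    def test_noise_free_interaction_recovery(self):
        # controls y = g, cases y = 2 g  ->  beta_g = 1, beta_gx = 1
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 40).astype(float)
        s = np.repeat([0, 1], 20).astype(float)
        y = g * (1.0 + s)
        fit = fit_qtl_models(g, y, s)
        assert fit.interaction_main.beta == pytest.approx(1.0, abs=1e-10)
        assert fit.interaction.beta == pytest.approx(1.0, abs=1e-10)
        assert fit.cases.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.controls.beta == pytest.approx(1.0, abs=1e-10)

    def test_constant_genotype_in_stratum_flags_failure(self):
        g = np.array([0, 0, 0, 0, 1, 2, 1, 0], dtype=float)
        s = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y = np.arange(8.0)
        fit = fit_qtl_models(g, y, s)
        assert not fit.cases.ok and np.isnan(fit.cases.p)
        assert np.isnan(fit.p_2df)  # 2DF marked missing, never fabricated

    def test_missing_genotype_mean_imputed_in_design_only(self):
        g = np.array([0, 1, np.nan, 2, 1, 0], dtype=float)
        y = np.array([0.0, 1.0, 0.5, 2.0, 1.2, 0.1])
        s = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_qtl_models(g, y, s)
        assert fit.baseline.ok
        assert np.isnan(g[2])  # caller's array untouched

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        n, reps = 300, 400
        g = rng.integers(0, 3, n).astype(float)
        s = (rng.random(n) < 0.25).astype(int)
        ps = []
        for _ in range(reps):
            y = rng.standard_normal(n)
            ps.append(fit_qtl_models(g, y, s).baseline.p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_baseline_beta_between_stratum_betas(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 80
            g = rng.integers(0, 3, n).astype(float)
            s = np.tile([0, 1], n // 2).astype(float)
            y = 0.4 * g + 0.3 * g * s + rng.standard_normal(n)
            fit = fit_qtl_models(g, y, s)
            lo, hi = sorted([fit.cases.beta, fit.controls.beta])
            assert lo - 0.15 <= fit.baseline.beta <= hi + 0.15

    def test_p_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(9)
        n = 60
        g = rng.integers(0, 3, n).astype(float)
        s = (rng.random(n) < 0.3).astype(int)
        C = rng.standard_normal((n, 2))
        y = 0.3 * g + C @ [0.5, -0.2] + rng.standard_normal(n)
        f1 = fit_qtl_models(g, y, s, C)
        f2 = fit_qtl_models(g, y, s, C * [100.0, 0.01] + 7.0)
        assert f1.baseline.p == pytest.approx(f2.baseline.p, rel=1e-9)
        assert f1.interaction.p == pytest.approx(f2.interaction.p, rel=1e-9)


class TestMapQtls:
    def test_matches_per_pair_fits(self, small_cohort):
        """Vectorized mapping equals the per-pair OLS path on every column."""
        sim, samples, meth = (small_cohort[k] for k in ("sim", "samples", "meth"))
        covs = ["age", "sex", "cell_prop", "array_pc1", "pc1", "pc2"]
        vals = rint_rows(meth.values)
        res = map_qtls(sim.geno, meth, samples, covs, values=vals)
        C = samples.covariates[covs].to_numpy()
        vindex = pd.Index(sim.geno.variants["variant_id"])
        findex = pd.Index(meth.features["feature_id"])
        rng = np.random.default_rng(1)
        for i in rng.choice(len(res), size=25, replace=False):
            row = res.iloc[i]
            g = sim.geno.dosages[vindex.get_loc(row["variant_id"])]
            y = vals[findex.get_loc(row["feature_id"])]
            fit = fit_qtl_models(g, y, samples.status, C)
            assert row["beta_baseline"] == pytest.approx(fit.baseline.beta, rel=1e-8)
            assert row["se_baseline"] == pytest.approx(fit.baseline.se, rel=1e-8)
            if fit.cases.ok:
                assert row["beta_cases"] == pytest.approx(fit.cases.beta, rel=1e-8)
                assert row["p_cases"] == pytest.approx(fit.cases.p, rel=1e-6)
            if fit.controls.ok:
                assert row["beta_controls"] == pytest.approx(fit.controls.beta, rel=1e-8)
            assert row["beta_gx"] == pytest.approx(fit.interaction.beta, rel=1e-8)
            assert row["p_interaction"] == pytest.approx(fit.interaction.p, rel=1e-6)
            assert row["p_main"] == pytest.approx(fit.interaction_main.p, rel=1e-6)
            if fit.cases.ok and fit.controls.ok:
                assert row["p_2df"] == pytest.approx(fit.p_2df, rel=1e-8)

    def test_matches_statsmodels_oracle(self):
        """Independent cross-check of the baseline and interaction fits."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 90
        g = rng.integers(0, 3, n).astype(float)
        s = (rng.random(n) < 0.3).astype(float)
        C = rng.standard_normal((n, 3))
        y = 0.5 * g + 0.4 * g * s + C @ [0.2, -0.1, 0.3] + rng.standard_normal(n)
        fit = fit_qtl_models(g, y, s, C)
        X = sm.add_constant(np.column_stack([g, C]))
        ref = sm.OLS(y, X).fit()
        assert fit.baseline.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.baseline.se == pytest.approx(ref.bse[1], rel=1e-10)
        assert fit.baseline.p == pytest.approx(ref.pvalues[1], rel=1e-10)
        Xi = sm.add_constant(np.column_stack([g, s, g * s, C]))
        refi = sm.OLS(y, Xi).fit()
        assert fit.interaction.beta == pytest.approx(refi.params[3], rel=1e-10)
        assert fit.interaction.p == pytest.approx(refi.pvalues[3], rel=1e-10)
        assert fit.interaction_main.p == pytest.approx(refi.pvalues[1], rel=1e-10)

    def test_mismatched_sample_ids_rejected(self, small_cohort):
        sim, samples, meth = (small_cohort[k] for k in ("sim", "samples", "meth"))
        bad = sim.geno.subset_samples(list(sim.geno.sample_id[::-1]))
        with pytest.raises(ValueError, match="not harmonized"):
            map_qtls(bad, meth, samples, ["age"])
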
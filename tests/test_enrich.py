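"""LD pruning, matched backgrounds, min-p collapse, KS enrichment."""

import numpy as np
import pandas as pd
import pytest

from gxqtl.enrich import collapse_min_p, enrichment_test, ld_prune, match_variants
from gxqtl.io import GenotypeMatrix


def _geno_from(dosages, positions=None):
    m = len(dosages)
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {"variant_id": [f"v{i}" for i in range(m)], "chrom": "1", "pos": pos,
         "ref": "A", "alt": "G"}
    )
    samples = np.array([f"s{i}" for i in range(len(dosages[0]))], dtype=object)
    return GenotypeMatrix(variants, samples, np.asarray(dosages, dtype=float))


class TestLdPrune:
    def test_identical_variants_keep_one(self):
        g = np.tile([0.0, 1, 2, 1, 0, 2], (4, 1))
        assert ld_prune(_geno_from(g)) == ["v0"]

    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(5, 3000)).astype(float)
        assert len(ld_prune(_geno_from(g))) == 5

    def test_greedy_hand_trace(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 2000).astype(float)
        v2 = base.copy()
        flip = rng.random(2000) < 0.02
        v2[flip] = rng.integers(0, 3, flip.sum())  # r2(v0,v1) ~ 0.95
        v3 = rng.integers(0, 3, 2000).astype(float)
        kept = ld_prune(_geno_from([base, v2, v3]))
        assert kept == ["v0", "v2"]

    def test_no_retained_pair_above_threshold(self, small_cohort):
        geno = small_cohort["sim"].geno
        kept = ld_prune(geno, r2_threshold=0.2)
        sub = geno.subset_variants(kept)
        G = np.where(np.isnan(sub.dosages), np.nanmean(sub.dosages, axis=1, keepdims=True), sub.dosages)
        R = np.corrcoef(G)
        pos = sub.variants["pos"].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(pos[i] - pos[j]) <= 500_000 and sub.variants["chrom"][i] == sub.variants["chrom"][j]:
                    assert R[i, j] ** 2 < 0.2 + 1e-9


class TestMatchVariants:
    def _props(self, n, rng, maf=None):
        return pd.DataFrame(
            {
                "variant_id": [f"p{i}" for i in range(n)],
                "maf": rng.uniform(0.05, 0.5, n) if maf is None else maf,
            }
        )

    def test_background_is_exact_multiple(self):
        rng = np.random.default_rng(0)
        n_target = 305
        props = pd.concat(
            [
                pd.DataFrame({"variant_id": [f"t{i}" for i in range(n_target)],
                              "maf": rng.uniform(0.1, 0.4, n_target)}),
                self._props(8000, rng),
            ]
        )
        pool = pd.DataFrame({"variant_id": [f"p{i}" for i in range(8000)]})
        bg = match_variants([f"t{i}" for i in range(n_target)], pool, props, n_per=10, seed=3)
        assert len(bg) == 3050
        assert len(set(bg)) == 3050  # without replacement
        assert not set(bg) & {f"t{i}" for i in range(n_target)}

    def test_exact_duplicates_preferred(self):
        rng = np.random.default_rng(1)
        props = pd.DataFrame(
            {
                "variant_id": ["t0"] + [f"dup{i}" for i in range(12)] + [f"o{i}" for i in range(50)],
                "maf": [0.2] + [0.2] * 12 + list(rng.uniform(0.16, 0.24, 50)),
            }
        )
        pool = pd.DataFrame({"variant_id": [f"dup{i}" for i in range(12)] + [f"o{i}" for i in range(50)]})
        bg = match_variants(["t0"], pool, props, n_per=10, seed=0)
        assert all(b.startswith("dup") for b in bg)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        props = pd.concat([pd.DataFrame({"variant_id": ["t0"], "maf": [0.3]}), self._props(200, rng)])
        pool = pd.DataFrame({"variant_id": [f"p{i}" for i in range(200)]})
        a = match_variants(["t0"], pool, props, n_per=10, seed=9)
        b = match_variants(["t0"], pool, props, n_per=10, seed=9)
        assert a == b

    def test_insufficient_pool_names_variant(self):
        props = pd.DataFrame({"variant_id": ["t0", "p0"], "maf": [0.5, 0.06]})
        pool = pd.DataFrame({"variant_id": ["p0"]})
        with pytest.raises(ValueError, match="t0"):
            match_variants(["t0"], pool, props, n_per=10, seed=0)

    def test_maf_window_respected(self):
        rng = np.random.default_rng(3)
        props = pd.concat([pd.DataFrame({"variant_id": ["t0"], "maf": [0.25]}), self._props(500, rng)])
        pool = pd.DataFrame({"variant_id": [f"p{i}" for i in range(500)]})
        bg = match_variants(["t0"], pool, props, n_per=10, seed=1)
        mafs = props.set_index("variant_id").loc[bg, "maf"]
        assert (abs(mafs - 0.25) <= 0.05).all()


class TestCollapseAndKs:
    def test_min_p_per_variant(self):
        df = pd.DataFrame(
            {"variant_id": ["a", "a", "a", "b"], "p_2df": [0.5, 0.01, 0.2, 0.9]}
        )
        mp = collapse_min_p(df)
        assert mp["a"] == 0.01
        assert mp["b"] == 0.9
        assert len(mp) == df["variant_id"].nunique()

    def test_target_equals_background(self):
        x = np.linspace(0.01, 0.99, 50)
        rep = enrichment_test(x, x)
        assert rep["D"] == 0.0 and rep["p"] == pytest.approx(1.0)

    def test_calibrated_when_background_matches_null(self):
        rng = np.random.default_rng(5)
        rejected = 0
        n_sims = 500
        for _ in range(n_sims):
            t = rng.random(60)
            b = rng.random(600)
            if enrichment_test(t, b)["p"] < 0.05:
                rejected += 1
        assert 0.03 <= rejected / n_sims <= 0.07

    def test_power_when_targets_enriched(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            # planted smaller p at targets (chi2(2) with modest signal)
            z = rng.normal(0.9, 1, size=(2, 100))
            t_p = np.exp(-(z[0] ** 2 + z[1] ** 2) / 2)
            b_p = rng.random(1000)
            if enrichment_test(t_p, b_p)["p"] < 0.05:
                hits += 1
        assert hits / n_sims >= 0.8
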
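"""ABF colocalization: pairwise H0-H4 and the 3-trait sharing posterior."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gxqtl.coloc import (
    call_significant_coloc,
    coloc_multitrait,
    coloc_pairwise,
    wakefield_abf,
)
from gxqtl.simulate import SimConfig, simulate_genotypes, simulate_gwas


class TestWakefield:
    def test_zero_z_formula(self):
        # r = W/(V+W) = 0.75 with V=1 -> W=3; lABF = 0.5*ln(0.25)
        labf = wakefield_abf(0.0, 1.0, W=3.0)
        assert labf == pytest.approx(0.5 * math.log(0.25))
        assert labf == pytest.approx(-0.6931, abs=5e-5)

    def test_zero_prior_variance_limit(self):
        assert wakefield_abf(1.3, 0.7, W=0.0) == pytest.approx(0.0)

    def test_strong_signal_formula(self):
        # z^2 = 10, r = 0.9 (V=1, W=9): lABF = 0.5*(ln 0.1 + 9)
        labf = wakefield_abf(math.sqrt(10.0), 1.0, W=9.0)
        assert labf == pytest.approx(3.3487, abs=5e-5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_abf(0.1, 0.0)

    def test_default_priors_by_trait_type(self):
        q = wakefield_abf(0.3, 0.1, "quantitative")
        cc = wakefield_abf(0.3, 0.1, "case_control")
        assert q != cc


SE = 0.05  # typical quantitative-trait summary-statistic scale


def _flat(Q, rng):
    return wakefield_abf(rng.normal(0, 0.1 * SE, Q), np.full(Q, SE))


class TestPairwise:
    def test_flat_region_is_h0(self):
        rng = np.random.default_rng(0)
        pp = coloc_pairwise(_flat(100, rng), _flat(100, rng))
        assert pp["PP.H0"] > 0.99

    def test_shared_peak_is_h4(self):
        rng = np.random.default_rng(1)
        l1, l2 = _flat(100, rng), _flat(100, rng)
        l1[40] = wakefield_abf(8.0 * SE, SE)
        l2[40] = wakefield_abf(-8.0 * SE, SE)
        pp = coloc_pairwise(l1, l2)
        assert pp["PP.H4"] > 0.95

    def test_distinct_peaks_are_h3(self):
        rng = np.random.default_rng(2)
        l1, l2 = _flat(100, rng), _flat(100, rng)
        l1[10] = wakefield_abf(8.0 * SE, SE)
        l2[80] = wakefield_abf(8.0 * SE, SE)
        pp = coloc_pairwise(l1, l2)
        assert pp["PP.H3"] > 0.95

    def test_posteriors_sum_to_one_and_symmetric(self):
        rng = np.random.default_rng(3)
        l1 = wakefield_abf(rng.normal(0, 1, 50), np.ones(50))
        l2 = wakefield_abf(rng.normal(0, 1, 50), np.ones(50))
        pp = coloc_pairwise(l1, l2)
        assert sum(pp.values()) == pytest.approx(1.0, abs=1e-10)
        sw = coloc_pairwise(l2, l1)
        assert pp["PP.H4"] == pytest.approx(sw["PP.H4"], rel=1e-12)
        assert pp["PP.H1"] == pytest.approx(sw["PP.H2"], rel=1e-12)

    def test_variant_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coloc_pairwise(np.zeros(5), np.zeros(6))

    def test_distinct_scenarios_rarely_colocalize(self):
        """Well-separated causal variants yield PP.H4 < 0.2 in >= 90% of
        200 seeded replicates of the GWAS simulator."""
        low = 0
        for rep in range(200):
            cfg = SimConfig(seed=1000 + rep, n_samples=50, n_variants=60,
                            ld_block_size=5, within_block_r=0.8, gwas_n=3000,
                            gwas_effect=0.25, missing_rate=0.0)
            sim = simulate_genotypes(cfg)
            vids = sim.geno.variants["variant_id"]
            ss1 = simulate_gwas(sim, "shared", [vids.iloc[5]], cfg)
            ss2 = simulate_gwas(sim, "shared", [vids.iloc[50]], replace(cfg, seed=cfg.seed + 50_000))
            common = ss1.table.merge(ss2.table, on="variant_id", suffixes=("_1", "_2"))
            l1 = wakefield_abf(common["beta_1"], common["se_1"])
            l2 = wakefield_abf(common["beta_2"], common["se_2"])
            if coloc_pairwise(l1, l2)["PP.H4"] < 0.2:
                low += 1
        assert low >= 180


def brute_force_multitrait(L, p_single, p_pair, p_triple):
    """O(Q^3) enumeration over per-trait causal assignments (0 = null)."""
    Q = L[0].size
    states = range(Q + 1)
    weights = {}
    for c1, c2, c3 in itertools.product(states, states, states):
        cs = (c1, c2, c3)
        active = [i for i, c in enumerate(cs) if c > 0]
        groups = {}
        for i in active:
            groups.setdefault(cs[i], []).append(i)
        prior = 1.0
        for variant, members in groups.items():
            prior *= {1: p_single, 2: p_pair, 3: p_triple}[len(members)]
        like = 1.0
        for i in active:
            like *= math.exp(L[i][cs[i] - 1])
        key = tuple(sorted(len(m) for m in groups.values()))
        weights[cs] = prior * like
    total = sum(weights.values())
    full = sum(w for cs, w in weights.items()
               if all(c > 0 for c in cs) and len(set(cs)) == 1)
    return full / total


class TestMultitrait:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for Q in (5, 12, 30):
            L = [rng.normal(0, 2, Q) for _ in range(3)]
            ours = coloc_multitrait(*L)["PP.full_share"]
            ref = brute_force_multitrait(L, 1e-4, 1e-5, 1e-6)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        pp = coloc_multitrait(*[rng.normal(0, 1, 40) for _ in range(3)])
        assert sum(pp.values()) == pytest.approx(1.0, abs=1e-10)

    def test_full_share_detected(self):
        rng = np.random.default_rng(6)
        Ls = []
        for _ in range(3):
            l = wakefield_abf(rng.normal(0, 0.1 * SE, 80), np.full(80, SE))
            l[33] = wakefield_abf(8.0 * SE, SE)
            Ls.append(l)
        assert coloc_multitrait(*Ls)["PP.full_share"] > 0.8

    def test_two_share_third_flat(self):
        rng = np.random.default_rng(7)
        l1 = wakefield_abf(rng.normal(0, 0.1 * SE, 80), np.full(80, SE))
        l2 = l1.copy()
        l1[33] = l2[33] = wakefield_abf(8.0 * SE, SE)
        l3 = wakefield_abf(rng.normal(0, 0.1 * SE, 80), np.full(80, SE))
        pp = coloc_multitrait(l1, l2, l3)
        assert pp["PP.full_share"] < 0.5
        assert pp["PP.pair_shared_12"] > 0.5


class TestDecisionRule:
    def _coloc_frame(self, pp):
        return pd.DataFrame({"feature_id": ["f1"], "PP.H4": [pp]})

    def _adj(self, p):
        return pd.DataFrame({"feature_id": ["f1"], "p_final": [p]})

    @pytest.mark.parametrize(
        "pp,adj_p,flag",
        [(0.85, 0.01, True), (0.85, 0.2, False), (0.8, 0.01, False)],  # strict > 0.8
    )
    def test_joint_rule(self, pp, adj_p, flag):
        out = call_significant_coloc(self._coloc_frame(pp), self._adj(adj_p))
        assert bool(out.loc[0, "flagged"]) is flag

    def test_missing_join_key_rejected(self):
        with pytest.raises(KeyError):
            call_significant_coloc(
                pd.DataFrame({"feature_id": ["f2"], "PP.H4": [0.9]}), self._adj(0.01)
            )
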
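"""Colocalization of simulated smoking-GWAS loci with the QTL maps.

A GWAS is simulated whose causal variant coincides with a planted meQTL
('shared' scenario). Pairwise colocalization (GWAS x meQTL) computes
PP.H0-H4 from Wakefield log-ABFs over the region; the GWAS x meQTL x eQTL
triplet is assessed with the 3-trait full-sharing posterior. Flags follow
the joint rule: posterior > 0.8 and two-stage adjusted p < 0.05.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from common import COHORT, RESULTS, STUDY

from gxqtl.coloc import call_significant_coloc, coloc_multitrait, coloc_pairwise, wakefield_abf
from gxqtl.simulate import simulate_genotypes, simulate_gwas

sim = simulate_genotypes(STUDY)  # deterministic re-derivation of the cohort LD panel
truth = pd.read_csv(COHORT / "truth.tsv", sep="\t")
meqtl = pd.read_csv(RESULTS / "meqtl_adjusted.tsv", sep="\t")
eqtl = pd.read_csv(RESULTS / "eqtl_adjusted.tsv", sep="\t")

# prefer the planted locus whose CpG has the strongest adjusted meQTL signal
best_p = meqtl.groupby("feature_id")["p_final"].min()
cand = truth[truth["beta_g"] != 0].copy()
cand["adj_p"] = cand["cpg_id"].map(best_p)
locus = cand.sort_values("adj_p").iloc[0]
gwas = simulate_gwas(sim, "shared", [locus["variant_id"]], STUDY)

vtab = sim.geno.variants.set_index("variant_id")
center, chrom = vtab.at[locus["variant_id"], "pos"], vtab.at[locus["variant_id"], "chrom"]
region = vtab[(vtab["chrom"] == chrom) & (abs(vtab["pos"] - center) <= 500_000)].index

me_reg = meqtl[(meqtl["feature_id"] == locus["cpg_id"]) & meqtl["variant_id"].isin(region)]
e_reg = eqtl[(eqtl["feature_id"] == locus["gene_id"]) & eqtl["variant_id"].isin(region)]
common = sorted(set(me_reg["variant_id"]) & set(e_reg["variant_id"])
                & set(gwas.table["variant_id"]))
print(f"locus {locus['variant_id']} ({chrom}:{center}): {len(common)} shared variants")

g = gwas.table.set_index("variant_id").loc[common]
m = me_reg.set_index("variant_id").loc[common]
e = e_reg.set_index("variant_id").loc[common]
l_gwas = wakefield_abf(g["beta"], g["se"])
l_me = wakefield_abf(m["beta_baseline"], m["se_baseline"])
l_e = wakefield_abf(e["beta_baseline"], e["se_baseline"])

pp = coloc_pairwise(l_gwas, l_me)
pp["feature_id"] = locus["cpg_id"]
flagged = call_significant_coloc(pd.DataFrame([pp]), meqtl)
mt = coloc_multitrait(l_gwas, l_me, l_e)

out = flagged.assign(full_share=mt["PP.full_share"])
out.to_csv(RESULTS / "coloc.tsv", sep="\t", index=False)
print("pairwise GWAS x meQTL:", {k: round(v, 4) for k, v in pp.items() if k.startswith("PP")})
print(f"flagged (PP.H4 > 0.8 and adjusted p < 0.05): {bool(flagged['flagged'][0])}")
print(f"triplet full-sharing posterior: {mt['PP.full_share']:.4f}")
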
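"""Simulate the study cohort and write it to results/cohort/.

Also prints the cohort characteristics table (exposure vs sex, ancestry and
age) with the same tests used for real cohort tables: Fisher's exact test
for categorical variables, Welch's t test for quantitative ones.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from common import COHORT, STUDY
from gxqtl.io import write_features, write_genotypes_tsv, write_sample_table
from gxqtl.simulate import simulate_genotypes, simulate_phenotypes
from gxqtl.stats import fisher_exact, welch_t_from_summary

COHORT.mkdir(parents=True, exist_ok=True)

sim = simulate_genotypes(STUDY)
samples, meth, genes, truth = simulate_phenotypes(sim, STUDY)

write_genotypes_tsv(sim.geno, COHORT / "genotypes.tsv")
write_sample_table(samples, COHORT / "samples.tsv")
write_features(meth, COHORT / "methylation.tsv", COHORT / "methylation.bed")
write_features(genes, COHORT / "counts.tsv", COHORT / "genes.bed")
truth.to_csv(COHORT / "truth.tsv", sep="\t", index=False)

s = samples.status
print(f"cohort: {len(s)} samples, {s.sum()} cases / {(1 - s).sum()} controls")
print(f"variants: {sim.geno.n_variants}; CpGs: {meth.n_features}; genes: {genes.n_features}")
print(f"planted cis effects: {(truth['beta_g'] != 0).sum()} "
      f"(of which {(truth['beta_gx'] != 0).sum()} with smoking interaction)")

rows = []
for name, vec in (("sex", samples.covariates["sex"]), ("ancestry", samples.ancestry == "AA")):
    tab = pd.crosstab(np.asarray(vec), s).to_numpy()
    rows.append((name, f"fisher p = {fisher_exact(tab):.2f}"))
age = samples.covariates["age"]
a1, a0 = age[s == 1], age[s == 0]
_, _, p = welch_t_from_summary(a1.mean(), a1.std(), len(a1), a0.mean(), a0.std(), len(a0))
rows.append(("age", f"welch p = {p:.2f}"))
print("case/control balance:")
for name, msg in rows:
    print(f"  {name:9s} {msg}")
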
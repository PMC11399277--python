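"""Map cis-meQTLs and cis-eQTLs: four models per pair + stratified 2DF.

Reads the cohort written by 01_simulate.py, applies the preprocessing
(pooled-MAF variant filter, RINT for methylation; low-expression filter,
median-of-ratios + RINT for expression) and writes one row per cis pair
with all model coefficients to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT, RESULTS

from gxqtl import preprocess, qtlmap
from gxqtl.io import GenotypeMatrix, FeatureMatrix, read_features, read_genotypes, read_sample_table

geno = read_genotypes(COHORT / "genotypes.tsv")
samples = read_sample_table(COHORT / "samples.tsv")
meth = read_features(COHORT / "methylation.tsv", COHORT / "methylation.bed", "beta")
genes = read_features(COHORT / "counts.tsv", COHORT / "genes.bed", "count")

keep_v, audit_v = preprocess.filter_variants(geno, samples.ancestry, mode="mapping")
geno_f = GenotypeMatrix(geno.variants[keep_v].reset_index(drop=True), geno.sample_id, geno.dosages[keep_v])
audit_v.to_csv(RESULTS / "variant_filter_audit.tsv", sep="\t", index=False)
print(f"variant filter (pooled MAF > 0.05): kept {keep_v.sum()} / {len(keep_v)}")

meth_rint = preprocess.rint_rows(meth.values)
meqtl = qtlmap.map_qtls(geno_f, meth, samples, qtlmap.MEQTL_COVARIATES,
                        anchor="variant", values=meth_rint)
meqtl.to_csv(RESULTS / "meqtl_mapping.tsv", sep="\t", index=False)
print(f"meQTL: {len(meqtl)} cis pairs over {meqtl['feature_id'].nunique()} CpGs")

lengths = (genes.features["end"] - genes.features["start"]).to_numpy()
tpm = preprocess.tpm_from_counts(genes.values, lengths)
keep_g, audit_g = preprocess.filter_low_expression(genes.values, tpm)
audit_g.to_csv(RESULTS / "expression_filter_audit.tsv", sep="\t", index=False)
genes_f = FeatureMatrix(genes.features[keep_g].reset_index(drop=True), genes.sample_id,
                        genes.values[keep_g], "count")
print(f"low-expression filter: kept {keep_g.sum()} / {len(keep_g)} genes")

_, norm = preprocess.median_of_ratios(genes_f.values)
gene_rint = preprocess.rint_rows(norm)
eqtl = qtlmap.map_qtls(geno_f, genes_f, samples, qtlmap.EQTL_COVARIATES,
                       anchor="gene_body", values=gene_rint)
eqtl.to_csv(RESULTS / "eqtl_mapping.tsv", sep="\t", index=False)
print(f"eQTL: {len(eqtl)} cis pairs over {eqtl['feature_id'].nunique()} genes")
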
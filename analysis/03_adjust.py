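"""Two-stage multiple-testing correction and the interaction decision rule.

Stage 1: per-feature effective-test correction from the eigenvalue spectrum
of the cis genotype correlation. Stage 2: across-feature multiplication,
capped at plain Bonferroni. Features are then post hoc filtered with the
per-ancestry robust MAF/missingness rule, and the interaction Bonferroni
threshold (0.05 / number of significant features) is applied to the
interaction-model p-values.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import COHORT, RESULTS

from gxqtl import mtcorr, preprocess
from gxqtl.io import read_genotypes, read_sample_table

samples = read_sample_table(COHORT / "samples.tsv")
geno = read_genotypes(COHORT / "genotypes.tsv")
vindex = pd.Index(geno.variants["variant_id"])

keep_rob, _ = preprocess.filter_variants(geno, samples.ancestry, mode="robust")
robust_ids = set(geno.variants.loc[keep_rob, "variant_id"])

for kind in ("meqtl", "eqtl"):
    res = pd.read_csv(RESULTS / f"{kind}_mapping.tsv", sep="\t")
    m_eff = {}
    for fid, grp in res.groupby("feature_id"):
        vidx = vindex.get_indexer(grp["variant_id"])
        m_eff[fid] = mtcorr.effective_tests(
            geno.dosages[vidx], positions=geno.variants["pos"].to_numpy()[vidx]
        )
    adj = mtcorr.two_stage_adjust(res, m_eff, res["feature_id"].nunique(), len(res))
    adj.to_csv(RESULTS / f"{kind}_adjusted.tsv", sep="\t", index=False)

    sig = adj[adj["significant"]]
    # robust post hoc filter: the feature's top variant must pass the
    # per-ancestry MAF/missingness rule
    top = sig.loc[sig.groupby("feature_id")["p_final"].idxmin()]
    robust_feats = set(top.loc[top["variant_id"].isin(robust_ids), "feature_id"])
    n_sig = sig["feature_id"].nunique()
    print(f"{kind}: {len(sig)} significant pairs, {n_sig} features "
          f"({len(robust_feats)} robust after per-ancestry MAF/missingness filter)")
    if robust_feats:
        thr = mtcorr.interaction_bonferroni(len(robust_feats))
        inter = sig[sig["feature_id"].isin(robust_feats)]
        inter_hits = inter[inter["p_interaction"] < thr]
        print(f"  interaction threshold 0.05/{len(robust_feats)} = "
              f"{mtcorr.format_threshold(thr):.2g}; "
              f"{inter_hits['feature_id'].nunique()} features with significant interaction")
        inter_hits.to_csv(RESULTS / f"{kind}_interaction_hits.tsv", sep="\t", index=False)
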
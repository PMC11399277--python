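"""Shared configuration for the analysis drivers.

The cohort mirrors the study design: 223 donors (~23% active smokers by
cotinine threshold, two ancestry strata), desk-scale genome of 2,000
LD-blocked variants on two chromosomes with 200 CpGs and 200 genes. The
same seed is used by every driver, so later stages can re-derive the
simulation deterministically instead of serializing generator state.
"""

from pathlib import Path

from gxqtl.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"

STUDY = SimConfig(
    seed=2024,
    n_samples=223,
    n_variants=2000,
    n_features=200,
    n_chromosomes=2,
    gwas_n=8000,
)
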
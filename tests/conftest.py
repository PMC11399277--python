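import numpy as np
import pandas as pd
import pytest

from gxqtl.io import FeatureMatrix, GenotypeMatrix, SampleTable
from gxqtl.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_samples=240, n_variants=200, n_features=30,
                     ld_block_size=5, missing_rate=0.02)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    sim = simulate_genotypes(small_cfg)
    samples, meth, genes, truth = simulate_phenotypes(sim, small_cfg)
    return dict(sim=sim, samples=samples, meth=meth, genes=genes, truth=truth)


@pytest.fixture()
def tiny_genotypes():
    variants = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chrom": ["1", "1", "1"],
            "pos": [1_000_000, 1_200_000, 2_000_000],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
        }
    )
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 1.0],
            [np.nan, 0.0, 1.0, 2.0],
            [2.0, 2.0, 0.0, 0.0],
        ]
    )
    return GenotypeMatrix(variants, np.array(["a", "b", "c", "d"], dtype=object), dosages)


def make_samples(n, n_cases, seed=0):
    rng = np.random.default_rng(seed)
    status = np.zeros(n, dtype=int)
    status[:n_cases] = 1
    cov = pd.DataFrame({"age": rng.normal(45, 10, n), "sex": rng.binomial(1, 0.3, n).astype(float)})
    return SampleTable(
        np.array([f"s{i}" for i in range(n)], dtype=object),
        status,
        np.where(rng.random(n) < 0.5, "AA", "EA"),
        cov,
    )
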
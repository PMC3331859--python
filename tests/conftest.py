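import numpy as np
import pandas as pd
import pytest

from poolgwas import (
    CohortSpec,
    GenotypeMatrix,
    IntensityModel,
    build_pools,
    generate_panel,
    plant_effects,
    simulate_genotypes,
    simulate_intensities,
)


@pytest.fixture(scope="session")
def small_panel():
    """40 SNPs in 4-SNP blocks at r2 = 0.9, MAF 0.2-0.5."""
    return generate_panel(40, (0.2, 0.5), block_length=4,
                          within_block_r2=0.9, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return CohortSpec(n_cases=90, n_controls=90, seed=5)


@pytest.fixture(scope="session")
def small_genotypes(small_panel, small_cohort):
    return simulate_genotypes(small_panel, small_cohort)


@pytest.fixture(scope="session")
def small_design(small_genotypes, small_cohort):
    return build_pools(small_genotypes.samples, small_cohort)


@pytest.fixture(scope="session")
def small_intensities(small_design, small_genotypes):
    return simulate_intensities(small_design, small_genotypes,
                                IntensityModel(noise_cv=0.05), seed=7)


def make_genotypes(dosage_rows, groups, snp_ids=None, ages=None):
    """Hand-build a GenotypeMatrix from a list of per-SNP dosage lists."""
    n = len(groups)
    sample_ids = [f"s{i}" for i in range(n)]
    snp_ids = snp_ids or [f"m{i}" for i in range(len(dosage_rows))]
    dosage = pd.DataFrame(np.array(dosage_rows, dtype=float),
                          index=snp_ids, columns=sample_ids)
    samples = pd.DataFrame({
        "group": groups,
        "sex": ["F"] * n,
        "age": ages if ages is not None else [60] * n,
        "cohort": "t",
    }, index=pd.Index(sample_ids, name="sample_id"))
    return GenotypeMatrix(dosage, samples)
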
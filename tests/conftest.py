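import numpy as np
import pandas as pd
import pytest

from genesize.assoc import CohortData
from genesize.synthcohort import CohortSpec, GeneSpec, MSpec, simulate_genotypes


@pytest.fixture
def toy_snps():
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": ["1", "1", "1", "1"],
            "pos": [99, 100, 200, 201],
            "pvalue": [0.5, 0.01, 0.2, np.nan],
        }
    )


@pytest.fixture
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA"],
            "chrom": ["1"],
            "start": [100],
            "end": [200],
            "sets": [""],
        }
    )


@pytest.fixture
def toy_cohort():
    # 8 subjects x 2 SNPs, hand-checkable
    dosages = np.array(
        [
            [0, 2],
            [1, 2],
            [2, 1],
            [0, 0],
            [1, 1],
            [0, 0],
            [2, 2],
            [1, 0],
        ],
        dtype=np.int8,
    )
    phenotype = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    return CohortData(dosages, phenotype)


def small_null_cohort(n_genes=150, n=300, rho=0.0, block=1, seed=11, m_max=60):
    """Genotype cohort at desk scale with a null phenotype."""
    rng = np.random.default_rng(seed)
    ms = MSpec(mu=2.0, sigma=1.0, m_max=m_max).draw(n_genes, rng)
    genes = [
        GeneSpec(f"g{i:04d}", int(m), min(block, int(m)), rho if m > 1 else 0.0)
        for i, m in enumerate(ms)
    ]
    spec = CohortSpec(n_cases=n // 2, n_controls=n - n // 2, genes=genes, seed=seed)
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def null_cohort_session():
    return small_null_cohort(n_genes=200, n=400, seed=11)
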
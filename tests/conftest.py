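import numpy as np
import pandas as pd
import pytest

from gwaspath.types import SimulationConfig
from gwaspath.synthetic import make_gene_annotation, simulate_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=300, n_genes=20, causal_set_size=5, seed=42
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return make_gene_annotation(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_config, small_annotation):
    return simulate_genotypes(small_annotation, small_config, cohort_index=0)


def make_ranking(p_values, gene_ids=None) -> pd.DataFrame:
    """Ranked gene list from raw P-values, via the package's own ranker."""
    from gwaspath.genes import rank_genes
    from gwaspath.genes import GeneResult

    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(len(p_values))]
    results = [
        GeneResult(gene_id=g, n_snps=1, stat=1.0, p=float(p), n_sims=1000)
        for g, p in zip(gene_ids, p_values)
    ]
    return rank_genes(results)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
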
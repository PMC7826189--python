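import numpy as np
import pytest

from chromaforge.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Desk-scale configuration used by unit tests (fast, deterministic)."""
    return SynthConfig(
        seed=11,
        n_species=6,
        n_families=80,
        n_proteins=60,
        n_planted_crtp=8,
        n_decoy_crtp=4,
        n_seed_crtps=6,
        n_genes_expr=120,
        n_gene_trees=30,
        genome_len=20_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
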
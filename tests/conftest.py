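import numpy as np
import pytest

from ventpop.synth import CommunityConfig, generate_community, simulate_reads


@pytest.fixture(scope="session")
def small_truth():
    """A small two-genome community with planted polymorphism."""
    cfg = CommunityConfig(
        n_genomes=2,
        genes_per_genome=10,
        gene_length_nt=300,
        intergenic_nt=60,
        n_haplotypes=12,
        planted_omega={"cellular": 0.22, "viral_amg": 0.15},
        per_site_polymorphism_rate=0.02,
        mge_gene_fraction=0.2,
        provirus_spec=[(0, 400, 1200)],
        seed=42,
    )
    return generate_community(cfg)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return simulate_reads(small_truth, mean_depth=15.0, read_len_range=(100, 200),
                          seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
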
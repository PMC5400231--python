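import pytest

from rvburden.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic cohort reused across tests (seeded, immutable)."""
    cfg = SimulationConfig(
        seed=42,
        n_genes=600,
        n_ranked=300,
        target_set_size=100,
        n_gwas_snps=120,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write(outdir)
    return paths
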
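import pytest

from famexome.synthetic_data import (
    SimulationConfig,
    simulate_family_variants,
    simulate_gene_models,
    write_fixture_bundle,
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down family: same strata structure, quick to generate."""
    defaults = dict(
        seed=seed,
        candidate_snvs=180,
        candidate_indels=25,
        background_snvs=60,
        background_indels=12,
        n_background_genes=30,
        n_candidate_genes=30,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """In-memory simulated family: (config, gene models, candidate set, variants, panels, truth)."""
    config = small_config()
    models, genes = simulate_gene_models(config)
    variants, panels, truth = simulate_family_variants(config, models, genes)
    return config, models, genes, variants, panels, truth


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete on-disk bundle at reduced scale."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = small_config(seed=5)
    return write_fixture_bundle(config, outdir)
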
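import pytest

import radiosig as rs


@pytest.fixture(scope="session")
def default_cfg():
    return rs.SimulationConfig()


@pytest.fixture(scope="session")
def default_bundle(default_cfg):
    """The reference synthetic study: 2,000 genes, 20 planted, fixed seed."""
    return rs.simulate_bundle(default_cfg)


@pytest.fixture(scope="session")
def default_report(default_bundle):
    """Full pipeline run on the reference bundle (shared across tests)."""
    bundle, _ = default_bundle
    return rs.run_pipeline(bundle)


@pytest.fixture()
def small_cfg():
    """A light bundle that still clears every pipeline stage."""
    return rs.SimulationConfig(
        n_genes=400,
        n_signature=12,
        n_profiles=2,
        n_coexpr_blocks=2,
        coexpr_block_size=40,
        seed=77,
    )
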
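import pytest

import tfeqtl as tq


@pytest.fixture(scope="session")
def small_config() -> tq.ScenarioConfig:
    """A reduced cohort that still exercises every pipeline stage."""
    return tq.ScenarioConfig(
        n_individuals=120, n_tissues=6, n_genes=30, n_tfs=4,
        samples_per_tissue=100,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> tq.SyntheticStudy:
    # seed chosen so the knocked-down TF has truth genes that are heterozygous
    # in the cell line, keeping the knockdown-validation path exercised
    return tq.generate_study(small_config, seed=19)


@pytest.fixture(scope="session")
def small_discovery(small_study) -> tq.DiscoveryResult:
    return tq.run_discovery(small_study)
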
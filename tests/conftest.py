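import pytest

from plastocomp.pipeline import RunConfig, run_pipeline
from plastocomp.simulate import (
    simulate_plastome_dataset,
    simulate_rrna_dataset,
)

SIM_SEED = 7


@pytest.fixture(scope="session")
def plastome_sim():
    """Default-scale six-specimen plastome dataset + truth manifest."""
    return simulate_plastome_dataset(seed=SIM_SEED)


@pytest.fixture(scope="session")
def rrna_sim():
    """Six-specimen nuclear rRNA cluster dataset + truth manifest."""
    return simulate_rrna_dataset(seed=SIM_SEED)


@pytest.fixture(scope="session")
def pipeline_result(plastome_sim, tmp_path_factory):
    """Full pipeline run on the session plastome dataset."""
    genomes, _ = plastome_sim
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(RunConfig(out_dir=str(out)), genomes=genomes)
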
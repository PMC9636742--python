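import pytest

from epilinc.pipeline import (
    PipelineConfig,
    PipelineInputs,
    run_pipeline,
    train_builtin_model,
)
from epilinc.synthetic_data import SimulationConfig, generate_fixture, paper_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """The default synthetic study: 6 vs 6 samples, ~1000 CpG sites with
    two planted epimutations, planted antisense lncRNA among decoys."""
    return generate_fixture(
        SimulationConfig(seed=FIXTURE_SEED), tmp_path_factory.mktemp("fixture")
    )


@pytest.fixture(scope="session")
def pipeline_result(sim_bundle, tmp_path_factory):
    inputs = PipelineInputs(
        samples_tsv=sim_bundle.samples_tsv,
        assembled_gtf=sim_bundle.assembled_gtf,
        annotation_gtf=sim_bundle.annotation_gtf,
        genome_fasta=sim_bundle.genome_fasta,
        counts_tsv=sim_bundle.counts_tsv,
    )
    return run_pipeline(
        PipelineConfig(seed=FIXTURE_SEED), inputs, tmp_path_factory.mktemp("out")
    )


@pytest.fixture(scope="session")
def paper_fx():
    return paper_fixture()


@pytest.fixture(scope="session")
def builtin_model():
    """(hexamer table, logistic model) trained on a seeded corpus."""
    return train_builtin_model(3)
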
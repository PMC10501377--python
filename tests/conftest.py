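import pytest

from pfasnta.pipeline import PipelineConfig, align_observations, prioritize
from pfasnta.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic screen: 4 case + 4 control pools in triplicate,
    500 matrix features, planted PFSA/FASA/Cl-PFSA/FASA-PrA series, seed 42."""
    return generate_dataset(GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def default_pipeline_run(default_dataset):
    cfg = PipelineConfig()
    feats = align_observations(default_dataset.observations, cfg)
    survivors = prioritize(feats, default_dataset.design, cfg)
    return cfg, feats, survivors
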
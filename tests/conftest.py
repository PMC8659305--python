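import numpy as np
import pytest

from crowdshift import (
    GeneratorConfig,
    all_conditions,
    build_design,
    generate_questions,
    simulate_experiment,
)
from crowdshift.influence_model import demo_params


@pytest.fixture(scope="session")
def full_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def questions(full_config):
    return generate_questions(full_config)


@pytest.fixture(scope="session")
def design(full_config):
    return build_design(full_config, all_conditions())


@pytest.fixture(scope="session")
def params():
    return demo_params()


@pytest.fixture(scope="session")
def small_records(questions, design, params):
    """A small record-level simulation of the full design (5 runs)."""
    return simulate_experiment(
        questions, design, params, gamma=0.9, n_runs=5, seed=21,
        collect="records",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
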
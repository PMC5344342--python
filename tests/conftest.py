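import pytest

from riskartifacts import (
    ExperimentConfig,
    StudyConfig,
    generate_experiment,
    generate_study1,
    load_life_events,
)


@pytest.fixture(scope="session")
def events():
    return load_life_events()


@pytest.fixture(scope="session")
def study_df(events):
    """One synthetic rating-study dataset under the null (no desirability effect)."""
    return generate_study1(StudyConfig(events=events, seed=0))


@pytest.fixture(scope="session")
def experiment_df():
    """A 2x2 experiment with an injected severity effect and no optimism."""
    return generate_experiment(ExperimentConfig(d_severity=8.0, seed=0))
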
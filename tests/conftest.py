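import pytest

import thermosize as tz


@pytest.fixture(scope="session")
def truth():
    return tz.default_truth()


@pytest.fixture(scope="session")
def jan_design():
    return tz.ExperimentDesign(months=("Jan",))


@pytest.fixture(scope="session")
def jan_experiment(jan_design, truth):
    return tz.generate_experiment(jan_design, truth, seed=7)


@pytest.fixture(scope="session")
def jan_stats(jan_experiment):
    return tz.process_experiment(jan_experiment)
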
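import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study():
    from matechoice import study_datasets

    return study_datasets()


@pytest.fixture(scope="session")
def designs():
    from matechoice import study_designs

    return study_designs()
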
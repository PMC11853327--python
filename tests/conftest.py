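import pytest
from hypothesis import settings

from pvdispro import aggregate, generate, reference_study_spec

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def reference_dataset():
    """Exact-mode synthetic line listing pinned to the published
    bevacizumab/panitumumab aggregates."""
    return generate(reference_study_spec())


@pytest.fixture(scope="session")
def reference_aggregates(reference_dataset):
    return aggregate(reference_dataset)


@pytest.fixture(scope="session")
def bev(reference_aggregates):
    return next(a for a in reference_aggregates if a.drug == "bevacizumab")


@pytest.fixture(scope="session")
def pan(reference_aggregates):
    return next(a for a in reference_aggregates if a.drug == "panitumumab")
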
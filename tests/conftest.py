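import pytest
from hypothesis import HealthCheck, settings

from amyloidpath import derive_ordering, load_effect_matrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matrix():
    """The embedded published effect matrix (20 x 6, intercept 1.083)."""
    return load_effect_matrix()


@pytest.fixture(scope="session")
def ordering(matrix):
    return derive_ordering(matrix)
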
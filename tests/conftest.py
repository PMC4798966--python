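import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_group_records():
    """The two-group worked example: six-member groups starting with 1 vs 5
    cooperators, after one round of the group-reproduction rule."""
    from mlsel import GroupRecord

    return [GroupRecord(6, 1, 16, 1), GroupRecord(6, 5, 32, 25)]
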
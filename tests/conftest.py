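import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from avert import EstimationConfig, FatalityRateModel, builtin_table1


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def uniform_rate():
    return FatalityRateModel(0.1, 0.8)


@pytest.fixture()
def default_config():
    return EstimationConfig()


#: (count, (range_lower, range_upper), (mc_point, ci_lower, ci_upper)) for the
#: nine known services of the builtin table, in table order.
TABLE1_CELLS = [
    (77, (8, 62), (35, 9, 60)),
    (18, (2, 15), (8, 2, 14)),
    (66, (7, 53), (30, 8, 52)),
    (0, (0, 0), (0, 0, 0)),
    (3, (1, 3), (1, 0, 2)),
    (33, (4, 27), (15, 4, 26)),
    (28, (3, 23), (13, 3, 22)),
    (74, (8, 60), (33, 9, 58)),
    (0, (0, 0), (0, 0, 0)),
]


@pytest.fixture(scope="session")
def table1_cells():
    return TABLE1_CELLS
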
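import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from qcrisk.records import DEFAULT_CATALOG, DEFAULT_GRID, QCMeasurement

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=75,
    # read-only module constants are safe to share across generated inputs
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

DAY0 = dt.date(2020, 6, 1)


def day(i: int) -> dt.date:
    """Operating day i of the synthetic observation window."""
    return DAY0 + dt.timedelta(days=int(i))


def measurement(day_index: int, item, deviation: float) -> QCMeasurement:
    return QCMeasurement(
        day(day_index), item.item_id, deviation, item.within_tolerance(deviation)
    )


@pytest.fixture
def catalog():
    return DEFAULT_CATALOG


@pytest.fixture
def grid():
    return DEFAULT_GRID


@pytest.fixture
def gantry(catalog):
    """The 0.2-degree-tolerance gantry angle item."""
    return catalog[0]
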
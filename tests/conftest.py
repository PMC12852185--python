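import numpy as np
import pytest

from colonytrend import published
from colonytrend.colony_data import CensusRecord, ColonySeries, load_published_trends


def make_series(years, counts, colony_id="X", **kwargs):
    records = tuple(
        CensusRecord(colony_id, int(y), float(c)) for y, c in zip(years, counts)
    )
    return ColonySeries(colony_id=colony_id, records=records, name=colony_id, **kwargs)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def malvinas():
    """The archipelago unit: 1.3M pairs in 1989, 100k in 2019."""
    return published.malvinas_series()


@pytest.fixture(scope="session")
def published_rows():
    return load_published_trends()
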
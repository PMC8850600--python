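import pandas as pd
import pytest
from hypothesis import settings

import grazemetrics as gm
from grazemetrics.synthetic_herd import ScheduleConfig, StudyScenario, default_animals

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def small_herd():
    """Seven animals spanning all three genetic groups."""
    herd = default_animals()
    return herd[:3] + herd[10:12] + herd[15:17]


@pytest.fixture(scope="session")
def small_bundle() -> gm.StudyBundle:
    """A 7-animal, 1-day study shared across unit tests."""
    scenario = StudyScenario(schedule=ScheduleConfig(day_span=1, animals=small_herd()))
    return gm.generate_study(scenario, seed=11)


@pytest.fixture(scope="session")
def default_bundle() -> gm.StudyBundle:
    """The default 22-animal study used by the acceptance checks."""
    return gm.generate_study(seed=1)


def make_records(offsets_s, animal_id="A01", start="2020-01-01T00:00:00Z", values=None):
    """Minimal record stream at the given second offsets."""
    start = pd.Timestamp(start)
    n = len(offsets_s)
    values = values if values is not None else [(0.1, 0.2, 0.9)] * n
    return pd.DataFrame(
        {
            "sensor_id": "S001",
            "animal_id": animal_id,
            "timestamp": [start + pd.Timedelta(seconds=s) for s in offsets_s],
            "x_g": [v[0] for v in values],
            "y_g": [v[1] for v in values],
            "z_g": [v[2] for v in values],
        }
    )
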
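from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from geotrigger.gazetteer import Gazetteer, KeywordDictionary, Place

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

STUDY_START = datetime(2019, 3, 1)


@pytest.fixture
def include_dict() -> KeywordDictionary:
    """v0-style dictionary: broad health terms, no exclusions."""
    return KeywordDictionary("v0", 0, frozenset({"hospital", "medical center", "health"}), frozenset())


@pytest.fixture
def exclude_dict() -> KeywordDictionary:
    """v1-style dictionary: same includes plus nonhospital exclusions."""
    return KeywordDictionary(
        "v1", 210,
        frozenset({"hospital", "medical center", "health"}),
        frozenset({"gym", "fitness", "pharmacy", "dentist"}),
    )


@pytest.fixture
def small_gazetteer() -> Gazetteer:
    """A hospital, a gym, a pharmacy and a restaurant around (45, -93)."""
    return Gazetteer(
        [
            Place("hosp-a", "St. Mary General Hospital", frozenset({"hospital", "health"}), 45.000, -93.000),
            Place("gym-a", "FitLife Gym", frozenset({"gym", "health"}), 45.020, -93.000),
            Place("pharm-a", "CityCare Pharmacy", frozenset({"pharmacy", "health"}), 45.040, -93.000),
            Place("rest-a", "Corner Restaurant", frozenset({"restaurant"}), 45.060, -93.000),
        ]
    )
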
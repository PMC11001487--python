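import random

import pytest
from hypothesis import settings

from panprimer import FilterSettings, ThermoSettings

settings.register_profile("deterministic", derandomize=True, database=None, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def tsettings():
    return ThermoSettings()


@pytest.fixture
def fsettings():
    return FilterSettings()


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
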
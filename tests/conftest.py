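import random

import pytest

from nppcur.dnalm import PRESETS

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def dnalm_params():
    return PRESETS["dnalm"]


@pytest.fixture
def rng():
    return random.Random(20231216)


def random_aa(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


@pytest.fixture
def valid_precursor() -> str:
    """A constructed well-formed precursor: signal + 2 APGW copies."""
    return "M" + "L" * 14 + "GKR" + ("APGW" + "GKR") * 2 + "SDEQNTSDEQNTSDEQ"
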
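import numpy as np
import pytest

from translatome.design import SampleDesign, build_design_dod


@pytest.fixture(scope="session")
def dod_design():
    return SampleDesign.balanced(4)


@pytest.fixture(scope="session")
def dod_pair(dod_design):
    return build_design_dod(dod_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_sequence(rng, length: int, p_gc: float = 0.5) -> str:
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
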
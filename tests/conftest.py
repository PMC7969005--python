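import numpy as np
import pytest

from lariatools import synth
from lariatools.seqio import IntronModel


@pytest.fixture(scope="session")
def human_layout_intron() -> IntronModel:
    """Synthetic intron with the human-style dBP cluster at 25/31/36/41.

    Long enough (260 nt) that lariat amplicons pass the 195-nt merged-length
    filter while keeping the dBP layout and a megaPPT/AGEZ architecture.
    """
    return synth.simulate_intron(260, (25, 31, 36, 41), agez_target=200, seed=7)


@pytest.fixture(scope="session")
def human_usage_vector() -> dict[int, float]:
    return {25: 0.35, 31: 0.38, 36: 0.24, 41: 0.03}


def random_intron(rng: np.random.Generator, length: int) -> IntronModel:
    """Uniform-composition permissive intron for scanner oracles."""
    body = "".join(rng.choice(list("ACGT"), size=length))
    return IntronModel(body, permissive=True)
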
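import numpy as np
import pytest

from mirslice.io import MatureMiRNA
from mirslice.simulate import MIR408_MATURE, MIR408_STAR


@pytest.fixture
def mir408() -> MatureMiRNA:
    """Sweet potato miR408 mature/star pair (21 nt each)."""
    return MatureMiRNA(
        id="Ib-miR408", sequence=MIR408_MATURE, star_sequence=MIR408_STAR
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
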
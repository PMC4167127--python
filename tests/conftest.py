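import numpy as np
import pytest
from hypothesis import settings

from locenrich.motif_model import Background, Motif, motif_from_consensus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def planted_motif():
    from locenrich.synthetic_data import example_motif

    return example_motif()


def random_motif(rng: np.random.Generator, width: int, motif_id: str = "RND") -> Motif:
    """A random Dirichlet PPM, for property tests."""
    probs = rng.dirichlet(np.ones(4), size=width)
    return Motif(motif_id, motif_id, "ACGT", probs)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
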
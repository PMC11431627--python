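import numpy as np
import pytest

from plasmidloom.simulate import PlasmidSpec, simulate_plasmid


@pytest.fixture(scope="session")
def plasmid6k():
    """One canonical 6 kb synthetic plasmid with annotations."""
    return simulate_plasmid(PlasmidSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes().decode()
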
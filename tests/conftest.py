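import numpy as np
import pytest

from afmock import DEFAULT_SCHEME, Clone, CloneLibrary
from afmock.synthetic_data import SynthesisParams, generate_libraries, generate_reference_db


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_clone(rng, its1_len=240, pad5=20, pad3=20):
    """Synthetic clone with bookkept layout: pad + F + core + rc(R) + pad."""
    from afmock.reference_io import reverse_complement

    f = DEFAULT_SCHEME.forward_core
    r = reverse_complement(DEFAULT_SCHEME.reverse_core)
    core = random_dna(rng, its1_len)
    return random_dna(rng, pad5) + f + core + r + random_dna(rng, pad3), len(f) + its1_len + len(r)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """Five-strain synthetic study (libraries, truth, reference DB)."""
    params = SynthesisParams(seed=7)
    libraries, truth = generate_libraries(params)
    db = generate_reference_db(libraries, truth, contamination=2, seed=7)
    return params, libraries, truth, db


@pytest.fixture()
def toy_library():
    return CloneLibrary(
        "toy",
        [Clone("a", "ACGT" * 50, 3), Clone("b", "AGGT" * 50, 1)],
    )
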
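import numpy as np
import pytest

import sinescout as ss


@pytest.fixture(scope="session")
def catalogue():
    return ss.load_fixture_catalogue()


@pytest.fixture(scope="session")
def sine3_head_refs(catalogue):
    """5S reference set built from the conserved 5' heads (positions 1-64)
    of the five 5S-derived elements."""
    return ss.Catalogue(
        [
            ss.ElementRecord(id=f"{r.id}-head", seq=r.seq[:64], origin_label="5S rRNA")
            for r in catalogue
            if r.id.startswith("AfuSINE3")
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(n, rng, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
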
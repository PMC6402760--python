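import numpy as np
import pytest
from hypothesis import settings

from utrlens.catalog_io import GeneCatalog, Region, UtrRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_catalog():
    return GeneCatalog(
        records=[
            UtrRecord("APOD", "b", "Hsap", Region.FIVE_PRIME, "ACGTACGTAC"),
            UtrRecord("APOD", "c", "Hsap", Region.FIVE_PRIME, "GGGCCCATGA"),
            UtrRecord("LCN2", "b", "Mmus", Region.FIVE_PRIME, "ATATATGCGC"),
        ]
    )


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def make_random_dna(rng):
    def _make(length, gc=0.5):
        return random_dna(rng, length, gc)

    return _make
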
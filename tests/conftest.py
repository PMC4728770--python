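from pathlib import Path

import pytest

from seqcerosene import (
    RepresentativeMode,
    build_document,
    embed_structure,
)
from seqcerosene.fixtures import (
    make_antiparallel_duplex,
    make_collinear_chain,
    make_ideal_helix,
    make_random_coil,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def collinear3():
    return make_collinear_chain(3, 23.0)


@pytest.fixture
def helix():
    return make_ideal_helix(30)


@pytest.fixture
def duplex():
    return make_antiparallel_duplex(10)


@pytest.fixture
def coil():
    return make_random_coil(25, seed=7)


@pytest.fixture
def coil_document(coil):
    embedding = embed_structure(coil, RepresentativeMode.C_BETA_DEFAULT)
    return build_document(coil, embedding)
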
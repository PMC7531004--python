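import pytest

from obocscreen.library_design import (
    PARENT_SEQUENCE,
    PeptideSequence,
    build_default_scheme,
    enumerate_library,
)

#: Parent with the single L->V substitution at residue 4 (one methylene less).
A1_SEQUENCE = "VGAVAVVVWLWLWLW"


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


@pytest.fixture(scope="session")
def library(scheme):
    return list(enumerate_library(scheme))


@pytest.fixture(scope="session")
def parent(scheme):
    return PeptideSequence.parse(PARENT_SEQUENCE, scheme)


@pytest.fixture(scope="session")
def a1(scheme):
    return PeptideSequence.parse(A1_SEQUENCE, scheme)
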
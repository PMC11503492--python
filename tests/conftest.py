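import pytest

from delscreen import build_codebook, enumerate_library, filter_building_blocks
from delscreen.demo import (
    FULLSCALE_BANNED_FLAGS,
    fullscale_building_blocks,
    toy_building_blocks,
)


@pytest.fixture(scope="session")
def toy_bbs():
    """3 starters, 4 acids with valid SMILES."""
    return toy_building_blocks()


@pytest.fixture(scope="session")
def toy_library(toy_bbs):
    starters, acids = toy_bbs
    return enumerate_library(starters, acids)


@pytest.fixture(scope="session")
def toy_codebook(toy_library):
    return build_codebook(toy_library, codon_length=8, d_min=3, seed=11)


@pytest.fixture(scope="session")
def fullscale_library():
    """14 starters x 382 filtered acids -> 5,348 members."""
    starters, acids = fullscale_building_blocks()
    acids = filter_building_blocks(
        acids, max_mw=200.0, banned_flags=FULLSCALE_BANNED_FLAGS,
        max_unassigned_stereocenters=0,
    )
    return enumerate_library(starters, acids)
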
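"""Small synthetic building-block tables for demos and tests.

The toy set is 3 starters x 4 acids (12 members) with simple, parseable
SMILES — handy for worked examples and exact-arithmetic oracles.  The full-
scale generator produces a table with the real screen's shape: 14 starters
and enough candidate acids that molecular-weight / alert / stereochemistry
filtering leaves exactly 382, giving a 5,348-member library.
"""

from __future__ import annotations

import numpy as np

from .library_design import BuildingBlock

__all__ = ["toy_building_blocks", "fullscale_building_blocks", "FULLSCALE_BANNED_FLAGS"]

#: structural-alert ban list matching the full-scale demo table
FULLSCALE_BANNED_FLAGS = frozenset({"reactive"})


def toy_building_blocks() -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """3 starters and 4 acids with valid SMILES; 12-member toy library."""
    starters = [
        BuildingBlock("S1", 1, mw=140.2, smiles="C1CCNCC1N"),         # aminopiperidine
        BuildingBlock("S2", 1, mw=155.2, smiles="C1CCNCC1Nc1ccccn1"),
        BuildingBlock("S3", 1, mw=170.3, smiles="C1CCNCC1Nc1ccncc1"),
    ]
    acids = [
        BuildingBlock("A1", 2, mw=60.05, smiles="CC(=O)O"),           # acetic
        BuildingBlock("A2", 2, mw=122.1, smiles="OC(=O)c1ccccc1"),    # benzoic
        BuildingBlock("A3", 2, mw=116.1, smiles="OC(=O)C1CCCC1"),     # cyclopentanecarboxylic
        BuildingBlock("A4", 2, mw=123.1, smiles="OC(=O)c1ccncc1"),    # isonicotinic
    ]
    return starters, acids


def fullscale_building_blocks(seed: int = 0) -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """14 starters and a 450-acid candidate table that filters to 382.

    Acid molecular weights are drawn from a plausible small-acid range;
    exactly 382 candidates pass QC with ``max_mw=200``,
    ``banned_flags={"reactive"}`` and ``max_unassigned_stereocenters=0``
    (see ``FULLSCALE_BANNED_FLAGS``).  The rejected 68 are split among the
    three failure modes.  SMILES are omitted: the full-scale table
    exercises counting and statistics, not chemistry.
    """
    rng = np.random.default_rng(seed)
    starters = [
        BuildingBlock(f"S{i + 1:02d}", 1, mw=float(rng.uniform(150, 280)))
        for i in range(14)
    ]

    acids: list[BuildingBlock] = []
    n_pass, n_heavy, n_flagged, n_stereo = 382, 30, 20, 18
    mws_pass = rng.uniform(46, 199.5, size=n_pass)
    for i, mw in enumerate(mws_pass):
        acids.append(BuildingBlock(f"A{i + 1:03d}", 2, mw=float(mw)))
    j = n_pass
    for mw in rng.uniform(200.0, 350, size=n_heavy):
        acids.append(BuildingBlock(f"A{j + 1:03d}", 2, mw=float(mw)))
        j += 1
    for mw in rng.uniform(46, 199.5, size=n_flagged):
        acids.append(
            BuildingBlock(f"A{j + 1:03d}", 2, mw=float(mw), flags=frozenset({"reactive"}))
        )
        j += 1
    for mw in rng.uniform(46, 199.5, size=n_stereo):
        acids.append(
            BuildingBlock(f"A{j + 1:03d}", 2, mw=float(mw), n_unassigned_stereocenters=1)
        )
        j += 1
    order = rng.permutation(len(acids))
    return starters, [acids[i] for i in order]
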
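"""Combinatorial DEL design: building-block filtering, enumeration, and DNA encoding.

A two-cycle DNA-encoded library (DEL) is built from cycle-1 "starter"
building blocks (amide head groups on a photocleavable linker) acylated with
cycle-2 carboxylic acid "tails".  Each enumerated member carries a pair of
DNA codons — one per cycle — embedded in a fixed amplicon scaffold so that
sequencing a bead's tag identifies its structure.

The codon scheme here is a generic error-tolerant design: fixed-length codons
with a guaranteed minimum pairwise Hamming distance ``d_min`` within each
cycle, which permits correction of up to ``floor((d_min - 1) / 2)``
substitutions per codon.  A reserved codon, at distance >= ``d_min`` from
every cycle-1 codon, labels positive-control beads so deconvolution can
separate them from library beads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BuildingBlock",
    "LibraryMember",
    "AmpliconLayout",
    "Codebook",
    "CodebookCapacityError",
    "CONTROL_ID",
    "filter_building_blocks",
    "enumerate_library",
    "build_codebook",
    "similarity_profile",
    "read_bb_table",
    "write_bb_table",
]

#: structure id used for positive-control beads throughout the pipeline
CONTROL_ID = "__control__"

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BuildingBlock:
    """One monomer of the combinatorial library.

    Parameters
    ----------
    bb_id
        Identifier, unique within its cycle.
    cycle
        1 for starters (head groups), 2 for carboxylic acids (tails).
    mw
        Molecular weight in Da; must be positive.
    smiles
        Optional structure; only needed for similarity profiling.
    n_unassigned_stereocenters
        Count of stereocenters with unassigned configuration (a standard
        DEL quality-control concern: racemic or undefined centers make a
        decoded hit ambiguous).
    flags
        Structural-alert labels matched against a configurable ban list.
    """

    bb_id: str
    cycle: int
    mw: float
    smiles: str | None = None
    n_unassigned_stereocenters: int = 0
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cycle not in (1, 2):
            raise ValueError(f"cycle must be 1 or 2, got {self.cycle}")
        if not self.mw > 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if self.n_unassigned_stereocenters < 0:
            raise ValueError("n_unassigned_stereocenters must be >= 0")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class LibraryMember:
    """An enumerated (starter, acid) product of the two-cycle synthesis."""

    member_id: str
    starter_id: str
    acid_id: str


@dataclass(frozen=True)
class AmpliconLayout:
    """Fixed scaffold around the two codon slots.

    The per-bead amplicon reads ``const5 + codon1 + spacer + codon2 + const3``.
    """

    const5: str = "ACGTTGCAGT"
    spacer: str = "TGACCA"
    const3: str = "GTTCAGACGT"


class CodebookCapacityError(ValueError):
    """Raised when the requested codon set cannot be packed at ``d_min``."""


@dataclass
class Codebook:
    """DNA codon assignments for both cycles plus the amplicon scaffold."""

    codon_length: int
    cycle1_codons: dict[str, str]
    cycle2_codons: dict[str, str]
    reserved_control_codon: str
    layout: AmpliconLayout = field(default_factory=AmpliconLayout)

    # ------------------------------------------------------------------ #
    # geometry

    @property
    def amplicon_length(self) -> int:
        return (
            len(self.layout.const5)
            + 2 * self.codon_length
            + len(self.layout.spacer)
            + len(self.layout.const3)
        )

    @property
    def codon1_slice(self) -> slice:
        start = len(self.layout.const5)
        return slice(start, start + self.codon_length)

    @property
    def codon2_slice(self) -> slice:
        start = len(self.layout.const5) + self.codon_length + len(self.layout.spacer)
        return slice(start, start + self.codon_length)

    def amplicon(self, codon1: str, codon2: str) -> str:
        """Assemble the full read sequence for a codon pair."""
        lay = self.layout
        return lay.const5 + codon1 + lay.spacer + codon2 + lay.const3

    # ------------------------------------------------------------------ #
    # inverse maps

    def codon_to_bb(self, cycle: int) -> dict[str, str]:
        codons = self.cycle1_codons if cycle == 1 else self.cycle2_codons
        inv = {codon: bb for bb, codon in codons.items()}
        if len(inv) != len(codons):
            raise ValueError("codebook contains duplicate codons within a cycle")
        return inv

    # ------------------------------------------------------------------ #
    # serialization: TSV with header cycle, bb_id, codon; the reserved
    # control codon is stored as cycle 0.

    def to_tsv(self, path) -> None:
        rows = [(0, CONTROL_ID, self.reserved_control_codon)]
        rows += [(1, bb, c) for bb, c in sorted(self.cycle1_codons.items())]
        rows += [(2, bb, c) for bb, c in sorted(self.cycle2_codons.items())]
        pd.DataFrame(rows, columns=["cycle", "bb_id", "codon"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, layout: AmpliconLayout | None = None) -> "Codebook":
        df = pd.read_csv(path, sep="\t", dtype={"cycle": int, "bb_id": str, "codon": str})
        control = df[df["cycle"] == 0]
        if len(control) != 1:
            raise ValueError("codebook TSV must contain exactly one cycle-0 control codon")
        c1 = dict(zip(df.loc[df["cycle"] == 1, "bb_id"], df.loc[df["cycle"] == 1, "codon"]))
        c2 = dict(zip(df.loc[df["cycle"] == 2, "bb_id"], df.loc[df["cycle"] == 2, "codon"]))
        return cls(
            codon_length=len(control["codon"].iloc[0]),
            cycle1_codons=c1,
            cycle2_codons=c2,
            reserved_control_codon=control["codon"].iloc[0],
            layout=layout or AmpliconLayout(),
        )


# ---------------------------------------------------------------------- #
# operations


def filter_building_blocks(
    bbs: Sequence[BuildingBlock],
    max_mw: float,
    banned_flags: Iterable[str] = (),
    max_unassigned_stereocenters: int = 0,
) -> list[BuildingBlock]:
    """Apply the library QC filters to a building-block table.

    A block is retained iff its molecular weight is *strictly* below
    ``max_mw``, it carries none of the ``banned_flags``, and its count of
    unassigned stereocenters is at most ``max_unassigned_stereocenters``.
    Input order is preserved and the input list is not modified.
    """
    if not len(bbs):
        raise ValueError("building-block list is empty")
    if not max_mw > 0:
        raise ValueError(f"max_mw must be > 0, got {max_mw}")
    banned = frozenset(banned_flags)
    kept = [
        bb
        for bb in bbs
        if bb.mw < max_mw
        and not (bb.flags & banned)
        and bb.n_unassigned_stereocenters <= max_unassigned_stereocenters
    ]
    if not kept:
        warnings.warn("all building blocks were filtered out", stacklevel=2)
    return kept


def enumerate_library(
    starters: Sequence[BuildingBlock], acids: Sequence[BuildingBlock]
) -> list[LibraryMember]:
    """Enumerate the full starter x acid cross product.

    ``member_id`` is the deterministic concatenation ``"<starter_id>-<acid_id>"``.
    """
    for bbs, cycle, name in ((starters, 1, "starters"), (acids, 2, "acids")):
        ids = [bb.bb_id for bb in bbs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate bb_id among {name}")
        wrong = [bb.bb_id for bb in bbs if bb.cycle != cycle]
        if wrong:
            raise ValueError(f"{name} must all be cycle {cycle}; offenders: {wrong}")
        hyphenated = [i for i in ids if "-" in i]
        if hyphenated:
            # member ids are "<starter>-<acid>"; a hyphen inside a bb_id
            # would make them unparseable downstream
            raise ValueError(f"bb_id may not contain '-': {hyphenated}")
    return [
        LibraryMember(f"{s.bb_id}-{a.bb_id}", s.bb_id, a.bb_id)
        for s in starters
        for a in acids
    ]


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def _place_codons(
    n_needed: int,
    codon_length: int,
    d_min: int,
    rng: np.random.Generator,
    avoid: list[np.ndarray],
    max_failures: int = 20_000,
) -> list[np.ndarray]:
    """Greedy random codon placement with a rejection cap.

    ``avoid`` codons also count toward the distance constraint but are not
    returned (used for the reserved control codon).
    """
    if 4**codon_length < n_needed:
        raise CodebookCapacityError(
            f"{n_needed} codons requested but only {4 ** codon_length} "
            f"length-{codon_length} sequences exist"
        )
    placed: list[np.ndarray] = []
    failures = 0
    constraint = list(avoid)
    while len(placed) < n_needed:
        cand = rng.integers(0, 4, size=codon_length).astype(np.uint8)
        if all(_hamming(cand, c) >= d_min for c in constraint):
            placed.append(cand)
            constraint.append(cand)
            failures = 0
        else:
            failures += 1
            if failures >= max_failures:
                raise CodebookCapacityError(
                    f"could not place {n_needed} length-{codon_length} codons at "
                    f"pairwise Hamming distance >= {d_min} "
                    f"({len(placed)} placed before giving up)"
                )
    return placed


def _to_dna(arr: np.ndarray) -> str:
    return _DNA[arr].tobytes().decode("ascii")


def build_codebook(
    members: Sequence[LibraryMember],
    codon_length: int = 8,
    d_min: int = 3,
    seed: int = 0,
    layout: AmpliconLayout | None = None,
) -> Codebook:
    """Assign DNA codons to every building block appearing in ``members``.

    Placement is greedy random rejection sampling, deterministic given
    ``seed``.  Within each cycle all codon pairs are at Hamming distance
    >= ``d_min``; the reserved control codon satisfies the same bound
    against every cycle-1 codon.

    Raises
    ------
    CodebookCapacityError
        If the requested codons cannot be packed at ``d_min``.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    starter_ids = sorted({m.starter_id for m in members})
    acid_ids = sorted({m.acid_id for m in members})
    rng = np.random.default_rng(seed)

    control = rng.integers(0, 4, size=codon_length).astype(np.uint8)
    cycle1 = _place_codons(len(starter_ids), codon_length, d_min, rng, avoid=[control])
    cycle2 = _place_codons(len(acid_ids), codon_length, d_min, rng, avoid=[])

    return Codebook(
        codon_length=codon_length,
        cycle1_codons={bb: _to_dna(c) for bb, c in zip(starter_ids, cycle1)},
        cycle2_codons={bb: _to_dna(c) for bb, c in zip(acid_ids, cycle2)},
        reserved_control_codon=_to_dna(control),
        layout=layout or AmpliconLayout(),
    )


# ---------------------------------------------------------------------- #
# similarity profiling (2D fingerprint stand-in)


def _morgan_bits(smiles: str) -> frozenset[int]:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def similarity_profile(
    members: Sequence[LibraryMember],
    bb_smiles: Mapping[str, str],
    reference_smiles: str,
    fingerprint: Callable[[str], frozenset] | None = None,
) -> list[tuple[str, float]]:
    """Tanimoto similarity of each member to a reference compound.

    This is a 2D fingerprint profile (Morgan radius 2, 2048 bits by
    default): a coarse stand-in for 3D shape/color overlap scoring, useful
    only for ranking library members by scaffold similarity.  A member's
    structure is approximated as the disconnected union of its starter and
    acid fragments, since the package does not model the coupling
    chemistry.

    Members with missing or unparseable SMILES are skipped with a warning.
    ``fingerprint`` may be any callable mapping a SMILES string to a set of
    hashable features; Tanimoto is computed as ``|A & B| / |A | B|``.
    """
    fp = fingerprint or _morgan_bits
    ref = fp(reference_smiles)
    out: list[tuple[str, float]] = []
    for m in members:
        s_smi = bb_smiles.get(m.starter_id)
        a_smi = bb_smiles.get(m.acid_id)
        if not s_smi or not a_smi:
            warnings.warn(f"member {m.member_id}: missing SMILES, skipped", stacklevel=2)
            continue
        try:
            bits = fp(f"{s_smi}.{a_smi}")
        except ValueError as exc:
            warnings.warn(f"member {m.member_id}: {exc}, skipped", stacklevel=2)
            continue
        union = ref | bits
        tan = len(ref & bits) / len(union) if union else 0.0
        out.append((m.member_id, tan))
    return out


# ---------------------------------------------------------------------- #
# building-block table I/O: CSV with header
# bb_id,cycle,smiles,mw,n_unassigned_stereocenters,flags  (flags ;-separated)


def read_bb_table(path) -> list[BuildingBlock]:
    df = pd.read_csv(path, dtype={"bb_id": str, "smiles": str, "flags": str})
    bbs = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", None)
        flags = frozenset() if pd.isna(flags) or not flags else frozenset(str(flags).split(";"))
        smiles = getattr(row, "smiles", None)
        smiles = None if pd.isna(smiles) else str(smiles)
        bbs.append(
            BuildingBlock(
                bb_id=str(row.bb_id),
                cycle=int(row.cycle),
                mw=float(row.mw),
                smiles=smiles,
                n_unassigned_stereocenters=int(row.n_unassigned_stereocenters),
                flags=flags,
            )
        )
    return bbs


def write_bb_table(bbs: Sequence[BuildingBlock], path) -> None:
    pd.DataFrame(
        {
            "bb_id": [b.bb_id for b in bbs],
            "cycle": [b.cycle for b in bbs],
            "smiles": [b.smiles or "" for b in bbs],
            "mw": [b.mw for b in bbs],
            "n_unassigned_stereocenters": [b.n_unassigned_stereocenters for b in bbs],
            "flags": [";".join(sorted(b.flags)) for b in bbs],
        }
    ).to_csv(path, index=False)
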
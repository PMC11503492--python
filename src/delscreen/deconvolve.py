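"""Hit-collection deconvolution: codon decoding, bead calling, k class, FDR, enrichment.

After a screen, the sorted (hit) droplets' beads are sequenced.  Each read
is an amplicon carrying two codons that identify the bead's cycle-1 starter
and cycle-2 acid.  Decoding proceeds per codon slot: exact dictionary match,
else unique neighbor within a Hamming-distance budget ("corrected"), else
ambiguous or fail.  Reads are grouped per bead and a plurality vote calls
the bead's structure.

The replication statistic is the *k class*: the number of distinct beads in
a screen's hit collection called as the same structure.  Because the library
is deeply represented on beads, a genuine inhibitor is expected to be sorted
on several independent beads, whereas sporadic false sorts land on random
structures and rarely repeat.  How rarely is quantified by a sampling null:
random bead samples of the same size as a hit collection, drawn uniformly
over library structures, give the fraction of called structures reaching
each k by chance alone — the false discovery matrix.  For a 5,348-member
library sampled 1,500 beads at a time the per-structure count is
approximately Poisson(lambda = 1500/5348), putting the chance fraction at
k >= 3 near 1%.

Building-block enrichment asks whether a starter or acid appears in the
distinct-structure hit set more often than a uniform draw from the library
would allow (one-sided hypergeometric tail, Bonferroni-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .library_design import CONTROL_ID, Codebook, LibraryMember

__all__ = [
    "DecodeStatus",
    "DecodedRead",
    "KClassTable",
    "FDRMatrix",
    "decode_read",
    "decode_reads",
    "call_bead",
    "call_beads",
    "compute_kclass",
    "estimate_fdr",
    "bb_enrichment",
    "export_heatmap",
]


class DecodeStatus(str, Enum):
    EXACT = "exact"
    CORRECTED = "corrected"
    AMBIGUOUS = "ambiguous"
    FAIL = "fail"


@dataclass(frozen=True)
class DecodedRead:
    codon1_id: str | None
    codon2_id: str | None
    status: DecodeStatus
    is_control: bool = False


def _hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _SlotDecoder:
    """One codon slot: exact dict lookup with a Hamming-neighbor fallback."""

    def __init__(self, codons: dict[str, str], control_codon: str | None = None):
        self.exact = {codon: bb for bb, codon in codons.items()}
        if control_codon is not None:
            self.exact[control_codon] = CONTROL_ID
        self.entries = list(self.exact.items())

    def decode(self, observed: str, max_mismatch: int) -> tuple[str | None, DecodeStatus]:
        bb = self.exact.get(observed)
        if bb is not None:
            return bb, DecodeStatus.EXACT
        if max_mismatch > 0:
            candidates = [
                bb for codon, bb in self.entries if _hamming_str(observed, codon) <= max_mismatch
            ]
            if len(candidates) == 1:
                return candidates[0], DecodeStatus.CORRECTED
            if len(candidates) > 1:
                return None, DecodeStatus.AMBIGUOUS
        return None, DecodeStatus.FAIL


_STATUS_ORDER = {
    DecodeStatus.EXACT: 0,
    DecodeStatus.CORRECTED: 1,
    DecodeStatus.AMBIGUOUS: 2,
    DecodeStatus.FAIL: 3,
}


def decode_read(seq: str, codebook: Codebook, max_mismatch: int = 1) -> DecodedRead:
    """Decode one amplicon read into building-block ids.

    Slot statuses combine pessimistically: the read is ``exact`` only if
    both slots matched exactly, ``corrected`` if any slot needed
    correction, ``ambiguous``/``fail`` if any slot was.  A read whose
    codon-1 slot resolves to the reserved control codon is a control read;
    its codon-2 slot is not interpreted.  A length mismatch yields a
    ``fail`` status, not an exception.
    """
    dec1, dec2 = _slot_decoders(codebook)
    return _decode_one(seq, codebook, dec1, dec2, max_mismatch)


def _slot_decoders(codebook: Codebook) -> tuple[_SlotDecoder, _SlotDecoder]:
    dec1 = _SlotDecoder(codebook.cycle1_codons, codebook.reserved_control_codon)
    dec2 = _SlotDecoder(codebook.cycle2_codons)
    return dec1, dec2


def _decode_one(
    seq: str,
    codebook: Codebook,
    dec1: _SlotDecoder,
    dec2: _SlotDecoder,
    max_mismatch: int,
) -> DecodedRead:
    if len(seq) != codebook.amplicon_length:
        return DecodedRead(None, None, DecodeStatus.FAIL)
    id1, st1 = dec1.decode(seq[codebook.codon1_slice], max_mismatch)
    if id1 == CONTROL_ID:
        return DecodedRead(None, None, st1, is_control=True)
    id2, st2 = dec2.decode(seq[codebook.codon2_slice], max_mismatch)
    status = max(st1, st2, key=_STATUS_ORDER.__getitem__)
    if status in (DecodeStatus.AMBIGUOUS, DecodeStatus.FAIL):
        return DecodedRead(None, None, status)
    return DecodedRead(id1, id2, status)


def decode_reads(
    seqs: list[str], codebook: Codebook, max_mismatch: int = 1
) -> list[DecodedRead]:
    """Decode many reads, building the slot dictionaries once."""
    dec1, dec2 = _slot_decoders(codebook)
    return [_decode_one(s, codebook, dec1, dec2, max_mismatch) for s in seqs]


def call_bead(
    reads_for_bead: list[DecodedRead], min_support: float = 0.5
) -> str | None:
    """Plurality structure call for one bead's reads.

    Non-fail reads form the denominator; ambiguous reads count there but
    cannot vote.  The winning (codon1, codon2) pair — or the control label —
    must reach a support fraction of at least ``min_support``, and an exact
    tie for the top vote is a no-call (``None``).  Control beads return the
    reserved control id.
    """
    usable = [r for r in reads_for_bead if r.status != DecodeStatus.FAIL]
    if not usable:
        return None
    votes: dict[str, int] = {}
    for r in usable:
        if r.is_control:
            votes[CONTROL_ID] = votes.get(CONTROL_ID, 0) + 1
        elif r.codon1_id is not None and r.codon2_id is not None:
            key = f"{r.codon1_id}-{r.codon2_id}"
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    top = max(votes.values())
    winners = [k for k, v in votes.items() if v == top]
    if len(winners) != 1 or top / len(usable) < min_support:
        return None
    return winners[0]


def call_beads(
    reads: pd.DataFrame, codebook: Codebook, max_mismatch: int = 1, min_support: float = 0.5
) -> pd.DataFrame:
    """Decode and call a whole read set.

    ``reads`` needs columns ``read_id`` (``<bead_id>:<n>``) and ``seq``.
    Returns one row per bead: ``bead_id, structure_id, n_reads, n_usable``;
    ``structure_id`` is NaN for no-calls.
    """
    dec1, dec2 = _slot_decoders(codebook)
    bead_ids = reads["read_id"].str.rsplit(":", n=1).str[0]
    rows = []
    for bead_id, grp in reads.groupby(bead_ids, sort=True):
        decoded = [
            _decode_one(s, codebook, dec1, dec2, max_mismatch) for s in grp["seq"]
        ]
        usable = sum(r.status != DecodeStatus.FAIL for r in decoded)
        rows.append(
            {
                "bead_id": bead_id,
                "structure_id": call_bead(decoded, min_support),
                "n_reads": len(decoded),
                "n_usable": usable,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# k class


@dataclass
class KClassTable:
    """Per-(structure, screen) distinct-bead counts.

    ``rows`` has columns ``structure_id, screen_id, k`` with ``k >= 1``.
    """

    rows: pd.DataFrame

    def summed(self) -> pd.Series:
        """k summed across screens, indexed by structure_id."""
        return self.rows.groupby("structure_id")["k"].sum()

    def total_beads(self) -> int:
        return int(self.rows["k"].sum())


def compute_kclass(bead_calls: pd.DataFrame) -> KClassTable:
    """Tabulate k — the distinct-bead count per structure per screen.

    ``bead_calls`` needs columns ``bead_id, screen_id, structure_id``;
    no-call rows (NaN structure) are dropped.  Duplicate bead ids within a
    screen are an error: k counts *distinct* beads.
    """
    calls = bead_calls.dropna(subset=["structure_id"])
    dup = calls.duplicated(subset=["screen_id", "bead_id"])
    if dup.any():
        raise ValueError(
            f"duplicate bead ids within a screen: {sorted(calls.loc[dup, 'bead_id'].unique()[:5])}"
        )
    rows = (
        calls.groupby(["structure_id", "screen_id"], sort=True)
        .size()
        .rename("k")
        .reset_index()
    )
    return KClassTable(rows=rows)


# ---------------------------------------------------------------------- #
# false discovery matrix


@dataclass
class FDRMatrix:
    """k-threshold -> chance fraction of called structures at >= k.

    ``table`` has columns ``k, fdr_mean, fdr_rep1..fdr_repN, degenerate``;
    ``degenerate`` marks thresholds where no replicate produced any
    structure at >= k (reported as 0).  FDR is nonincreasing in k and
    FDR(1) = 1 by construction.
    """

    table: pd.DataFrame
    sample_size: int
    n_samples: int
    seed: int

    def fdr(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k, "fdr_mean"]
        if row.empty:
            raise KeyError(f"k = {k} not in matrix (k_max = {self.table['k'].max()})")
        return float(row.iloc[0])


def estimate_fdr(
    library: list[LibraryMember] | int,
    sample_size: int = 1500,
    n_samples: int = 3,
    k_max: int = 10,
    seed: int = 0,
) -> FDRMatrix:
    """Sampling null for the k statistic.

    Each replicate draws ``sample_size`` beads uniformly over library
    structures with replacement (the bead pool is deep enough that
    replacement is a faithful null) and computes, for each threshold k,
    the fraction of *called* (observed) structures with count >= k.  The
    replicates emulate sequencing random unsorted bead samples of the same
    size as a typical hit collection.

    ``library`` may be the member list or just the library size.
    """
    n_structures = library if isinstance(library, int) else len(library)
    if n_structures < 1:
        raise ValueError("library must be non-empty")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    rng = np.random.default_rng(seed)
    per_rep = np.zeros((n_samples, k_max))
    for rep in range(n_samples):
        counts = np.bincount(rng.integers(0, n_structures, size=sample_size), minlength=n_structures)
        observed = int((counts > 0).sum())
        for k in range(1, k_max + 1):
            per_rep[rep, k - 1] = (counts >= k).sum() / observed

    table = pd.DataFrame({"k": np.arange(1, k_max + 1)})
    for rep in range(n_samples):
        table[f"fdr_rep{rep + 1}"] = per_rep[rep]
    table["fdr_mean"] = per_rep.mean(axis=0)
    table["degenerate"] = (per_rep == 0).all(axis=0)
    return FDRMatrix(table=table, sample_size=sample_size, n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------- #
# building-block enrichment


def bb_enrichment(
    hit_structures: list[str] | set[str],
    library: list[LibraryMember],
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation test per building block.

    The hit set is reduced to distinct structures (replicate beads of one
    structure carry no extra evidence about its building blocks).  For a
    block present in ``n_lib_containing`` of the ``n_lib_total`` library
    members, the p-value is the upper hypergeometric tail of observing at
    least ``n_hits_containing`` members carrying it among
    ``n_hits_total`` distinct structures drawn from the library.
    Bonferroni adjustment multiplies by the number of blocks tested
    (clipped at 1).

    Returns a DataFrame sorted by p: ``bb_id, cycle, n_hits_containing,
    n_hits_total, n_lib_containing, n_lib_total, p, p_adjusted``.
    """
    hits = set(hit_structures)
    member_ids = {m.member_id for m in library}
    stray = hits - member_ids
    if stray:
        raise ValueError(f"hit structures not in library: {sorted(stray)[:5]}")
    if not hits:
        warnings.warn("empty hit set: no enrichment computed", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "bb_id", "cycle", "n_hits_containing", "n_hits_total",
                "n_lib_containing", "n_lib_total", "p", "p_adjusted",
            ]
        )

    by_member = {m.member_id: (m.starter_id, m.acid_id) for m in library}
    n_lib_total = len(library)
    n_hits_total = len(hits)

    lib_counts: dict[tuple[str, int], int] = {}
    for m in library:
        lib_counts[(m.starter_id, 1)] = lib_counts.get((m.starter_id, 1), 0) + 1
        lib_counts[(m.acid_id, 2)] = lib_counts.get((m.acid_id, 2), 0) + 1
    hit_counts: dict[tuple[str, int], int] = {}
    for sid in hits:
        starter, acid = by_member[sid]
        hit_counts[(starter, 1)] = hit_counts.get((starter, 1), 0) + 1
        hit_counts[(acid, 2)] = hit_counts.get((acid, 2), 0) + 1

    n_tests = len(lib_counts)
    rows = []
    for (bb_id, cycle), n_lib_containing in sorted(lib_counts.items()):
        n_hit = hit_counts.get((bb_id, cycle), 0)
        # P(X >= n_hit), X ~ Hypergeom(N=n_lib_total, K=n_lib_containing, n=n_hits_total)
        p = float(hypergeom.sf(n_hit - 1, n_lib_total, n_lib_containing, n_hits_total))
        rows.append(
            {
                "bb_id": bb_id,
                "cycle": cycle,
                "n_hits_containing": n_hit,
                "n_hits_total": n_hits_total,
                "n_lib_containing": n_lib_containing,
                "n_lib_total": n_lib_total,
                "p": p,
                "p_adjusted": min(1.0, p * n_tests),
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------- #
# heat map


def export_heatmap(
    kclass: KClassTable, starters: list[str], acids: list[str]
) -> pd.DataFrame:
    """Starter-row x acid-column matrix of k summed across screens.

    Cells for structures never observed are 0.  Control calls must be
    removed before tabulation; an unresolvable structure id is an error.
    """
    summed = kclass.summed()
    mat = pd.DataFrame(0, index=list(starters), columns=list(acids), dtype=int)
    for structure_id, k in summed.items():
        starter, _, acid = str(structure_id).partition("-")
        if starter not in mat.index or acid not in mat.columns:
            raise ValueError(f"structure {structure_id!r} not resolvable to (starter, acid)")
        mat.at[starter, acid] = int(k)
    mat.index.name = "starter_id"
    mat.columns.name = "acid_id"
    return mat
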
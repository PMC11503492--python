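"""Synthetic droplet screen and bead-barcode sequencing generator.

Emulates the statistical structure of an activity-based droplet screen of a
bead-displayed DEL against a fluorescent in vitro transcription-translation
(IVTT) reporter:

* beads are encapsulated at low Poisson occupancy (default lambda = 0.06,
  i.e. ~90,000 beads per 1.5 million droplets, so multi-bead droplets are
  rare);
* droplets without an inhibitor draw fluorescence from a Gaussian negative
  population Normal(neg_mu, neg_sigma);
* a droplet containing one or more active or positive-control beads has its
  mean scaled by (1 - max inhibition among its occupants) with unchanged
  sigma — the dominant inhibitor wins;
* positive-control beads (a nonselective translation inhibitor on a
  photocleavable linker) are spiked in at a configurable fraction.

Fluorescence is not clipped at zero: detector offset is arbitrary in RFU and
noise may take the signal slightly negative; downstream code tolerates this.

Sequencing reads are per-bead amplicons of the codebook layout with i.i.d.
per-base substitution errors; read ids carry the bead id as simulation
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_design import CONTROL_ID, Codebook, LibraryMember

__all__ = [
    "ScreenParams",
    "SimResult",
    "simulate_screen",
    "generate_reads",
    "write_fastq",
    "read_fastq",
    "write_events_csv",
    "read_events_csv",
]


@dataclass
class ScreenParams:
    """Screen-level simulation settings.

    Attributes
    ----------
    n_droplets
        Number of droplets generated.
    droplet_rate
        Droplet generation rate in droplets/s; timestamps are spaced at
        ``1 / droplet_rate``.
    bead_lambda
        Mean beads per droplet (Poisson).  Default 0.06 reproduces the
        ~90,000 beads in ~1.5e6 droplets regime.
    neg_mu, neg_sigma
        Mean and SD (RFU) of the negative (uninhibited) droplet population.
        The defaults (100, 5) give Z' = 0.70 against a full-inhibition
        positive control — a deliberate calibration to a high-quality
        droplet IVTT assay, not a measured value.
    control_bead_fraction
        Probability that a bead is a positive-control bead rather than a
        library bead.
    control_inhibition
        Inhibition fraction conferred by a control bead (1.0 = complete
        knockdown of the reporter).
    active_map
        structure_id -> inhibition fraction in [0, 1] for planted actives;
        unlisted structures are inactive.
    beads_per_structure
        Physical copies of each library structure in the screened bead
        pool; library beads are drawn from this finite pool without
        replacement.  Default 18 mimics deep (~20x) library representation.
    detectable_inhibition
        Ground-truth labelling bound: a droplet is labelled an expected hit
        iff its strongest occupant has inhibition >= this value.  At the
        default assay settings, 0.5 places the droplet mean 5 sigma below
        the sorting threshold, i.e. essentially always sortable.
    seed
        RNG seed; identical params + seed give byte-identical output.
    """

    n_droplets: int
    droplet_rate: float = 250.0
    bead_lambda: float = 0.06
    neg_mu: float = 100.0
    neg_sigma: float = 5.0
    control_bead_fraction: float = 0.01
    control_inhibition: float = 1.0
    active_map: dict[str, float] = field(default_factory=dict)
    beads_per_structure: int = 18
    detectable_inhibition: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be > 0")
        if self.droplet_rate <= 0:
            raise ValueError("droplet_rate must be > 0")
        if self.bead_lambda < 0:
            raise ValueError("bead_lambda must be >= 0")
        if self.neg_sigma <= 0:
            raise ValueError("neg_sigma must be > 0")
        if not 0 <= self.control_bead_fraction <= 1:
            raise ValueError("control_bead_fraction must be in [0, 1]")
        for name, v in [("control_inhibition", self.control_inhibition)] + [
            (f"active_map[{k}]", v) for k, v in self.active_map.items()
        ]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beads_per_structure < 1:
            raise ValueError("beads_per_structure must be >= 1")


@dataclass
class SimResult:
    """Events, beads, and ground truth of one simulated screen.

    events
        One row per droplet: ``t`` (s), ``fluorescence`` (RFU),
        ``bead_ids`` (``;``-joined, empty string if unoccupied).
    beads
        One row per bead: ``bead_id``, ``kind`` (library / control_pos),
        ``structure_id`` (library member id or the reserved control id),
        ``droplet`` (row index into events), ``inhibition``.
    truth
        One row per droplet: ``max_inhibition``, ``n_beads``,
        ``expected_hit`` (strongest occupant above the detectability
        bound).
    """

    events: pd.DataFrame
    beads: pd.DataFrame
    truth: pd.DataFrame
    params: ScreenParams


def simulate_screen(params: ScreenParams, library: list[LibraryMember]) -> SimResult:
    """Generate a droplet event stream with planted actives and ground truth."""
    params.validate()
    structure_ids = [m.member_id for m in library]
    unknown = set(params.active_map) - set(structure_ids)
    if unknown:
        raise ValueError(f"active_map references structures not in library: {sorted(unknown)}")

    rng = np.random.default_rng(params.seed)
    n = params.n_droplets

    beads_per_droplet = rng.poisson(params.bead_lambda, size=n)
    total_beads = int(beads_per_droplet.sum())

    is_control = rng.random(total_beads) < params.control_bead_fraction
    n_lib = int((~is_control).sum())

    # library beads come from a finite pool: beads_per_structure copies of
    # each structure, drawn without replacement (screening a physical aliquot)
    pool_size = len(structure_ids) * params.beads_per_structure
    if n_lib > pool_size:
        raise ValueError(
            f"screen needs {n_lib} library beads but the pool holds only "
            f"{pool_size} ({len(structure_ids)} structures x "
            f"{params.beads_per_structure} beads); increase beads_per_structure"
        )
    pool = np.repeat(np.arange(len(structure_ids)), params.beads_per_structure)
    lib_struct_idx = rng.permutation(pool)[:n_lib]

    inhibition_by_struct = np.zeros(len(structure_ids))
    for sid, inh in params.active_map.items():
        inhibition_by_struct[structure_ids.index(sid)] = inh

    bead_inhibition = np.empty(total_beads)
    bead_inhibition[is_control] = params.control_inhibition
    bead_inhibition[~is_control] = inhibition_by_struct[lib_struct_idx]

    bead_structure = np.empty(total_beads, dtype=object)
    bead_structure[is_control] = CONTROL_ID
    bead_structure[~is_control] = np.asarray(structure_ids, dtype=object)[lib_struct_idx]

    bead_droplet = np.repeat(np.arange(n), beads_per_droplet)
    bead_ids = np.array([f"bead{i:07d}" for i in range(total_beads)], dtype=object)

    beads = pd.DataFrame(
        {
            "bead_id": bead_ids,
            "kind": np.where(is_control, "control_pos", "library"),
            "structure_id": bead_structure,
            "droplet": bead_droplet,
            "inhibition": bead_inhibition,
        }
    )

    max_inh = np.zeros(n)
    if total_beads:
        grouped = beads.groupby("droplet")["inhibition"].max()
        max_inh[grouped.index.to_numpy()] = grouped.to_numpy()

    fluor = rng.normal(params.neg_mu * (1.0 - max_inh), params.neg_sigma)

    bead_id_strings = np.full(n, "", dtype=object)
    if total_beads:
        joined = beads.groupby("droplet")["bead_id"].agg(";".join)
        bead_id_strings[joined.index.to_numpy()] = joined.to_numpy()

    events = pd.DataFrame(
        {
            "t": np.arange(n) / params.droplet_rate,
            "fluorescence": fluor,
            "bead_ids": bead_id_strings,
        }
    )
    truth = pd.DataFrame(
        {
            "max_inhibition": max_inh,
            "n_beads": beads_per_droplet,
            "expected_hit": max_inh >= params.detectable_inhibition,
        }
    )
    return SimResult(events=events, beads=beads, truth=truth, params=params)


# ---------------------------------------------------------------------- #
# sequencing reads


def generate_reads(
    sorted_beads: pd.DataFrame,
    codebook: Codebook,
    reads_per_bead: int = 20,
    sub_error_rate: float = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Amplicon reads for a bead collection, with i.i.d. substitution errors.

    ``sorted_beads`` needs columns ``bead_id`` and ``structure_id``
    (member id ``"<starter>-<acid>"`` or the reserved control id).  Control
    beads emit the reserved control codon in both codon slots.  Read ids
    are ``<bead_id>:<n>``; every read has the full amplicon length and
    constant placeholder quality.
    """
    if reads_per_bead <= 0:
        raise ValueError("reads_per_bead must be > 0")
    if not 0 <= sub_error_rate < 1:
        raise ValueError("sub_error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    member_codons: dict[str, tuple[str, str]] = {}

    templates = []
    ids = []
    for bead_id, structure_id in zip(sorted_beads["bead_id"], sorted_beads["structure_id"]):
        if structure_id == CONTROL_ID:
            c1 = c2 = codebook.reserved_control_codon
        else:
            if structure_id not in member_codons:
                starter, _, acid = structure_id.partition("-")
                try:
                    member_codons[structure_id] = (
                        codebook.cycle1_codons[starter],
                        codebook.cycle2_codons[acid],
                    )
                except KeyError as exc:
                    raise KeyError(
                        f"structure {structure_id!r}: no codon for building block {exc}"
                    ) from None
            c1, c2 = member_codons[structure_id]
        templates.append(codebook.amplicon(c1, c2))
        ids.append(bead_id)

    if not templates:
        return []

    length = codebook.amplicon_length
    tmpl = np.frombuffer("".join(templates).encode("ascii"), dtype=np.uint8).reshape(
        len(templates), length
    )
    seqs = np.repeat(tmpl, reads_per_bead, axis=0).copy()

    if sub_error_rate > 0:
        mask = rng.random(seqs.shape) < sub_error_rate
        # substitute with one of the three *other* bases: shift the base
        # index by 1..3 mod 4
        base_idx = np.zeros_like(seqs)
        for i, b in enumerate(b"ACGT"):
            base_idx[seqs == b] = i
        shift = rng.integers(1, 4, size=seqs.shape)
        new_idx = (base_idx + shift) % 4
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs[mask] = lut[new_idx[mask]]

    records = []
    qual = [40] * length
    for row, (bead_i, read_i) in zip(
        seqs, ((b, r) for b in range(len(ids)) for r in range(reads_per_bead))
    ):
        rec = SeqRecord(
            Seq(row.tobytes().decode("ascii")),
            id=f"{ids[bead_i]}:{read_i}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fastq"))


# ---------------------------------------------------------------------- #
# event stream I/O: CSV `t,fluorescence,bead_ids`


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bead_ids": str})
    df["bead_ids"] = df["bead_ids"].fillna("")
    return df
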
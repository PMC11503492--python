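"""End-to-end orchestration: design -> simulate -> sort -> decode -> analyze.

Each stage gets its own seed derived from the global one by hashing the
stage name, so a stage can be re-run in isolation from its serialized
inputs and still reproduce the full-pipeline output.  Identical config +
seed yields byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconvolve, droplet_sim, library_design, sorter
from .config import PipelineConfig
from .library_design import CONTROL_ID

__all__ = ["stage_seed", "run_pipeline"]

log = logging.getLogger("delscreen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole screen pipeline and write all artifacts.

    Writes into ``config.out_dir``: the filtered library and codebook, the
    droplet event stream, sort decisions and threshold trace, the transient
    histogram, hit-collection FASTQ, bead calls, the k-class table, FDR
    matrix, enrichment table, heat map, and a JSON run report (also
    returned).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": json.loads(config.model_dump_json()), "stages": {}}

    # ---- design ------------------------------------------------------- #
    design = _stage("design")(_design)
    library, codebook, starters, acids = design(config, out)
    report["library_size"] = len(library)
    report["n_starters"] = len(starters)
    report["n_acids"] = len(acids)

    # ---- simulate ----------------------------------------------------- #
    simulate = _stage("simulate")(_simulate)
    sim = simulate(config, library, out)
    report["n_droplets"] = int(len(sim.events))
    report["n_beads"] = int(len(sim.beads))

    # ---- sort --------------------------------------------------------- #
    sort = _stage("sort")(_sort)
    decisions, trace, qc = sort(config, sim, out)
    report["zprime"] = qc.zprime
    report["overall_hit_rate"] = qc.overall_hit_rate
    report["library_hit_rate"] = qc.library_hit_rate
    report["control_hit_rate"] = qc.control_hit_rate
    report["occupied_fraction"] = qc.occupied_fraction
    report["n_hits"] = int(decisions["is_hit"].sum())

    # ---- decode ------------------------------------------------------- #
    decode = _stage("decode")(_decode)
    bead_calls = decode(config, sim, decisions, codebook, out)
    report["n_hit_beads"] = int(len(bead_calls))
    report["n_called_beads"] = int(bead_calls["structure_id"].notna().sum())

    # ---- analyze ------------------------------------------------------ #
    analyze = _stage("analyze")(_analyze)
    analysis = analyze(config, bead_calls, library, starters, acids, out)
    report.update(analysis)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


# ---------------------------------------------------------------------- #
# stage bodies


def _design(config: PipelineConfig, out: Path):
    bbs = library_design.read_bb_table(config.bb_table)
    starters_raw = [b for b in bbs if b.cycle == 1]
    acids_raw = [b for b in bbs if b.cycle == 2]
    # the MW / alert / stereochemistry QC applies to the acid (cycle 2) set;
    # starters are a bespoke hand-curated series
    acids = library_design.filter_building_blocks(
        acids_raw,
        max_mw=config.max_mw,
        banned_flags=config.banned_flags,
        max_unassigned_stereocenters=config.max_unassigned_stereocenters,
    )
    library = library_design.enumerate_library(starters_raw, acids)
    codebook = library_design.build_codebook(
        library,
        codon_length=config.codon_length,
        d_min=config.d_min,
        seed=stage_seed(config.seed, "design"),
    )
    library_design.write_bb_table(starters_raw + acids, out / "building_blocks.filtered.csv")
    pd.DataFrame(
        {
            "member_id": [m.member_id for m in library],
            "starter_id": [m.starter_id for m in library],
            "acid_id": [m.acid_id for m in library],
        }
    ).to_csv(out / "library.csv", index=False)
    codebook.to_tsv(out / "codebook.tsv")
    return library, codebook, [b.bb_id for b in starters_raw], [b.bb_id for b in acids]


def _simulate(config: PipelineConfig, library, out: Path):
    seed = stage_seed(config.seed, "simulate")
    rng_pick = np.random.default_rng(stage_seed(config.seed, "actives"))
    n_active = min(config.n_active_structures, len(library))
    active_idx = rng_pick.choice(len(library), size=n_active, replace=False)
    active_map = {library[i].member_id: config.active_inhibition for i in sorted(active_idx)}
    params = droplet_sim.ScreenParams(
        n_droplets=config.n_droplets,
        droplet_rate=config.droplet_rate,
        bead_lambda=config.bead_lambda,
        neg_mu=config.neg_mu,
        neg_sigma=config.neg_sigma,
        control_bead_fraction=config.control_bead_fraction,
        control_inhibition=config.control_inhibition,
        active_map=active_map,
        beads_per_structure=config.beads_per_structure,
        detectable_inhibition=config.detectable_inhibition,
        seed=seed,
    )
    sim = droplet_sim.simulate_screen(params, library)
    droplet_sim.write_events_csv(sim.events, out / "events.csv")
    sim.beads.to_csv(out / "beads.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "active_map": active_map,
                "n_expected_hits": int(sim.truth["expected_hit"].sum()),
            },
            indent=2,
        )
        + "\n"
    )
    return sim


def _sort(config: PipelineConfig, sim, out: Path):
    decisions, trace = sorter.dynamic_threshold_sort(
        sim.events,
        k_sigma=config.k_sigma,
        t_window=config.t_window,
        min_events=config.min_window_events,
    )
    hist = sorter.bin_transient(sim.events, t_bin=config.t_bin, f_bin=config.f_bin)
    qc = sorter.screen_qc(decisions, sim.events, beads=sim.beads)
    decisions.to_csv(out / "decisions.csv", index=False)
    trace.to_csv(out / "threshold_trace.csv", index=False)
    hist.to_frame().to_csv(out / "transient_histogram.tsv", sep="\t")
    (out / "qc.json").write_text(json.dumps(qc.to_dict(), indent=2) + "\n")
    return decisions, trace, qc


def _decode(config: PipelineConfig, sim, decisions, codebook, out: Path):
    hit_droplets = decisions.index[decisions["is_hit"]]
    hit_beads = sim.beads[sim.beads["droplet"].isin(hit_droplets)]
    reads = droplet_sim.generate_reads(
        hit_beads,
        codebook,
        reads_per_bead=config.reads_per_bead,
        sub_error_rate=config.sub_error_rate,
        seed=stage_seed(config.seed, "sequence"),
    )
    droplet_sim.write_fastq(reads, out / "hit_reads.fastq")
    read_df = pd.DataFrame({"read_id": [r.id for r in reads], "seq": [str(r.seq) for r in reads]})
    if len(read_df):
        bead_calls = deconvolve.call_beads(
            read_df, codebook, max_mismatch=config.max_mismatch, min_support=config.min_support
        )
    else:
        bead_calls = pd.DataFrame(columns=["bead_id", "structure_id", "n_reads", "n_usable"])
    bead_calls.to_csv(out / "bead_calls.csv", index=False)
    return bead_calls


def _analyze(config: PipelineConfig, bead_calls, library, starters, acids, out: Path):
    calls = bead_calls.assign(screen_id="screen1")
    lib_calls = calls[calls["structure_id"].notna() & (calls["structure_id"] != CONTROL_ID)]
    kclass = deconvolve.compute_kclass(lib_calls)
    kclass.rows.to_csv(out / "kclass.csv", index=False)

    fdr = deconvolve.estimate_fdr(
        library,
        sample_size=config.sample_size,
        n_samples=config.n_samples,
        k_max=config.k_max,
        seed=stage_seed(config.seed, "fdr"),
    )
    fdr.table.to_csv(out / "fdr_matrix.csv", index=False)

    summed = kclass.summed()
    hit_set = summed.index[summed >= config.enrichment_k_min].tolist()
    enrich = deconvolve.bb_enrichment(hit_set, library) if hit_set else pd.DataFrame()
    enrich.to_csv(out / "enrichment.csv", index=False)

    heatmap = deconvolve.export_heatmap(kclass, starters, acids)
    heatmap.to_csv(out / "heatmap.tsv", sep="\t")

    n_ctrl = int((bead_calls["structure_id"] == CONTROL_ID).sum())
    return {
        "n_hit_structures": int(kclass.rows["structure_id"].nunique()),
        "n_control_beads_called": n_ctrl,
        "fdr_matrix": fdr.table[["k", "fdr_mean"]].to_dict(orient="records"),
        "enriched_bbs": (
            enrich.loc[enrich["p_adjusted"] < 0.05, "bb_id"].tolist() if len(enrich) else []
        ),
        "hit_set_k_min": config.enrichment_k_min,
        "n_hit_set_structures": len(hit_set),
    }
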
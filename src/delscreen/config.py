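"""Pipeline configuration: validated parameter bundle loaded from YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    """All pipeline parameters in one validated object.

    Unknown keys are rejected on load so a typo cannot silently fall back
    to a default.  ``seed`` is the single global seed; per-stage seeds are
    derived from it deterministically (see ``pipeline.stage_seed``).
    """

    model_config = ConfigDict(extra="forbid")

    # paths
    bb_table: Path
    out_dir: Path

    # library design
    max_mw: float = Field(200.0, gt=0)
    banned_flags: list[str] = Field(default_factory=list)
    max_unassigned_stereocenters: int = Field(0, ge=0)
    codon_length: int = Field(8, ge=1)
    d_min: int = Field(3, ge=1)

    # screen simulation
    n_droplets: int = Field(100_000, gt=0)
    droplet_rate: float = Field(250.0, gt=0)
    bead_lambda: float = Field(0.06, ge=0)
    neg_mu: float = 100.0
    neg_sigma: float = Field(5.0, gt=0)
    control_bead_fraction: float = Field(0.01, ge=0, le=1)
    control_inhibition: float = Field(1.0, ge=0, le=1)
    beads_per_structure: int = Field(18, ge=1)
    n_active_structures: int = Field(3, ge=0)
    active_inhibition: float = Field(0.9, ge=0, le=1)
    detectable_inhibition: float = Field(0.5, ge=0, le=1)

    # sorting
    k_sigma: float = Field(5.0, gt=0)
    t_window: float = Field(30.0, gt=0)
    f_bin: float = Field(7.0, gt=0)
    t_bin: float = Field(30.0, gt=0)
    min_window_events: int = Field(100, ge=1)

    # sequencing + deconvolution
    reads_per_bead: int = Field(20, ge=1)
    sub_error_rate: float = Field(0.01, ge=0, lt=1)
    max_mismatch: int = Field(1, ge=0)
    min_support: float = Field(0.5, gt=0, le=1)

    # null / enrichment analysis
    sample_size: int = Field(1500, ge=1)
    n_samples: int = Field(3, ge=1)
    k_max: int = Field(10, ge=1)
    enrichment_k_min: int = Field(3, ge=1)

    seed: int = 0

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return PipelineConfig(**data)
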
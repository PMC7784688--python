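"""Pipeline configuration: a strict YAML-backed schema.

Unknown keys are rejected and every threshold is range-checked; defaults
are the study's stated values (hit filters, spacer thresholds, the 50%
wGRR network threshold, the five-day AUC window).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # input paths (subcommands require the subset they consume)
    proteome_fastas: list[str] = Field(default_factory=list)
    hits_table: str | None = None
    prophage_fasta: str | None = None
    prophage_table: str | None = None
    infection_matrix: str | None = None
    strain_table: str | None = None
    rm_table: str | None = None
    rm_proteins_fasta: str | None = None
    crispr_table: str | None = None
    trajectory_csv: str | None = None

    # thresholds
    wgrr_network_threshold: float = Field(0.5, ge=0.0, le=1.0)
    max_evalue: float = Field(1e-4, gt=0.0)
    min_identity_pct: float = Field(35.0, ge=0.0, le=100.0)
    min_coverage: float = Field(0.5, ge=0.0, le=1.0)
    coverage_mode: Literal["both", "query"] = "both"
    spacer_min_identity: float = Field(0.9, ge=0.0, le=1.0)
    spacer_min_coverage: float = Field(0.9, ge=0.0, le=1.0)
    two_site_mode: bool = False
    include_self: bool = True
    auc_window: int = Field(5, ge=1)
    n_replicates: int = Field(3, ge=1)

    seed: int = 0
    outdir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return PipelineConfig(**data)
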
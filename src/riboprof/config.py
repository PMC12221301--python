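"""Pipeline configuration: a strict YAML-backed parameter block.

Unknown keys are rejected so a typo cannot silently fall back to a default.
The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths
    output_dir: str = "results/pipeline"
    fasta: str | None = None
    annotation: str | None = None
    alignments_dir: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None

    # simulation block
    n_genes: int = 2000
    n_reps: int = 3
    dispersion: float = 0.1
    frac_ko_effect: float = 0.05
    dlog2_ko: float = -1.0
    frac_tm_effect: float = 0.02
    dlog2_tm: float = 1.5
    frac_blunted: float = 0.5
    uorf_load: float = 0.1
    n_footprint_transcripts: int = 200

    # quantify block
    psite_offset: int = 12
    weighting: str = "fractional"
    rpk_threshold: float = 2.5
    filter_scope: str = "all"

    # diffte block
    contrast: str = "ko"
    alpha: float = 0.05
    lfc_cut: float = 1.0
    size_factor_strata: str | None = "assay"

    # metagene block
    metagene_anchor: str = "morf_start"
    metagene_normalization: str = "per-transcript-mean"
    min_uorf_gap: int = 50

    # global
    seed: int = 0
    log_level: str = "INFO"
    threads: int = 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
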
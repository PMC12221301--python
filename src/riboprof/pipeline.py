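"""Stage orchestration: simulate -> quantify -> diffte / metagene / uorf-shift.

Each stage reads the previous stage's files from the output directory, writes
its own outputs, and records what it did in a JSON manifest (parameters, seed,
package version, SHA-256 checksums of inputs and outputs). Stages fail fast
with a message naming the stage to run first when an upstream file is absent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import discover_all_uorfs, discover_uorfs, read_transcripts
from .config import PipelineConfig
from .diffte import blunted_induction, call_significant, run_te_test
from .metagene import metagene_profile
from .quantify import (
    CountMatrix,
    assign_psite,
    count_cds,
    default_offsets,
    qc_region_enrichment,
    read_alignments,
    rpk_filter,
    write_alignments,
)
from .synthetic import (
    SimulationConfig,
    make_effect_table,
    make_transcriptome,
    simulate_counts,
    simulate_footprints,
    write_bed12,
    write_fasta,
    write_truth,
)
from .uorf_analysis import te_shift_by_class, uorf_occupancy

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "quantify", "diffte", "metagene", "uorf-shift"]


class StageDependencyError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"missing {path.name}: run the '{producer}' stage first"
        )
    return path


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order and return the manifest."""
    stages = stages or STAGE_ORDER
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    stages = [s for s in STAGE_ORDER if s in stages]
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "rng": "numpy.random.default_rng (PCG64)",
    }
    for stage in stages:
        logger.info("running stage %s", stage)
        outputs = _STAGES[stage](cfg, out)
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "parameters": _stage_params(stage, cfg),
        }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def _stage_params(stage: str, cfg: PipelineConfig) -> dict:
    blocks = {
        "simulate": ["n_genes", "n_reps", "dispersion", "frac_ko_effect", "dlog2_ko",
                     "frac_tm_effect", "dlog2_tm", "frac_blunted", "uorf_load",
                     "n_footprint_transcripts", "seed"],
        "quantify": ["psite_offset", "weighting", "rpk_threshold", "filter_scope"],
        "diffte": ["contrast", "alpha", "lfc_cut", "size_factor_strata"],
        "metagene": ["metagene_anchor", "metagene_normalization", "min_uorf_gap"],
        "uorf-shift": ["contrast", "min_uorf_gap"],
    }
    return {k: getattr(cfg, k) for k in blocks[stage]}


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    effects = make_effect_table(
        gene_ids, rng,
        frac_ko=cfg.frac_ko_effect, dlog2_ko=cfg.dlog2_ko,
        frac_tm=cfg.frac_tm_effect, dlog2_tm=cfg.dlog2_tm,
        frac_blunted=cfg.frac_blunted,
    )
    sim = SimulationConfig(
        n_genes=cfg.n_genes, n_reps=cfg.n_reps, dispersion=cfg.dispersion,
        te_effect_table=effects, uorf_load=cfg.uorf_load,
        psite_offset=cfg.psite_offset, seed=cfg.seed,
    )
    cm, truth = simulate_counts(sim, rng)
    cm.to_tsv(out / "counts.tsv", out / "samples.tsv")
    write_truth(truth, out / "truth.tsv")

    # small transcriptome + footprint files for the positional analyses
    fp_genes = gene_ids[: cfg.n_footprint_transcripts]
    transcripts = make_transcriptome(fp_genes, rng)
    write_fasta(transcripts, out / "transcripts.fa")
    write_bed12(transcripts, out / "transcripts.bed")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    outputs = [out / "counts.tsv", out / "samples.tsv", out / "truth.tsv",
               out / "transcripts.fa", out / "transcripts.bed"]
    fp_samples = cm.samples.index[cm.samples["assay"] == "FP"]
    for sid in fp_samples:
        table = simulate_footprints(sim, transcripts, cm.counts.loc[fp_genes, sid], rng)
        path = aln_dir / f"{sid}.tsv"
        write_alignments(table, path)
        outputs.append(path)
    return outputs


def _load_transcripts(cfg: PipelineConfig, out: Path):
    fasta = Path(cfg.fasta) if cfg.fasta else _require(out / "transcripts.fa", "simulate")
    bed = Path(cfg.annotation) if cfg.annotation else _require(out / "transcripts.bed", "simulate")
    return read_transcripts(fasta, bed)


def _load_psites(cfg: PipelineConfig, out: Path, transcripts) -> dict[str, pd.DataFrame]:
    aln_dir = Path(cfg.alignments_dir) if cfg.alignments_dir else out / "alignments"
    if not aln_dir.exists():
        raise StageDependencyError("missing alignments: run the 'simulate' stage first")
    offsets = default_offsets(offset=cfg.psite_offset)
    tables = {}
    for path in sorted(aln_dir.glob("*.tsv")):
        df, _ = assign_psite(read_alignments(path), offsets, transcripts)
        tables[path.stem] = df
    return tables


def _stage_quantify(cfg: PipelineConfig, out: Path) -> list[Path]:
    transcripts = _load_transcripts(cfg, out)
    tables = _load_psites(cfg, out, transcripts)
    cm_fp, tallies = count_cds(tables, transcripts, weighting=cfg.weighting)
    cm_fp.counts.rename_axis("gene_id").to_csv(out / "fp_cds_counts.tsv", sep="\t")
    qc = {
        sid: qc_region_enrichment(df, transcripts) for sid, df in tables.items()
    }
    for sid, tally in tallies.items():
        qc[sid]["region_weights"] = tally.region_weights
    with open(out / "qc.json", "w") as handle:
        json.dump(qc, handle, indent=2, default=float)
    return [out / "fp_cds_counts.tsv", out / "qc.json"]


def _load_counts(cfg: PipelineConfig, out: Path) -> CountMatrix:
    counts = Path(cfg.counts) if cfg.counts else _require(out / "counts.tsv", "simulate")
    sheet = Path(cfg.sample_sheet) if cfg.sample_sheet else _require(out / "samples.tsv", "simulate")
    return CountMatrix.from_tsv(counts, sheet)


def _stage_diffte(cfg: PipelineConfig, out: Path) -> list[Path]:
    cm = _load_counts(cfg, out)
    transcripts = _load_transcripts(cfg, out)
    cds_len = pd.Series({t.gene_id: t.cds_length for t in transcripts.values()})
    # filter on the genes with known structure; others keep all counts-based genes
    known = cm.gene_ids.intersection(cds_len.index)
    retained = cm.gene_ids.difference(known)
    if len(known):
        kept = rpk_filter(cm.subset_genes(known), cds_len, cfg.rpk_threshold, cfg.filter_scope)
        retained = retained.union(kept)
    results = run_te_test(cm, cfg.contrast, genes=retained, stratify_sf=cfg.size_factor_strata)
    results.to_csv(out / f"te_results_{cfg.contrast}.tsv", sep="\t")
    down = call_significant(results, "down", cfg.lfc_cut, cfg.alpha)
    up = call_significant(results, "up", cfg.lfc_cut, cfg.alpha)
    flagged = pd.concat(
        [results.loc[down].assign(direction="down"), results.loc[up].assign(direction="up")]
    )
    flagged.to_csv(out / f"te_flagged_{cfg.contrast}.tsv", sep="\t")
    outputs = [out / f"te_results_{cfg.contrast}.tsv", out / f"te_flagged_{cfg.contrast}.tsv"]
    if cfg.contrast == "ko":
        res_ctrl = run_te_test(cm, "tm-ctrl", genes=retained, stratify_sf=cfg.size_factor_strata)
        res_ko = run_te_test(cm, "tm-ko", genes=retained, stratify_sf=cfg.size_factor_strata)
        blunted = blunted_induction(res_ctrl, res_ko, cfg.lfc_cut, cfg.alpha)
        pd.DataFrame(index=blunted).to_csv(out / "blunted_induction.tsv", sep="\t")
        outputs.append(out / "blunted_induction.tsv")
    return outputs


def _stage_metagene(cfg: PipelineConfig, out: Path) -> list[Path]:
    transcripts = _load_transcripts(cfg, out)
    tables = _load_psites(cfg, out, transcripts)
    pooled = pd.concat(tables.values(), ignore_index=True)
    uorfs = {tid: discover_uorfs(t, ("AUG",)) for tid, t in transcripts.items()}
    outputs = []
    for anchor in ("morf_start", "morf_stop", "uorf_start", "uorf_stop"):
        profile = metagene_profile(
            pooled, transcripts, anchor=anchor,
            normalization=cfg.metagene_normalization,
            uorfs=uorfs, min_gap=cfg.min_uorf_gap,
        )
        path = out / f"metagene_{anchor}.tsv"
        profile.to_tsv(path)
        outputs.append(path)
    return outputs


def _stage_uorf_shift(cfg: PipelineConfig, out: Path) -> list[Path]:
    transcripts = _load_transcripts(cfg, out)
    table = discover_all_uorfs(transcripts)
    table.to_csv(out / "uorfs.tsv", sep="\t", index=False)
    res_path = _require(out / f"te_results_{cfg.contrast}.tsv", "diffte")
    te_results = pd.read_csv(res_path, sep="\t", index_col=0)
    shifts = te_shift_by_class(te_results, table)
    shifts.to_csv(out / "uorf_class_shift.tsv", sep="\t")
    tables = _load_psites(cfg, out, transcripts)
    pooled = pd.concat(tables.values(), ignore_index=True)
    occupancy = uorf_occupancy(pooled, table, transcripts)
    occupancy.to_csv(out / "uorf_occupancy.tsv", sep="\t", index=False)
    return [out / "uorfs.tsv", out / "uorf_class_shift.tsv", out / "uorf_occupancy.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "diffte": _stage_diffte,
    "metagene": _stage_metagene,
    "uorf-shift": _stage_uorf_shift,
}
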
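"""Footprint quantification: P-site assignment, per-CDS counting, RPK filtering, QC.

Footprint alignments arrive as a BED-like table in transcript coordinates with
columns ``transcript_id, pos5, length, multiplicity``. A multi-mapping read
appears once per equally-good target with its shared ``multiplicity``; under
the default fractional weighting each row contributes 1/multiplicity, so the
read as a whole contributes one unit of evidence.

The P-site of a footprint is inferred as its 5' end plus a length-dependent
offset (+12 nt for all lengths by default, the conventional mammalian choice).
A read is counted for a gene when its P-site falls inside the annotated CDS
half-open interval; P-sites in UTRs are tallied for QC only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

ALIGNMENT_COLUMNS = ["transcript_id", "pos5", "length", "multiplicity"]

#: default P-site offset from the footprint 5' end, applied to every length
DEFAULT_PSITE_OFFSET = 12
DEFAULT_LENGTH_RANGE = (25, 35)


def default_offsets(
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    offset: int = DEFAULT_PSITE_OFFSET,
) -> dict[int, int]:
    """Constant offset map over the configured footprint length support."""
    return {n: offset for n in range(length_range[0], length_range[1] + 1)}


@dataclass
class CountMatrix:
    """Genes × samples count table with per-sample metadata.

    ``counts`` is a DataFrame indexed by gene id with one column per sample;
    fractional values are allowed (multi-mapping weights). ``samples`` is
    indexed by sample id and carries at least ``assay`` ('FP' or 'RNA') plus
    condition labels (here ``genotype`` and ``treatment``) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample sheet rows disagree")
        if "assay" not in self.samples.columns:
            raise ValueError("sample sheet must declare an 'assay' column")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask: pd.Series | np.ndarray | list) -> "CountMatrix":
        samples = self.samples.loc[mask]
        return CountMatrix(self.counts[samples.index], samples)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.samples)

    def assay(self, assay: str) -> "CountMatrix":
        return self.subset_samples(self.samples["assay"] == assay)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", comment="#", index_col=0)
        samples.index = samples.index.astype(str)
        counts.columns = counts.columns.astype(str)
        return cls(counts, samples)


@dataclass
class PsiteTally:
    """Bookkeeping for reads dropped or routed during P-site assignment/counting."""

    n_input: int = 0
    n_assigned: int = 0
    n_length_discarded: int = 0
    n_out_of_bounds: int = 0
    region_weights: dict = field(default_factory=lambda: {"utr5": 0.0, "cds": 0.0, "utr3": 0.0})


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read a footprint BED-like TSV (transcript_id, pos5, length, multiplicity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: alignment table missing columns {missing}")
    return df[ALIGNMENT_COLUMNS]


def write_alignments(df: pd.DataFrame, path: str | Path) -> None:
    df[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def assign_psite(
    alignments: pd.DataFrame,
    offsets: Mapping[int, int] | None = None,
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> tuple[pd.DataFrame, PsiteTally]:
    """Add a ``psite`` column; discard reads whose length has no offset or whose
    P-site falls past the transcript end.

    Returns the retained table and a tally of what was discarded.
    """
    offsets = offsets or default_offsets()
    tally = PsiteTally(n_input=len(alignments))
    df = alignments.copy()
    offset_series = df["length"].map(offsets)
    keep = offset_series.notna()
    tally.n_length_discarded = int((~keep).sum())
    df = df[keep].copy()
    df["psite"] = df["pos5"].to_numpy() + offset_series[keep].astype(int).to_numpy()

    if transcripts is not None:
        lengths = df["transcript_id"].map(lambda t: transcripts[t].length)
        in_bounds = df["psite"] < lengths
        tally.n_out_of_bounds = int((~in_bounds).sum())
        df = df[in_bounds]
    tally.n_assigned = len(df)
    return df.reset_index(drop=True), tally


def _check_known_transcripts(df: pd.DataFrame, transcripts: Mapping[str, TranscriptModel]) -> None:
    unknown = set(df["transcript_id"]) - set(transcripts)
    if unknown:
        shown = ", ".join(sorted(unknown)[:10])
        raise KeyError(f"alignments reference unknown transcript id(s): {shown}")


def _read_weights(df: pd.DataFrame, weighting: str) -> np.ndarray:
    if weighting == "fractional":
        return 1.0 / df["multiplicity"].to_numpy(dtype=float)
    if weighting == "unit":
        return np.ones(len(df))
    raise ValueError(f"unknown weighting {weighting!r} (expected 'fractional' or 'unit')")


def count_cds(
    alignments: pd.DataFrame | Mapping[str, pd.DataFrame],
    transcripts: Mapping[str, TranscriptModel],
    weighting: str = "fractional",
    samples: pd.DataFrame | None = None,
    mode: str = "psite",
) -> tuple[CountMatrix, dict[str, PsiteTally]]:
    """Count footprints per gene whose P-site lies in the CDS.

    ``alignments`` is either one P-site-assigned table (single sample 'FP') or
    a mapping sample id -> table. ``mode='psite'`` counts a read when its
    P-site is inside the CDS; ``mode='overlap'`` counts any read whose span
    overlaps the CDS. Reads landing in UTRs are tallied per region for QC.
    """
    if isinstance(alignments, pd.DataFrame):
        alignments = {"FP": alignments}
    gene_of = {tid: t.gene_id for tid, t in transcripts.items()}
    gene_ids = pd.Index(sorted(set(gene_of.values())), name="gene_id")
    counts = pd.DataFrame(0.0, index=gene_ids, columns=list(alignments))
    tallies: dict[str, PsiteTally] = {}

    for sample, df in alignments.items():
        _check_known_transcripts(df, transcripts)
        tally = PsiteTally(n_input=len(df), n_assigned=len(df))
        weights = _read_weights(df, weighting)
        if mode == "psite":
            if "psite" not in df.columns:
                raise ValueError("alignments lack a 'psite' column; run assign_psite first")
            positions = df["psite"].to_numpy()
            regions = np.array(
                [transcripts[t].region_of(p) for t, p in zip(df["transcript_id"], positions)]
            )
        elif mode == "overlap":
            start = df["pos5"].to_numpy()
            end = start + df["length"].to_numpy()
            regions = np.array(
                [
                    "cds"
                    if (s < transcripts[t].cds[1] and e > transcripts[t].cds[0])
                    else transcripts[t].region_of(s)
                    for t, s, e in zip(df["transcript_id"], start, end)
                ]
            )
        else:
            raise ValueError(f"unknown counting mode {mode!r}")

        for region in ("utr5", "cds", "utr3"):
            tally.region_weights[region] = float(weights[regions == region].sum())
        in_cds = regions == "cds"
        if in_cds.any():
            genes = df.loc[in_cds, "transcript_id"].map(gene_of)
            contrib = pd.Series(weights[in_cds]).groupby(genes.to_numpy()).sum()
            counts.loc[contrib.index, sample] += contrib.to_numpy()
        tallies[sample] = tally

    if samples is None:
        samples = pd.DataFrame(
            {"assay": "FP", "genotype": "", "treatment": "", "replicate": 0},
            index=pd.Index(list(alignments), name="sample"),
        )
    return CountMatrix(counts, samples.loc[list(alignments)]), tallies


def count_transcript(
    alignments: pd.DataFrame | Mapping[str, pd.DataFrame],
    transcripts: Mapping[str, TranscriptModel],
    weighting: str = "fractional",
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """RNA-side counting: every read counts for its transcript's gene,
    regardless of region (RNA fragments are not ribosome-positioned)."""
    if isinstance(alignments, pd.DataFrame):
        alignments = {"RNA": alignments}
    gene_of = {tid: t.gene_id for tid, t in transcripts.items()}
    gene_ids = pd.Index(sorted(set(gene_of.values())), name="gene_id")
    counts = pd.DataFrame(0.0, index=gene_ids, columns=list(alignments))
    for sample, df in alignments.items():
        _check_known_transcripts(df, transcripts)
        weights = _read_weights(df, weighting)
        contrib = pd.Series(weights).groupby(df["transcript_id"].map(gene_of).to_numpy()).sum()
        counts.loc[contrib.index, sample] += contrib.to_numpy()
    if samples is None:
        samples = pd.DataFrame(
            {"assay": "RNA", "genotype": "", "treatment": "", "replicate": 0},
            index=pd.Index(list(alignments), name="sample"),
        )
    return CountMatrix(counts, samples.loc[list(counts.columns)])


def rpk(counts: pd.DataFrame, cds_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of CDS, per gene and sample."""
    lengths = cds_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:10]
        raise ValueError(f"CDS length unknown for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("zero-length CDS encountered in RPK computation")
    return counts.div(lengths / 1000.0, axis=0)


def rpk_filter(
    cm: CountMatrix,
    cds_lengths: pd.Series,
    threshold: float = 2.5,
    scope: str = "all",
) -> pd.Index:
    """Genes whose CDS read density passes the expression filter.

    RPK = counts / (CDS length / 1000). With ``scope='all'`` (default) the
    gene must reach ``RPK >= threshold`` in every library of every assay;
    ``scope='any'`` requires a single passing library. The boundary is
    inclusive.
    """
    values = rpk(cm.counts, cds_lengths)
    passing = values >= threshold
    if scope == "all":
        keep = passing.all(axis=1)
    elif scope == "any":
        keep = passing.any(axis=1)
    else:
        raise ValueError(f"unknown filter scope {scope!r}")
    return cm.gene_ids[keep]


def qc_region_enrichment(
    alignments: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
) -> dict:
    """Region occupancy and triplet periodicity of assigned P-sites.

    Returns fractions over {utr5, cds, utr3} and, for CDS P-sites, fractions
    over reading frames {0, 1, 2} relative to the annotated CDS start. Each
    block sums to 1; an empty input yields zero tallies with ``n=0``.
    """
    if "psite" not in alignments.columns:
        raise ValueError("alignments lack a 'psite' column; run assign_psite first")
    n = len(alignments)
    result = {
        "n": n,
        "region_fractions": {"utr5": 0.0, "cds": 0.0, "utr3": 0.0},
        "frame_fractions": {0: 0.0, 1: 0.0, 2: 0.0},
        "n_cds": 0,
    }
    if n == 0:
        return result
    _check_known_transcripts(alignments, transcripts)
    regions = np.array(
        [
            transcripts[t].region_of(p)
            for t, p in zip(alignments["transcript_id"], alignments["psite"])
        ]
    )
    for region in ("utr5", "cds", "utr3"):
        result["region_fractions"][region] = float((regions == region).sum()) / n
    in_cds = regions == "cds"
    n_cds = int(in_cds.sum())
    result["n_cds"] = n_cds
    if n_cds:
        sub = alignments[in_cds]
        cds_starts = sub["transcript_id"].map(lambda t: transcripts[t].cds[0]).to_numpy()
        frames = (sub["psite"].to_numpy() - cds_starts) % 3
        for f in (0, 1, 2):
            result["frame_fractions"][f] = float((frames == f).sum()) / n_cds
    return result
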
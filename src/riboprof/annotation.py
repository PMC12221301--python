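"""Transcript models and upstream ORF discovery.

All coordinates are transcript-relative, 0-based and half-open; sequences are
stored sense-strand as DNA (T, not U). A transcript is partitioned into a
5'UTR, a CDS (the main ORF, mORF) and a 3'UTR that tile ``[0, len(sequence))``.

uORF discovery is a sequence scan of the 5'UTR: every occurrence of a
configured start codon (AUG or the near-cognate CUG/GUG/UUG) opens a candidate
that is closed by the first in-frame stop codon; candidates without a stop
before the transcript end are discarded. Candidates whose stop lies inside the
mORF are kept but flagged ``overlaps_morf`` so aggregate analyses can exclude
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: DNA codon -> start-codon class label (RNA-style, as used in reports)
START_CODON_CLASSES = {"ATG": "AUG", "CTG": "CUG", "GTG": "GUG", "TTG": "UUG"}
_CLASS_TO_CODON = {v: k for k, v in START_CODON_CLASSES.items()}

NEAR_COGNATE_CLASSES = ("CUG", "GUG", "UUG")
ALL_START_CLASSES = ("AUG",) + NEAR_COGNATE_CLASSES

PURINES = frozenset("AG")


class AnnotationError(ValueError):
    """Raised for unrecoverable annotation/sequence mismatches."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus the 5'UTR / CDS / 3'UTR partition."""

    transcript_id: str
    gene_id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0]

    def validate(self) -> None:
        """Check the interval invariants; raise ``AnnotationError`` if violated."""
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == self.length):
            raise AnnotationError(
                f"{self.transcript_id}: utr5/cds/utr3 do not tile [0, {self.length})"
            )
        if self.cds_length <= 0 or self.cds_length % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {self.cds_length} is not a positive multiple of 3"
            )

    def region_of(self, position: int) -> str:
        """Region label ('utr5' | 'cds' | 'utr3') containing a transcript position."""
        if self.cds[0] <= position < self.cds[1]:
            return "cds"
        if self.utr5[0] <= position < self.utr5[1]:
            return "utr5"
        if self.utr3[0] <= position < self.utr3[1]:
            return "utr3"
        raise IndexError(f"position {position} outside transcript {self.transcript_id}")


@dataclass(frozen=True)
class UORF:
    """An upstream ORF found in a 5'UTR.

    ``end`` is the exclusive position just past the last stop-codon base;
    ``spacing_nt`` = cds.start − end, i.e. the gap between the uORF's stop and
    the main-ORF start (negative when they overlap).
    """

    transcript_id: str
    start: int
    end: int
    start_class: str
    kozak_class: str
    frame_vs_morf: int
    spacing_nt: int
    overlaps_morf: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def read_transcripts(
    fasta_path: str | Path,
    annotation_path: str | Path,
    fmt: str = "auto",
) -> dict[str, TranscriptModel]:
    """Load transcript models from a FASTA plus a BED12 or GTF annotation.

    Both files are in transcript space: the BED/GTF 'chromosome' is the
    transcript id and coordinates are positions along the transcript. Models
    violating the partition/CDS invariants are skipped with a warning; an
    annotated id missing from the FASTA is a hard error.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    if fmt == "auto":
        suffix = annotation_path.suffix.lower()
        fmt = "gtf" if suffix in {".gtf", ".gff"} else "bed12"
    if fmt == "bed12":
        spans = _parse_bed12(annotation_path)
    elif fmt == "gtf":
        spans = _parse_gtf(annotation_path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected 'bed12' or 'gtf')")

    sequences = Fasta(str(fasta_path), as_raw=True, build_index=True)
    models: dict[str, TranscriptModel] = {}
    n_skipped = 0
    for tid, (gene_id, cds_start, cds_end, declared_len) in spans.items():
        if tid not in sequences:
            raise AnnotationError(f"annotation references id {tid!r} absent from FASTA")
        seq = str(sequences[tid])
        if declared_len is not None and declared_len != len(seq):
            logger.warning(
                "%s: annotated length %d != sequence length %d; skipped",
                tid, declared_len, len(seq),
            )
            n_skipped += 1
            continue
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            sequence=seq,
            utr5=(0, cds_start),
            cds=(cds_start, cds_end),
            utr3=(cds_end, len(seq)),
        )
        try:
            model.validate()
        except AnnotationError as exc:
            logger.warning("skipping transcript: %s", exc)
            n_skipped += 1
            continue
        models[tid] = model
    if n_skipped:
        logger.warning("skipped %d transcript(s) with invalid structure", n_skipped)
    return models


def _parse_bed12(path: Path) -> dict[str, tuple[str, int, int, int | None]]:
    """BED12 in transcript space: chrom=transcript id, thickStart/End=CDS."""
    spans = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise AnnotationError(f"{path}: BED12 line with {len(fields)} fields: {line[:60]}")
            tid = fields[0]
            gene_id = fields[3] if len(fields) > 3 and fields[3] != "." else tid
            spans[tid] = (gene_id, int(fields[6]), int(fields[7]), int(fields[2]))
    return spans


def _parse_gtf(path: Path) -> dict[str, tuple[str, int, int, int | None]]:
    """GTF in transcript space: seqname=transcript id, CDS features 1-based inclusive."""
    cds_bounds: dict[str, list[int]] = {}
    genes: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            tid, _, feature, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if feature != "CDS":
                continue
            lo, hi = int(start) - 1, int(end)
            if tid in cds_bounds:
                cds_bounds[tid][0] = min(cds_bounds[tid][0], lo)
                cds_bounds[tid][1] = max(cds_bounds[tid][1], hi)
            else:
                cds_bounds[tid] = [lo, hi]
            attrs = fields[8]
            if "gene_id" in attrs:
                genes[tid] = attrs.split("gene_id")[1].split('"')[1]
    return {
        tid: (genes.get(tid, tid), lo, hi, None) for tid, (lo, hi) in cds_bounds.items()
    }


def discover_uorfs(
    t: TranscriptModel,
    start_classes: Sequence[str] = ALL_START_CLASSES,
) -> list[UORF]:
    """Scan the 5'UTR for uORFs initiating at the requested start-codon classes.

    One uORF per qualifying start position; the first in-frame stop codon
    (searched to the transcript end) closes it. Candidates with no stop are
    discarded. Results are sorted by start position. Nested and overlapping
    candidates are all reported.
    """
    wanted = {_CLASS_TO_CODON[c] for c in start_classes}
    seq = t.sequence
    utr5_end = t.utr5[1]
    found: list[UORF] = []
    for start in range(utr5_end):
        codon = seq[start : start + 3]
        if codon not in wanted:
            continue
        stop_end = _first_inframe_stop(seq, start)
        if stop_end is None:
            continue
        end = stop_end
        overlaps = end > t.cds[0]
        found.append(
            UORF(
                transcript_id=t.transcript_id,
                start=start,
                end=end,
                start_class=START_CODON_CLASSES[codon],
                kozak_class="",  # filled below
                frame_vs_morf=(start - t.cds[0]) % 3,
                spacing_nt=t.cds[0] - end,
                overlaps_morf=overlaps,
            )
        )
    found.sort(key=lambda u: (u.start, u.end))
    return [replace(u, kozak_class=classify_kozak(t, u)) for u in found]


def _first_inframe_stop(seq: str, start: int) -> int | None:
    """Exclusive end position of the first in-frame stop at/after ``start``+3."""
    for pos in range(start + 3, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos + 3
    return None


def classify_kozak(t: TranscriptModel, u: UORF) -> str:
    """Initiation-context strength of a uORF start codon.

    strong: purine at −3 AND G at +4; medium: exactly one of the two;
    weak: neither. A start too close to the 5' end to have a −3 base is
    weak by convention.
    """
    if u.start < 3:
        return "weak"
    seq = t.sequence
    minus3 = seq[u.start - 3] in PURINES
    pos4 = u.start + 3 < len(seq) and seq[u.start + 3] == "G"
    if minus3 and pos4:
        return "strong"
    if minus3 or pos4:
        return "medium"
    return "weak"


def spacing_eligible(u: UORF, min_gap: int = 50) -> bool:
    """True when the uORF stop sits strictly more than ``min_gap`` nt before the mORF."""
    return u.spacing_nt > min_gap


def uorf_table(
    uorfs_by_transcript: dict[str, list[UORF]],
    transcripts: dict[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Flatten discovered uORFs into a table (one row per uORF)."""
    rows = []
    for tid, uorfs in uorfs_by_transcript.items():
        gene = transcripts[tid].gene_id if transcripts else tid
        for u in uorfs:
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene,
                    "start": u.start,
                    "end": u.end,
                    "start_class": u.start_class,
                    "kozak_class": u.kozak_class,
                    "frame_vs_morf": u.frame_vs_morf,
                    "spacing_nt": u.spacing_nt,
                    "overlaps_morf": u.overlaps_morf,
                }
            )
    columns = [
        "transcript_id", "gene_id", "start", "end", "start_class",
        "kozak_class", "frame_vs_morf", "spacing_nt", "overlaps_morf",
    ]
    return pd.DataFrame(rows, columns=columns)


def discover_all_uorfs(
    transcripts: dict[str, TranscriptModel] | Iterable[TranscriptModel],
    start_classes: Sequence[str] = ALL_START_CLASSES,
) -> pd.DataFrame:
    """Run :func:`discover_uorfs` over a transcript set and return the flat table."""
    if isinstance(transcripts, dict):
        models = transcripts
    else:
        models = {t.transcript_id: t for t in transcripts}
    per_tx = {tid: discover_uorfs(t, start_classes) for tid, t in models.items()}
    return uorf_table(per_tx, models)


def write_uorf_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_uorf_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
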
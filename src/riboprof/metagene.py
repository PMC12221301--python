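"""Metagene profiles: footprint density averaged around shared anchor codons.

Each contributing unit (a transcript for mORF anchors; a transcript-uORF pair
for uORF anchors) supplies a windowed P-site count vector around the anchor —
the first base of the start codon or the first base of the stop codon. Units
with no reads in the window are excluded from the average and counted.
Averaging is with equal unit weight, so highly expressed transcripts do not
dominate; offsets that fall outside some transcripts are averaged over the
covering units only (coverage-aware denominator).

For uORF stop-codon profiles only uORFs separated from the main ORF by more
than 50 nt enter, so that mORF-start signal does not bleed into the uORF-stop
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, UORF, spacing_eligible

ANCHORS = ("morf_start", "morf_stop", "uorf_start", "uorf_stop")
DEFAULT_WINDOWS = {
    "morf_start": (-30, 90),
    "morf_stop": (-90, 30),
    "uorf_start": (-30, 90),
    "uorf_stop": (-90, 30),
}


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray
    density: np.ndarray
    coverage: np.ndarray  # units covering each offset
    n_transcripts: int
    n_reads: float
    n_zero_excluded: int
    normalization: str
    unit_matrix: np.ndarray | None = None  # units x offsets, NaN outside coverage

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "density": self.density, "n_covering": self.coverage}
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(
                f"# anchor={self.anchor} normalization={self.normalization} "
                f"n_transcripts={self.n_transcripts} n_reads={self.n_reads:g}\n"
            )
            self.to_frame().to_csv(handle, sep="\t", index=False)


def _anchor_positions(
    anchor: str,
    transcripts: Mapping[str, TranscriptModel],
    uorfs: Mapping[str, list[UORF]] | None,
    min_gap: int,
) -> list[tuple[str, int]]:
    """(transcript_id, anchor position) pairs; anchor = first base of the
    start codon or first base of the stop codon."""
    units: list[tuple[str, int]] = []
    if anchor == "morf_start":
        units = [(tid, t.cds[0]) for tid, t in transcripts.items()]
    elif anchor == "morf_stop":
        units = [(tid, t.cds[1] - 3) for tid, t in transcripts.items()]
    elif anchor in ("uorf_start", "uorf_stop"):
        if uorfs is None:
            raise ValueError(f"anchor {anchor!r} requires a uORF set")
        for tid, ulist in uorfs.items():
            if tid not in transcripts:
                continue
            for u in ulist:
                if u.overlaps_morf or not spacing_eligible(u, min_gap):
                    continue
                pos = u.start if anchor == "uorf_start" else u.end - 3
                units.append((tid, pos))
    else:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    return units


def metagene_profile(
    alignments: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "morf_start",
    window: tuple[int, int] | None = None,
    normalization: str = "per-transcript-mean",
    uorfs: Mapping[str, list[UORF]] | None = None,
    min_gap: int = 50,
    keep_units: bool = False,
) -> MetageneProfile:
    """Average windowed P-site density around an anchor codon.

    ``window`` is (lo, hi) inclusive offsets relative to the anchor; the
    defaults are -30..+90 for start anchors and -90..+30 for stop anchors.
    ``normalization='per-transcript-mean'`` rescales each unit's window to
    mean 1 over its covered offsets before averaging; ``'raw'`` averages the
    counts themselves, so density times coverage sums back to the read total.
    ``keep_units`` retains the per-unit matrix for bootstrap comparison.
    """
    if normalization not in ("per-transcript-mean", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lo, hi = window if window is not None else DEFAULT_WINDOWS[anchor]
    offsets = np.arange(lo, hi + 1)
    width = len(offsets)

    units = _anchor_positions(anchor, transcripts, uorfs, min_gap)
    if "psite" not in alignments.columns:
        raise ValueError("alignments lack a 'psite' column; run assign_psite first")
    psites_by_tx: dict[str, np.ndarray] = {
        tid: grp["psite"].to_numpy() for tid, grp in alignments.groupby("transcript_id")
    }

    rows, n_reads, n_zero = [], 0.0, 0
    for tid, pos in units:
        t = transcripts[tid]
        cover_lo = max(lo, -pos)
        cover_hi = min(hi, t.length - 1 - pos)
        if cover_lo > cover_hi:
            continue
        vec = np.full(width, np.nan)
        span = np.arange(cover_lo, cover_hi + 1)
        counts = np.zeros(len(span))
        ps = psites_by_tx.get(tid)
        if ps is not None:
            rel = ps - pos
            in_win = (rel >= cover_lo) & (rel <= cover_hi)
            if in_win.any():
                binned = np.bincount(rel[in_win] - cover_lo, minlength=len(span))
                counts = binned.astype(float)
        total = counts.sum()
        if total == 0:
            n_zero += 1
            continue
        n_reads += total
        if normalization == "per-transcript-mean":
            counts = counts / counts.mean()
        vec[(span - lo)] = counts
        rows.append(vec)

    if rows:
        mat = np.vstack(rows)
        coverage = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore"):
            density = np.where(coverage > 0, np.nansum(mat, axis=0) / np.maximum(coverage, 1), 0.0)
    else:
        mat = np.empty((0, width))
        coverage = np.zeros(width, dtype=int)
        density = np.zeros(width)

    return MetageneProfile(
        anchor=anchor,
        offsets=offsets,
        density=density,
        coverage=coverage,
        n_transcripts=len(rows),
        n_reads=float(n_reads),
        n_zero_excluded=n_zero,
        normalization=normalization,
        unit_matrix=mat if keep_units else None,
    )


def _bootstrap_means(mat: np.ndarray, rng: np.random.Generator, b: int) -> np.ndarray:
    """Coverage-aware unit-resampled profile means, b x offsets."""
    n = mat.shape[0]
    out = np.empty((b, mat.shape[1]))
    for i in range(b):
        pick = rng.integers(0, n, size=n)
        sub = mat[pick]
        cov = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(cov > 0, np.nansum(sub, axis=0) / np.maximum(cov, 1), np.nan)
    return out


def compare_profiles(
    p1: MetageneProfile,
    p2: MetageneProfile,
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-offset difference p1 - p2 with a bootstrap confidence band.

    Units (transcripts) are resampled independently within each profile B
    times; the band is the (1-level)/2 .. 1-(1-level)/2 percentile envelope of
    the resampled differences. Both profiles must have been built with
    ``keep_units=True`` on the same anchor and window.
    """
    if p1.anchor != p2.anchor or not np.array_equal(p1.offsets, p2.offsets):
        raise ValueError("profiles have different anchors or windows")
    if p1.unit_matrix is None or p2.unit_matrix is None:
        raise ValueError("profiles must be built with keep_units=True for comparison")
    rng = np.random.default_rng(seed)
    diff = p1.density - p2.density
    if len(p1.unit_matrix) == 0 or len(p2.unit_matrix) == 0:
        band = np.full((2, len(diff)), np.nan)
    else:
        boots = _bootstrap_means(p1.unit_matrix, rng, b) - _bootstrap_means(
            p2.unit_matrix, rng, b
        )
        q = (1.0 - level) / 2.0
        band = np.nanpercentile(boots, [100 * q, 100 * (1 - q)], axis=0)
    return pd.DataFrame(
        {
            "offset": p1.offsets,
            "difference": diff,
            "ci_lo": band[0],
            "ci_hi": band[1],
        }
    )
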
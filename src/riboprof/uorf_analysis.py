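"""Aggregate TE-shift analysis over uORF-defined transcript classes.

Even when no single gene reaches significance, a factor acting through uORFs
would shift the translation-efficiency fold-change distribution of
uORF-bearing transcripts as a group. Genes are classified by their discovered
uORFs (AUG-initiated takes priority over near-cognate when both occur;
uORFs overlapping the main ORF are excluded by default), and each class's
log2 TE fold-change distribution is compared against the background with a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import NEAR_COGNATE_CLASSES, TranscriptModel

CLASS_AUG = "AUG_uORF"
CLASS_NEAR_COGNATE = "near_cognate_uORF"
CLASS_NONE = "none"
CLASS_ALL = "all"


def classify_genes(
    genes: pd.Index,
    uorf_table: pd.DataFrame,
    exclude_overlapping: bool = True,
) -> pd.Series:
    """Assign each gene to AUG_uORF, near_cognate_uORF, or none.

    A gene with any AUG-initiated uORF is AUG_uORF regardless of additional
    near-cognate uORFs (priority rule); otherwise any CUG/GUG/UUG uORF makes
    it near_cognate_uORF. uORFs flagged ``overlaps_morf`` are ignored when
    ``exclude_overlapping``.
    """
    table = uorf_table
    if exclude_overlapping and "overlaps_morf" in table.columns:
        table = table[~table["overlaps_morf"].astype(bool)]
    aug_genes = set(table.loc[table["start_class"] == "AUG", "gene_id"])
    nc_genes = set(table.loc[table["start_class"].isin(NEAR_COGNATE_CLASSES), "gene_id"])
    labels = pd.Series(CLASS_NONE, index=genes, dtype=object)
    labels[labels.index.isin(nc_genes)] = CLASS_NEAR_COGNATE
    labels[labels.index.isin(aug_genes)] = CLASS_AUG
    return labels


def te_shift_by_class(
    te_results: pd.DataFrame,
    uorf_table: pd.DataFrame,
    background: str = "all",
    exclude_overlapping: bool = True,
) -> pd.DataFrame:
    """Median TE log2 fold change per uORF class, with shift vs background.

    Returns one row per class label ('all', 'AUG_uORF', 'near_cognate_uORF',
    'none'): class size, median log2FC_TE, difference of medians against the
    background distribution, and a two-sided Mann-Whitney U p-value. The
    background is all retained transcripts by default, or the uORF-free
    class with ``background='uorf_free'``.
    """
    lfc = te_results["log2FC_TE"].dropna()
    labels = classify_genes(lfc.index, uorf_table, exclude_overlapping)
    if background == "all":
        bg = lfc
    elif background == "uorf_free":
        bg = lfc[labels == CLASS_NONE]
    else:
        raise ValueError(f"unknown background {background!r}")
    bg_median = float(bg.median()) if len(bg) else np.nan

    rows = []
    for label in (CLASS_ALL, CLASS_AUG, CLASS_NEAR_COGNATE, CLASS_NONE):
        values = lfc if label == CLASS_ALL else lfc[labels == label]
        n = len(values)
        median = float(values.median()) if n else np.nan
        # the rank test compares the class against its complement: testing a
        # sample against a superset containing itself is non-uniform under the null
        rest = lfc[~lfc.index.isin(values.index)] if label != CLASS_ALL else lfc[:0]
        if label == CLASS_ALL or n == 0 or len(rest) == 0:
            p = np.nan
        else:
            p = float(stats.mannwhitneyu(values, rest, alternative="two-sided").pvalue)
        rows.append(
            {
                "class_label": label,
                "n": n,
                "median_lfc": median,
                "shift_vs_background": median - bg_median if n else np.nan,
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows).set_index("class_label")


def uorf_occupancy(
    alignments: pd.DataFrame,
    uorf_table: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """P-site counts per uORF and the uORF/mORF footprint-density ratio.

    Density is reads per nt of the interval; the ratio is missing when the
    main ORF of the transcript has zero footprint density.
    """
    if "psite" not in alignments.columns:
        raise ValueError("alignments lack a 'psite' column; run assign_psite first")
    psites_by_tx = {
        tid: np.sort(grp["psite"].to_numpy()) for tid, grp in alignments.groupby("transcript_id")
    }
    rows = []
    for _, u in uorf_table.iterrows():
        tid = u["transcript_id"]
        t = transcripts[tid]
        ps = psites_by_tx.get(tid, np.empty(0, dtype=int))
        u_count = int(np.count_nonzero((ps >= u["start"]) & (ps < u["end"])))
        m_count = int(np.count_nonzero((ps >= t.cds[0]) & (ps < t.cds[1])))
        u_density = u_count / (u["end"] - u["start"])
        m_density = m_count / t.cds_length
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": u.get("gene_id", t.gene_id),
                "start": u["start"],
                "end": u["end"],
                "start_class": u["start_class"],
                "uorf_count": u_count,
                "morf_count": m_count,
                "uorf_density": u_density,
                "morf_density": m_density,
                "density_ratio": u_density / m_density if m_density > 0 else np.nan,
            }
        )
    columns = [
        "transcript_id", "gene_id", "start", "end", "start_class",
        "uorf_count", "morf_count", "uorf_density", "morf_density", "density_ratio",
    ]
    return pd.DataFrame(rows, columns=columns)
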
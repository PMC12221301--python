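"""Synthetic ribosome-profiling data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: gamma-Poisson (negative binomial, var = mu + alpha*mu^2) counts per
gene for both assays, footprints with 25-35 nt lengths, triplet periodicity,
start/stop-codon accumulation and optional uORF occupancy, and per-gene
translation-efficiency effects injected for the knockout and the
tunicamycin-treatment contrasts.

Samples span assay in {FP, RNA} x genotype in {control, KO} x treatment in
{DMSO, TM} x replicates. RNA means depend only on gene abundance; FP means are
abundance x baseline TE x the injected condition effects, so a TE effect is by
construction an assay-by-condition interaction and never an RNA change.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a fixed
seed reproduces the data byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, discover_uorfs
from .quantify import CountMatrix, ALIGNMENT_COLUMNS, DEFAULT_PSITE_OFFSET

GENOTYPES = ("control", "KO")
TREATMENTS = ("DMSO", "TM")

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def _default_length_dist() -> dict[int, float]:
    """Footprint length distribution over 25-35 nt, peaked at 28-29 nt as in
    typical mammalian monosome profiling."""
    weights = {25: 2, 26: 4, 27: 8, 28: 16, 29: 14, 30: 10, 31: 6, 32: 3, 33: 2, 34: 1, 35: 1}
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the analysed experiment: triplicate libraries per
    (assay, condition), negative-binomial counts with dispersion 0.1, gene
    abundances log-normal around 500 expected counts, footprints of 25-35 nt
    with ~70% in-frame P-sites, and per-sample depth factors log-uniform in
    [0.5, 2] so normalization is exercised.
    """

    n_genes: int = 2000
    n_reps: int = 3
    mu_meanlog: float = math.log(500.0)
    mu_sdlog: float = 1.0
    dispersion: float = 0.1
    te_sdlog: float = 0.5
    te_effect_table: pd.DataFrame | None = None
    frame_weights: tuple[float, float, float] = (0.7, 0.15, 0.15)
    length_dist: dict[int, float] = field(default_factory=_default_length_dist)
    start_peak: float = 3.0
    stop_peak: float = 3.0
    uorf_load: float = 0.1
    depth_range: tuple[float, float] = (0.5, 2.0)
    psite_offset: int = DEFAULT_PSITE_OFFSET
    include_tm_arm: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2: TE testing needs replication")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise ValueError("frame_weights must sum to 1")
        if not all(25 <= n <= 35 for n in self.length_dist):
            raise ValueError("length_dist support must lie within [25, 35] nt")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length_dist must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.uorf_load <= 1.0:
            raise ValueError("uorf_load must lie in [0, 1]")


def make_effect_table(
    gene_ids: list[str],
    rng: np.random.Generator,
    frac_ko: float = 0.0,
    dlog2_ko: float = -1.0,
    frac_tm: float = 0.0,
    dlog2_tm: float = 1.5,
    frac_blunted: float = 0.0,
) -> pd.DataFrame:
    """Draw a per-gene TE-effect table.

    ``frac_ko`` of genes receive a knockout TE shift of ``dlog2_ko`` (sign
    alternating so both directions occur); ``frac_tm`` receive a tunicamycin
    induction of ``dlog2_tm`` in control cells, of which ``frac_blunted`` lose
    the induction in the KO background (dlog2te_tm_ko = 0).
    """
    n = len(gene_ids)
    table = pd.DataFrame(
        {"dlog2te_ko": 0.0, "dlog2te_tm": 0.0, "dlog2te_tm_ko": 0.0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    n_ko = int(round(frac_ko * n))
    if n_ko:
        picks = rng.choice(n, size=n_ko, replace=False)
        signs = np.where(np.arange(n_ko) % 2 == 0, 1.0, -1.0)
        table.iloc[picks, 0] = dlog2_ko * signs
    n_tm = int(round(frac_tm * n))
    if n_tm:
        pool = np.flatnonzero(table["dlog2te_ko"] == 0.0)
        picks = rng.choice(pool, size=min(n_tm, len(pool)), replace=False)
        table.iloc[picks, 1] = dlog2_tm
        n_blunt = int(round(frac_blunted * len(picks)))
        table.iloc[picks, 2] = dlog2_tm
        if n_blunt:
            table.iloc[picks[:n_blunt], 2] = 0.0
    return table


def _sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    treatments = TREATMENTS if cfg.include_tm_arm else TREATMENTS[:1]
    for assay in ("FP", "RNA"):
        for genotype in GENOTYPES:
            for treatment in treatments:
                for rep in range(1, cfg.n_reps + 1):
                    sid = f"{assay}_{genotype}_{treatment}_r{rep}"
                    rows.append(
                        {"sample": sid, "assay": assay, "genotype": genotype,
                         "treatment": treatment, "replicate": rep}
                    )
    return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha*mu^2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    return rng.poisson(rng.gamma(shape, mean * alpha))


def simulate_counts(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the RNA and footprint count matrix plus its ground-truth table.

    RNA counts ~ NB(mu_g * s_j, alpha); FP counts ~ NB(mu_g * TE_g * effect *
    s_j, alpha) where the effect is 2**dlog2te for the sample's condition.
    Returns the :class:`CountMatrix` and a truth table with one row per gene
    (baseline abundance, baseline TE, injected effects, per-sample depths are
    attached as ``truth.attrs['size_factors']``).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mu = rng.lognormal(cfg.mu_meanlog, cfg.mu_sdlog, size=cfg.n_genes)
    te = rng.lognormal(0.0, cfg.te_sdlog, size=cfg.n_genes)

    effects = cfg.te_effect_table
    if effects is None:
        effects = make_effect_table(gene_ids, rng)
    effects = effects.reindex(gene_ids).fillna(0.0)

    samples = _sample_sheet(cfg)
    depths = pd.Series(
        rng.uniform(np.log(cfg.depth_range[0]), np.log(cfg.depth_range[1]), size=len(samples)),
        index=samples.index,
    ).pipe(np.exp)

    counts = np.empty((cfg.n_genes, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        mean = mu * depths[sid]
        if row["assay"] == "FP":
            lfc = np.zeros(cfg.n_genes)
            if row["genotype"] == "KO":
                lfc = lfc + effects["dlog2te_ko"].to_numpy()
            if row["treatment"] == "TM":
                col = "dlog2te_tm" if row["genotype"] == "control" else "dlog2te_tm_ko"
                lfc = lfc + effects[col].to_numpy()
            mean = mean * te * np.exp2(lfc)
        counts[:, j] = _nb_draw(rng, mean, cfg.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index),
        samples,
    )
    truth = pd.DataFrame(
        {
            "baseline_abundance": mu,
            "baseline_te": te,
            "dlog2te_ko": effects["dlog2te_ko"].to_numpy(),
            "dlog2te_tm": effects["dlog2te_tm"].to_numpy(),
            "dlog2te_tm_ko": effects["dlog2te_tm_ko"].to_numpy(),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth.attrs["size_factors"] = depths
    return cm, truth


def make_transcriptome(
    gene_ids: list[str],
    rng: np.random.Generator,
    utr5_range: tuple[int, int] = (60, 240),
    n_codons_range: tuple[int, int] = (120, 500),
    utr3_range: tuple[int, int] = (60, 200),
) -> dict[str, TranscriptModel]:
    """Random toy transcriptome, one transcript per gene.

    The CDS starts with ATG, ends with a stop codon, and has no internal
    in-frame stops; UTR sequence is uniform random, so uORFs arise by chance
    at natural codon frequencies and are found by the discovery scan.
    """
    models = {}
    bases = np.array(list("ACGT"))
    for gid in gene_ids:
        n5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        n3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        utr5 = "".join(rng.choice(bases, size=n5))
        utr3 = "".join(rng.choice(bases, size=n3))
        body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        cds = "ATG" + body + stop
        seq = utr5 + cds + utr3
        tid = f"{gid}.t1"
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            sequence=seq,
            utr5=(0, n5),
            cds=(n5, n5 + len(cds)),
            utr3=(n5 + len(cds), len(seq)),
        )
    return models


def simulate_footprints(
    cfg: SimulationConfig,
    transcripts: Mapping[str, TranscriptModel],
    fp_counts: pd.Series,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place footprints on transcripts for one footprint library.

    ``fp_counts`` maps gene id -> number of reads; each gene's single
    transcript receives exactly that many reads (multiplicity 1), so CDS
    counting round-trips the totals when ``uorf_load`` is 0. P-site codons are
    drawn uniformly over the CDS with ``start_peak``/``stop_peak`` multipliers
    on the first and last codon; the within-codon offset follows
    ``frame_weights``; for uORF-bearing transcripts a ``uorf_load`` fraction of
    reads is placed on a random AUG uORF instead. The 5' end is P-site minus
    the configured offset; transcripts too short to place a footprint are
    skipped with a warning.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    by_gene: dict[str, TranscriptModel] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, t)

    lengths = np.array(sorted(cfg.length_dist))
    length_p = np.array([cfg.length_dist[n] for n in lengths])
    frame_p = np.asarray(cfg.frame_weights)
    offset = cfg.psite_offset
    max_len = int(lengths.max())

    records: list[pd.DataFrame] = []
    skipped = []
    for gid, n_reads in fp_counts.items():
        n_reads = int(n_reads)
        if n_reads <= 0 or gid not in by_gene:
            continue
        t = by_gene[gid]
        cds_start, cds_end = t.cds
        n_codons = (cds_end - cds_start) // 3
        if cds_start < offset or t.length - cds_end < max_len - offset or n_codons < 1:
            skipped.append(gid)
            continue

        on_uorf = np.zeros(n_reads, dtype=bool)
        uorf_starts = None
        if cfg.uorf_load > 0:
            eligible = [
                u for u in discover_uorfs(t, ("AUG",))
                if not u.overlaps_morf and u.start >= offset and u.length >= 6
            ]
            if eligible:
                on_uorf = rng.random(n_reads) < cfg.uorf_load
                uorf_starts = eligible

        codon_w = np.ones(n_codons)
        codon_w[0] = cfg.start_peak
        codon_w[-1] = cfg.stop_peak
        codon_w /= codon_w.sum()

        psite = np.empty(n_reads, dtype=int)
        n_cds = int((~on_uorf).sum())
        codons = rng.choice(n_codons, size=n_cds, p=codon_w)
        frames = rng.choice(3, size=n_cds, p=frame_p)
        psite[~on_uorf] = cds_start + 3 * codons + frames
        if on_uorf.any():
            for i in np.flatnonzero(on_uorf):
                u = uorf_starts[int(rng.integers(len(uorf_starts)))]
                u_codons = u.length // 3
                c = int(rng.integers(u_codons))
                psite[i] = u.start + 3 * c + int(rng.choice(3, p=frame_p))

        read_len = rng.choice(lengths, size=n_reads, p=length_p)
        pos5 = psite - offset
        # clamp rare edge reads so every record satisfies pos5+length <= L
        over = pos5 + read_len > t.length
        read_len[over] = t.length - pos5[over]
        records.append(
            pd.DataFrame(
                {
                    "transcript_id": t.transcript_id,
                    "pos5": pos5,
                    "length": read_len,
                    "multiplicity": 1,
                }
            )
        )
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "%d transcript(s) too short for footprint placement; skipped", len(skipped)
        )
    if not records:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    return pd.concat(records, ignore_index=True)[ALIGNMENT_COLUMNS]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def write_fasta(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        for tid, t in transcripts.items():
            handle.write(f">{tid}\n")
            for i in range(0, t.length, 70):
                handle.write(t.sequence[i : i + 70] + "\n")


def write_bed12(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    """Transcript-space BED12: chrom = transcript id, thickStart/End = CDS."""
    with open(path, "w") as handle:
        for tid, t in transcripts.items():
            fields = [
                tid, 0, t.length, t.gene_id, 0, "+", t.cds[0], t.cds[1],
                "0,0,0", 1, t.length, 0,
            ]
            handle.write("\t".join(str(f) for f in fields) + "\n")


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["rng"] = "numpy.random.default_rng (PCG64)"
    d.pop("te_effect_table", None)
    return d
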
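import numpy as np
import pandas as pd
import pytest

from riboprof.annotation import TranscriptModel
from riboprof.quantify import CountMatrix


def make_transcript(
    utr5: str,
    n_cds_codons: int = 40,
    utr3: str | None = None,
    transcript_id: str = "tx1",
    gene_id: str | None = None,
) -> TranscriptModel:
    """Build a valid transcript around a given 5'UTR: ATG + (GCC)*k + TAA CDS."""
    cds = "ATG" + "GCC" * (n_cds_codons - 2) + "TAA"
    utr3 = utr3 if utr3 is not None else "C" * 60
    seq = utr5 + cds + utr3
    n5 = len(utr5)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id.split(".")[0],
        sequence=seq,
        utr5=(0, n5),
        cds=(n5, n5 + len(cds)),
        utr3=(n5 + len(cds), len(seq)),
    )


@pytest.fixture
def toy_transcripts() -> dict[str, TranscriptModel]:
    t1 = make_transcript("A" * 80, n_cds_codons=50, transcript_id="g1.t1", gene_id="g1")
    t2 = make_transcript("G" * 100, n_cds_codons=80, transcript_id="g2.t1", gene_id="g2")
    return {t.transcript_id: t for t in (t1, t2)}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def factorial_count_matrix(group_means: dict, n_genes: int = 1, n_reps: int = 2,
                           n_background: int = 0, background_mean: float = 100.0) -> CountMatrix:
    """Noise-free 2x2 factorial counts; keys of group_means are (assay, genotype).

    ``n_background`` genes receive ``background_mean`` in every sample so that
    median-of-ratios size factors are 1 even when every foreground gene carries
    the effect.
    """
    rows = []
    cols = []
    samples = []
    for assay in ("RNA", "FP"):
        for genotype in ("control", "KO"):
            for rep in range(1, n_reps + 1):
                sid = f"{assay}_{genotype}_r{rep}"
                cols.append(sid)
                samples.append({"sample": sid, "assay": assay, "genotype": genotype,
                                "treatment": "DMSO", "replicate": rep})
    genes = [f"fg{i}" for i in range(n_genes)] + [f"bg{i}" for i in range(n_background)]
    data = {}
    for sid, meta in zip(cols, samples):
        key = (meta["assay"], meta["genotype"])
        col = [group_means[key]] * n_genes + [background_mean] * n_background
        data[sid] = col
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), dtype=float)
    sheet = pd.DataFrame(samples).set_index("sample")
    return CountMatrix(counts, sheet)
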
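"""Transcript reading and uORF discovery/classification."""

import numpy as np
import pytest

from riboprof.annotation import (
    ALL_START_CLASSES,
    STOP_CODONS,
    START_CODON_CLASSES,
    AnnotationError,
    TranscriptModel,
    classify_kozak,
    discover_uorfs,
    read_transcripts,
    spacing_eligible,
)
from riboprof.synthetic import write_bed12, write_fasta

from conftest import make_transcript


def brute_force_uorfs(seq: str, utr5_end: int, cds_start: int, classes) -> list[tuple]:
    """Independent oracle: enumerate every (start, end) pair in every frame and
    keep ends whose codon is a stop with no earlier in-frame stop."""
    codon_of = {v: k for k, v in START_CODON_CLASSES.items()}
    wanted = {codon_of[c] for c in classes}
    out = []
    for start in range(utr5_end):
        if seq[start : start + 3] not in wanted:
            continue
        for end in range(start + 6, len(seq) + 1, 3):
            if seq[end - 3 : end] in STOP_CODONS and all(
                seq[q : q + 3] not in STOP_CODONS for q in range(start + 3, end - 3, 3)
            ):
                out.append((start, end, START_CODON_CLASSES[seq[start : start + 3]]))
                break
    return sorted(out)


class TestReadTranscripts:
    def test_round_trip_fixture(self, toy_transcripts, tmp_path):
        fasta, bed = tmp_path / "t.fa", tmp_path / "t.bed"
        write_fasta(toy_transcripts, fasta)
        write_bed12(toy_transcripts, bed)
        models = read_transcripts(fasta, bed)
        assert set(models) == set(toy_transcripts)
        for tid, t in toy_transcripts.items():
            got = models[tid]
            assert (got.utr5, got.cds, got.utr3) == (t.utr5, t.cds, t.utr3)
            assert got.sequence == t.sequence
            assert got.gene_id == t.gene_id

    def test_missing_sequence_is_hard_error(self, toy_transcripts, tmp_path):
        fasta, bed = tmp_path / "t.fa", tmp_path / "t.bed"
        write_fasta({"g1.t1": toy_transcripts["g1.t1"]}, fasta)
        write_bed12(toy_transcripts, bed)
        with pytest.raises(AnnotationError, match="g2.t1"):
            read_transcripts(fasta, bed)

    def test_cds_not_multiple_of_three_is_skipped(self, toy_transcripts, tmp_path, caplog):
        bad = toy_transcripts["g1.t1"]
        models = dict(toy_transcripts)
        models["bad.t1"] = TranscriptModel(
            "bad.t1", "bad", bad.sequence, (0, 80), (80, 180), (180, bad.length)
        )
        fasta, bed = tmp_path / "t.fa", tmp_path / "t.bed"
        write_fasta(models, fasta)
        write_bed12(models, bed)
        with caplog.at_level("WARNING"):
            got = read_transcripts(fasta, bed)
        assert set(got) == set(toy_transcripts)
        assert any("skipped 1" in rec.message for rec in caplog.records)

    def test_gtf_dialect(self, toy_transcripts, tmp_path):
        fasta, gtf = tmp_path / "t.fa", tmp_path / "t.gtf"
        write_fasta(toy_transcripts, fasta)
        with open(gtf, "w") as fh:
            for tid, t in toy_transcripts.items():
                fh.write(
                    f"{tid}\ttoy\tCDS\t{t.cds[0] + 1}\t{t.cds[1]}\t.\t+\t0\t"
                    f'gene_id "{t.gene_id}";\n'
                )
        models = read_transcripts(fasta, gtf)
        for tid, t in toy_transcripts.items():
            assert models[tid].cds == t.cds
            assert models[tid].gene_id == t.gene_id


class TestDiscoverUorfs:
    def test_no_start_codon(self):
        t = make_transcript("CCCCCCCCC")
        assert discover_uorfs(t) == []

    def test_hand_scanned_aug_uorf(self):
        # ATG at 2, in-frame TAA at 8 -> [2, 11)
        t = make_transcript("AAATGGCCTAACC")
        (u,) = discover_uorfs(t, ("AUG",))
        assert (u.start, u.end, u.start_class) == (2, 11, "AUG")
        assert u.spacing_nt == t.cds[0] - 11
        assert not u.overlaps_morf

    def test_near_cognate_needs_opt_in(self):
        t = make_transcript("AACTGGCCTAACC")
        assert discover_uorfs(t, ("AUG",)) == []
        (u,) = discover_uorfs(t, ("AUG", "CUG"))
        assert (u.start, u.end, u.start_class) == (2, 11, "CUG")

    def test_candidate_without_stop_is_discarded(self):
        # ATG in utr5 whose frame hits no stop anywhere (CDS body is GCC repeats,
        # and the frame runs past the annotated stop into a C-run)
        t = make_transcript("ATGAA", n_cds_codons=5, utr3="CCCCCC")
        starts = {u.start for u in discover_uorfs(t, ("AUG",))}
        assert 0 not in starts

    def test_overlapping_morf_flag(self):
        # uORF starting in utr5 with first in-frame stop inside the CDS
        t = make_transcript("CCATGCC")  # ATG at 2, frame 2 vs CDS; stop lies downstream
        uorfs = discover_uorfs(t, ("AUG",))
        for u in uorfs:
            assert u.overlaps_morf == (u.end > t.cds[0])
            if not u.overlaps_morf:
                assert u.end <= t.cds[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        for _ in range(250):
            n5 = int(rng.integers(0, 301))
            utr5 = "".join(rng.choice(bases, size=n5))
            t = make_transcript(utr5, n_cds_codons=20)
            got = [(u.start, u.end, u.start_class) for u in discover_uorfs(t)]
            expected = brute_force_uorfs(t.sequence, t.utr5[1], t.cds[0], ALL_START_CLASSES)
            assert got == expected

    def test_reported_uorfs_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            utr5 = "".join(rng.choice(bases, size=int(rng.integers(20, 200))))
            t = make_transcript(utr5)
            for u in discover_uorfs(t):
                assert u.start < u.end and (u.end - u.start) % 3 == 0
                assert u.start < t.utr5[1]
                codon = t.sequence[u.start : u.start + 3]
                assert START_CODON_CLASSES[codon] == u.start_class
                assert t.sequence[u.end - 3 : u.end] in STOP_CODONS
                # first in-frame stop: none earlier
                for q in range(u.start + 3, u.end - 3, 3):
                    assert t.sequence[q : q + 3] not in STOP_CODONS
                assert u.frame_vs_morf == (u.start - t.cds[0]) % 3


class TestKozak:
    def test_strong_context(self):
        # GCCACC ATG G...: A at -3, G at +4
        t = make_transcript("GCCACCATGGGATAGTTTTTT")
        u = next(u for u in discover_uorfs(t, ("AUG",)) if u.start == 6)
        assert classify_kozak(t, u) == "strong"

    def test_weak_context(self):
        # T at -3, C at +4
        t = make_transcript("TTTTTTATGCTATAAGGGGGG")
        u = next(u for u in discover_uorfs(t, ("AUG",)) if u.start == 6)
        assert classify_kozak(t, u) == "weak"

    def test_medium_context(self):
        # A at -3, C at +4: exactly one feature
        t = make_transcript("GCCACCATGCTATAAGGGGGG")
        u = next(u for u in discover_uorfs(t, ("AUG",)) if u.start == 6)
        assert classify_kozak(t, u) == "medium"

    def test_start_near_cap_is_weak_by_convention(self):
        t = make_transcript("CATGGGATAGTTT")  # ATG at 1, no -3 base
        u = next(u for u in discover_uorfs(t, ("AUG",)) if u.start == 1)
        assert classify_kozak(t, u) == "weak"


class TestSpacing:
    def _uorf(self, spacing):
        t = make_transcript("AAATGGCCTAACC" + "C" * 60)
        (u,) = discover_uorfs(t, ("AUG",))
        object.__setattr__(u, "spacing_nt", spacing)
        return u

    def test_strictly_more_than_gap(self):
        assert spacing_eligible(self._uorf(60)) is True
        assert spacing_eligible(self._uorf(51)) is True
        assert spacing_eligible(self._uorf(50)) is False

    def test_overlap_is_ineligible(self):
        assert spacing_eligible(self._uorf(-5)) is False

    def test_monotone_in_min_gap(self):
        u = self._uorf(60)
        flags = [spacing_eligible(u, g) for g in range(0, 120, 10)]
        assert all(a >= b for a, b in zip(flags, flags[1:]))
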
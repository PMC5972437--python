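"""Alignment against the DP oracle, CIGAR classification, and summaries."""

import numpy as np
import pytest

from crisprbench import AmpliconExperiment, align_read, classify_reads, summarize
from crisprbench.classify import (
    AlignScores,
    ReadOutcome,
    _make_aligner,
    classify_hdr,
    classify_nhej,
    classify_read,
)
from _oracles import gotoh_score
from conftest import random_dna


@pytest.fixture(scope="module")
def reference():
    return random_dna(np.random.default_rng(3), 200)


class TestAlignRead:
    def test_identical_read_full_match(self, reference):
        aln = align_read(reference, reference)
        assert aln.cigar == f"{len(reference)}M"
        assert aln.identity == 1.0
        assert aln.events == []

    def test_three_nt_deletion_in_cigar(self, reference):
        read = reference[:80] + reference[83:]
        aln = align_read(read, reference)
        assert "3D" in aln.cigar
        assert sum(n for op, _, n in aln.events if op == "D") == 3

    def test_insertion_in_cigar(self, reference):
        read = reference[:100] + "TTAACC" + reference[100:]
        aln = align_read(read, reference)
        assert ("I", 100, 6) in aln.events or any(op == "I" and n == 6 for op, _, n in aln.events)

    def test_short_read_unaligned(self, reference):
        assert align_read("ACGTACGT", reference) is None

    def test_garbage_read_unaligned(self, reference):
        assert align_read("AC" * 50, reference, min_identity=0.75) is None

    def test_leftmost_gap_placement(self):
        # deletion inside a homopolymer must sit at the run's left edge
        ref = "ACGT" + "AAAAAA" + "CGCGCGCGCGCGCGCGCGCGCGCGCGCGCG"
        read = "ACGT" + "AAAA" + "CGCGCGCGCGCGCGCGCGCGCGCGCGCGCG"
        aln = align_read(read, ref, min_read_len=10)
        assert aln.events == [("D", 4, 2)]

    def test_score_equals_dp_oracle_on_random_pairs(self, rng):
        """Aligner score == textbook Gotoh score for random mutated pairs."""
        scores = AlignScores()
        aligner = _make_aligner(scores)
        for _ in range(60):
            m = int(rng.integers(30, 61))
            ref = random_dna(rng, m)
            read = list(ref)
            for _ in range(int(rng.integers(0, 4))):
                kind = rng.choice(["sub", "ins", "del"])
                pos = int(rng.integers(1, len(read) - 1))
                if kind == "sub":
                    read[pos] = "ACGT"[int(rng.integers(4))]
                elif kind == "ins":
                    read.insert(pos, "ACGT"[int(rng.integers(4))])
                elif len(read) > 31:
                    del read[pos]
            read = "".join(read)
            assert aligner.score(ref, read) == pytest.approx(gotoh_score(ref, read))


class TestClassifyNhej:
    def _exp(self, reference):
        return AmpliconExperiment(reference, spacer_start=80, spacer_end=100)

    def test_perfect_read_is_match(self, reference):
        exp = self._exp(reference)
        out = classify_read("r", reference, exp)
        assert out.nhej_label == "Match"

    def test_substitutions_only_is_match(self, reference):
        exp = self._exp(reference)
        read = list(reference)
        read[90] = "A" if reference[90] != "A" else "C"
        out = classify_read("r", "".join(read), exp)
        assert out.nhej_label == "Match"

    def test_insertion_in_spacer(self, reference):
        exp = self._exp(reference)
        read = reference[:90] + "T" + reference[90:]
        out = classify_read("r", read, exp)
        assert out.nhej_label == "Insertion"

    def test_deletion_outside_window_is_match(self, reference):
        # spacer [80,100), window [40,140): a deletion at 10 is 50 bp clear
        exp = self._exp(reference)
        read = reference[:10] + reference[15:]
        out = classify_read("r", read, exp)
        assert out.nhej_label == "Match"

    def test_both_events_longest_wins_ties_deletion(self, reference):
        exp = self._exp(reference)
        aln = align_read(reference, reference)
        aln.events = [("I", 85, 2), ("D", 92, 4)]
        assert classify_nhej(aln, exp) == "Deletion"
        aln.events = [("I", 85, 4), ("D", 92, 2)]
        assert classify_nhej(aln, exp) == "Insertion"
        aln.events = [("I", 85, 3), ("D", 92, 3)]
        assert classify_nhej(aln, exp) == "Deletion"

    def test_window_monotonicity(self, reference, rng):
        """Enlarging the window never decreases the indel call count."""
        reads = []
        for _ in range(40):
            pos = int(rng.integers(20, 180))
            ln = int(rng.integers(1, 6))
            reads.append((f"r{pos}", reference[:pos] + reference[pos + ln :]))
        prev = -1
        for flank in (10, 25, 40, 60, 90):
            exp = AmpliconExperiment(reference, 80, 100, flank=flank)
            _, summary = classify_reads(reads, exp, min_read_len=20)
            n_indel = summary.n_insertion + summary.n_deletion
            assert n_indel >= prev
            prev = n_indel


class TestClassifyHdr:
    @pytest.fixture()
    def hdr_exp(self, reference):
        return AmpliconExperiment(
            reference, 80, 100,
            insert_seq="TCTAGA", insertion_point=95, recognition_seq="TCTAGA",
        )

    def test_modified_reference_read_is_correct(self, hdr_exp):
        read = hdr_exp.modified_reference_seq
        out = classify_read("r", read, hdr_exp)
        assert (out.nhej_label, out.hdr_label) == ("Match", "Correct")

    def test_read_without_site_is_no(self, hdr_exp, reference):
        out = classify_read("r", reference, hdr_exp)
        assert out.hdr_label == "No"

    def test_site_plus_deletion_is_wrong(self, hdr_exp):
        mod = hdr_exp.modified_reference_seq
        read = mod[:85] + mod[87:]  # 2-nt deletion in window, site intact
        out = classify_read("r", read, hdr_exp)
        assert (out.nhej_label, out.hdr_label) == ("Deletion", "Wrong")

    def test_hdr_without_modified_reference_is_config_error(self, reference):
        exp = AmpliconExperiment(reference, 80, 100)
        aln = align_read(reference, reference)
        with pytest.raises(ValueError):
            classify_hdr(reference, aln, exp, "Match")


class TestSummarize:
    @staticmethod
    def _o(nhej, hdr="NA"):
        return ReadOutcome("r", nhej, hdr, 1.0)

    def test_indel_percentage(self):
        outcomes = (
            [self._o("Insertion")] * 20 + [self._o("Deletion")] * 10 + [self._o("Match")] * 70
        )
        s = summarize(outcomes)
        assert s.indel_pct == pytest.approx(30.0)
        assert s.n_insertion + s.n_deletion + s.n_match == s.n_aligned == 100

    def test_all_match_zero_indel(self):
        s = summarize([self._o("Match")] * 10)
        assert s.indel_pct == 0.0

    def test_unaligned_excluded_from_denominator(self):
        outcomes = [self._o("Match")] * 8 + [self._o("Unaligned")] * 2 + [self._o("Deletion")] * 2
        s = summarize(outcomes)
        assert s.n_total == 12 and s.n_aligned == 10
        assert s.indel_pct == pytest.approx(20.0)

    def test_zero_aligned_warns_with_nan(self):
        with pytest.warns(UserWarning):
            s = summarize([self._o("Unaligned")] * 3)
        assert np.isnan(s.indel_pct)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
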
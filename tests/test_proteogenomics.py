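"""Six-frame translation, Lys-C digestion, peptide matching, protein
grouping and RNA-seq validation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from expressome.proteogenomics import (SixFrameORF, call_novel_orfs,
                                       digest_lysC, group_proteins,
                                       match_peptides, six_frame_translate,
                                       validate_with_coverage)
from expressome.tracks import CoverageTrack


class TestSixFrame:
    def test_hand_translated_orf(self):
        orfs = six_frame_translate("ATGAAAGCTGGTTGGACCCTGAAATAA", min_aa=7)
        plus1 = [o for o in orfs if o.frame == 1]
        assert len(plus1) == 1
        assert plus1[0].aa == "MKAGWTLK"
        assert plus1[0].start == 0 and plus1[0].end == 24

    def test_minimum_length_boundary(self):
        # 6 aa stretch between stops is excluded, 7 aa is included
        six = "TAA" + "GCT" * 6 + "TAA"
        seven = "TAA" + "GCT" * 7 + "TAA"
        assert all(o.frame != 1 for o in six_frame_translate(six, min_aa=7))
        plus1 = [o for o in six_frame_translate(seven, min_aa=7)
                 if o.frame == 1]
        assert len(plus1) == 1 and plus1[0].aa == "A" * 7

    def test_strand_symmetry(self):
        seq = "TAAATGAAAGCTGGTTGGACCCTGAAATAG"
        rc = str(Seq(seq).reverse_complement())
        fwd = {o.aa for o in six_frame_translate(seq, min_aa=7)}
        rev = {o.aa for o in six_frame_translate(rc, min_aa=7)}
        assert fwd == rev

    def test_coordinates_round_trip(self, small_genome):
        orfs = six_frame_translate(small_genome.sequence, min_aa=7)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(orfs), size=50, replace=False):
            orf = orfs[i]
            sub = small_genome.sequence[orf.start:orf.end]
            if orf.strand == "-":
                sub = str(Seq(sub).reverse_complement())
            assert str(Seq(sub).translate()) == orf.aa
            assert orf.end - orf.start == 3 * len(orf.aa)

    def test_empty_sequence(self):
        assert six_frame_translate("", min_aa=7) == []


class TestDigest:
    def test_hand_enumerated_lattice(self):
        protein = "AAAAAKGGGGGGKCCC"
        zero = set(digest_lysC(protein, max_missed=0, min_len=1))
        assert zero == {"AAAAAK", "GGGGGGK", "CCC"}
        zero6 = set(digest_lysC(protein, max_missed=0, min_len=6))
        assert zero6 == {"AAAAAK", "GGGGGGK"}
        one = set(digest_lysC(protein, max_missed=1, min_len=6))
        assert one == zero6 | {"AAAAAKGGGGGGK", "GGGGGGKCCC"}
        two = set(digest_lysC(protein, max_missed=2, min_len=6))
        assert two == one | {"AAAAAKGGGGGGKCCC"}

    def test_lysine_free_sequence(self):
        assert digest_lysC("ACDEFGH", max_missed=2, min_len=6) == ["ACDEFGH"]

    def test_all_lysine_sequence_empty(self):
        assert digest_lysC("KKKKKK", max_missed=2, min_len=6) == []

    def test_cleaves_before_proline(self):
        pieces = digest_lysC("AAAAAKPGGGGG", max_missed=0, min_len=1)
        assert pieces == ["AAAAAK", "PGGGGG"]

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACDKGST", min_size=1, max_size=40))
    def test_lattice_closure(self, protein):
        """Every contiguous piece-run with <= max_missed internal K is
        emitted exactly once."""
        peptides = digest_lysC(protein, max_missed=2, min_len=1)
        # reconstruct expected lattice from the 0-missed pieces
        pieces = digest_lysC(protein, max_missed=0, min_len=1)
        expected = ["".join(pieces[i:j + 1])
                    for i in range(len(pieces))
                    for j in range(i, min(i + 3, len(pieces)))]
        assert peptides == expected


class TestMatching:
    DB = {
        "annot1": "MAAAAAKGGGGGGKCCCCCC",
        "annot2": "MWWWWWKGGGGGGKDDDDDD",
        "orf1": "SSSSSKTTTTTTKYYYYYYK",
    }

    def test_unique_peptide_matches_one_sequence(self):
        out = match_peptides(["TTTTTTK"], self.DB)
        assert list(out["seq_id"]) == ["orf1"]

    def test_shared_peptide_lists_all_sequences(self):
        out = match_peptides(["GGGGGGK"], self.DB)
        assert set(out["seq_id"]) == {"annot1", "annot2"}

    def test_mismatch_does_not_match(self):
        assert match_peptides(["TTTTATK"], self.DB).empty

    def test_termini_must_be_lysC_consistent(self):
        # internal substring without a preceding K boundary
        assert match_peptides(["AAAAKG"], self.DB).empty


class TestGrouping:
    def test_annotated_member_suppresses_novel_call(self):
        matches = pd.DataFrame({
            "peptide": ["GGGGGGK", "GGGGGGK", "AAAAAK"],
            "seq_id": ["annot1", "sixframe:+1:10", "annot1"],
        })
        groups, calls = group_proteins(matches, {"annot1"})
        assert len(groups) == 1
        assert groups[0].has_annotated_member
        assert calls.empty

    def test_unannotated_group_with_enough_peptides_called(self):
        matches = pd.DataFrame({
            "peptide": ["SSSSSK", "TTTTTTK", "YYYYYYK"],
            "seq_id": ["sixframe:+2:5"] * 3,
        })
        _, calls = group_proteins(matches, {"annot1"})
        assert list(calls["orf_id"]) == ["sixframe:+2:5"]
        assert calls.loc[0, "n_peptides"] == 3

    def test_single_peptide_insufficient(self):
        matches = pd.DataFrame({"peptide": ["SSSSSK"],
                                "seq_id": ["sixframe:+2:5"]})
        _, calls = group_proteins(matches, set())
        assert calls.empty

    def test_grouping_is_a_partition(self, small_results):
        groups, _ = group_proteins(pd.DataFrame({
            "peptide": ["AK" * 3, "CK" * 3, "DK" * 3],
            "seq_id": ["s1", "s1", "s2"]}), set())
        seen = [m for g in groups for m in g.members]
        assert len(seen) == len(set(seen))


class TestCoverageValidation:
    def _orf(self, start=10, end=40, strand="+"):
        return SixFrameORF("chr:+1:4", 1, start, end, strand, "A" * 10)

    def _track(self, values_plus, n=100):
        plus = np.zeros(n)
        plus[:len(values_plus)] = values_plus
        return CoverageTrack("chr", plus, np.zeros(n))

    def test_uniform_coverage_supported(self):
        track = CoverageTrack("chr", np.full(100, 50.0), np.zeros(100))
        out = validate_with_coverage(self._orf(), track)
        assert out["status"] == "supported"
        assert out["mean_coverage"] == pytest.approx(50.0)

    def test_zero_coverage_insufficient(self):
        track = CoverageTrack("chr", np.zeros(100), np.zeros(100))
        out = validate_with_coverage(self._orf(), track)
        assert out["status"] == "insufficient"

    def test_sparse_coverage_fails_fraction_gate(self):
        plus = np.zeros(100)
        plus[10:25] = 100.0  # half the ORF, high depth
        track = CoverageTrack("chr", plus, np.zeros(100))
        out = validate_with_coverage(self._orf(), track)
        assert out["status"] == "insufficient"
        assert out["covered_fraction"] == pytest.approx(0.5)

    def test_orf_outside_track_rejected(self):
        track = CoverageTrack("chr", np.zeros(20), np.zeros(20))
        with pytest.raises(ValueError):
            validate_with_coverage(self._orf(), track)


def test_planted_orfs_recovered_end_to_end(small_results, small_truth):
    """All planted novel ORFs are discovered; exactly the transcribed
    ones gain RNA-seq support; no false novel calls arise."""
    calls = small_results["novel_calls"]
    truth = small_truth["novel"]
    hits = {}
    false_calls = 0
    for row in calls.itertuples(index=False):
        matched = truth[(truth["strand"] == row.strand)
                        & (truth["start"] >= row.start)
                        & (truth["end"] <= row.end)]
        if matched.empty:
            false_calls += 1
        for orf_id, expressed in zip(matched["orf_id"], matched["expressed"]):
            hits[orf_id] = row.rnaseq_status
    assert false_calls == 0
    for row in truth.itertuples(index=False):
        assert row.orf_id in hits
        expected = "supported" if row.expressed else "insufficient"
        assert hits[row.orf_id] == expected
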
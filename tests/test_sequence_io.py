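import gzip

import numpy as np
import pytest
from Bio.Seq import Seq

from domainmine.sequence_io import (
    LimitExceededError,
    QuerySequence,
    SequenceError,
    detect_alphabet,
    enforce_limits,
    read_fasta,
    reverse_complement,
    translate_six_frames,
    write_fasta,
)


def _write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_two_record_protein_file(self, tmp_path):
        p = _write(tmp_path, ">q1\nMKLV\n>q2\nWYHH\n")
        seqs = read_fasta(p)
        assert [s.query_id for s in seqs] == ["q1", "q2"]
        assert seqs[0].alphabet == "aa"
        assert seqs[1].source_index == 1

    def test_nucleotide_autodetection(self, tmp_path):
        p = _write(tmp_path, ">q\n" + "ACGTACGT" * 5 + "\n")
        assert read_fasta(p)[0].alphabet == "nt"

    def test_duplicate_id_names_offender(self, tmp_path):
        p = _write(tmp_path, ">dup\nMKLV\n>dup\nMKIV\n")
        with pytest.raises(SequenceError, match="dup"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(SequenceError):
            read_fasta(_write(tmp_path, ""))

    def test_alphabet_mismatch_rejected(self, tmp_path):
        p = _write(tmp_path, ">q\nMKLVWYHH\n")
        with pytest.raises(SequenceError):
            read_fasta(p, expected_alphabet="nt")

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "in.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">q\nMKLV\n")
        assert read_fasta(p)[0].residues == "MKLV"

    def test_read_write_round_trip(self, tmp_path):
        p = _write(tmp_path, ">a\nMKLVWY\n>b\nHHHH\n")
        seqs = read_fasta(p)
        out = tmp_path / "out.fasta"
        write_fasta([(s.query_id, s.residues) for s in seqs], out)
        again = read_fasta(out)
        assert [(s.query_id, s.residues) for s in seqs] == [
            (s.query_id, s.residues) for s in again
        ]


class TestLimits:
    def _mk(self, n, length=1):
        return [QuerySequence(f"q{i}", "aa", "M" * length, i) for i in range(n)]

    def test_sequence_count_boundary(self):
        enforce_limits(self._mk(10), max_count=10)
        with pytest.raises(LimitExceededError, match="1"):
            enforce_limits(self._mk(11), max_count=10)

    def test_residue_byte_boundary_inclusive(self):
        seqs = [QuerySequence("q", "aa", "M" * 1000, 0)]
        enforce_limits(seqs, max_bytes=1000)
        with pytest.raises(LimitExceededError):
            enforce_limits(seqs, max_bytes=999)

    def test_empty_input_rejected(self):
        with pytest.raises(SequenceError):
            enforce_limits([])


class TestTranslation:
    def test_forward_frame_one(self):
        q = QuerySequence("q", "nt", "ATGGCC", 0)
        frames = {f.frame: f for f in translate_six_frames(q)}
        assert frames[1].aa_residues == "MA"

    def test_reverse_frame_of_cat_is_methionine(self):
        q = QuerySequence("q", "nt", "CAT", 0)
        frames = {f.frame: f for f in translate_six_frames(q)}
        assert frames[-1].aa_residues == "M"

    def test_ambiguous_codons_translate_to_x(self):
        q = QuerySequence("q", "nt", "NNNATG", 0)
        frames = {f.frame: f for f in translate_six_frames(q)}
        assert frames[1].aa_residues == "XM"

    def test_short_frames_are_empty_not_errors(self):
        q = QuerySequence("q", "nt", "AT", 0)
        for f in translate_six_frames(q):
            assert f.aa_residues == ""

    def test_coordinate_round_trip_all_frames(self, rng):
        """Re-translating the mapped codon interval reproduces every residue."""
        nt = "".join(rng.choice(list("ACGT"), size=301))
        q = QuerySequence("q", "nt", nt, 0)
        for frame in translate_six_frames(q):
            for i in range(len(frame.aa_residues)):
                s, e = frame.aa_to_nt(i, i + 1)
                codon = nt[s:e]
                if frame.frame < 0:
                    codon = reverse_complement(codon)
                assert str(Seq(codon).translate()) == frame.aa_residues[i]
                assert frame.nt_to_aa(s, e) == (i, i + 1)

    def test_reverse_complement_swaps_frames(self, rng):
        nt = "".join(rng.choice(list("ACGT"), size=300))
        fwd = {f.frame: f.aa_residues for f in translate_six_frames(QuerySequence("q", "nt", nt, 0))}
        rc = {f.frame: f.aa_residues for f in translate_six_frames(QuerySequence("q", "nt", reverse_complement(nt), 0))}
        for k in (1, 2, 3):
            assert fwd[k] == rc[-k]
            assert fwd[-k] == rc[k]


def test_alphabet_detection_threshold():
    assert detect_alphabet("ACGTACGTAN") == "nt"
    assert detect_alphabet("MKLVWYHHDE") == "aa"


from hypothesis import given, settings
from hypothesis import strategies as st

nt_strings = st.text(alphabet="ACGT", min_size=3, max_size=120)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(nt_strings)
def test_frame_lengths_account_for_every_codon(nt):
    q = QuerySequence("q", "nt", nt, 0)
    for frame in translate_six_frames(q):
        k = abs(frame.frame) - 1
        assert len(frame.aa_residues) == (len(nt) - k) // 3


@settings(derandomize=True, max_examples=50, deadline=None)
@given(nt_strings)
def test_reverse_complement_involution_on_frames(nt):
    q = QuerySequence("q", "nt", nt, 0)
    rc = QuerySequence("q", "nt", reverse_complement(nt), 0)
    fwd = {f.frame: f.aa_residues for f in translate_six_frames(q)}
    rev = {f.frame: f.aa_residues for f in translate_six_frames(rc)}
    assert all(fwd[k] == rev[-k] for k in fwd)
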
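"""Sequence containers, translation frames and coordinate round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dirscan import seqio
from dirscan.seqio import (
    AaFragment,
    AlphabetError,
    Interval,
    NucSequence,
    map_aa_to_nt,
    reverse_complement,
    six_frame_translate,
    translate_str,
)

nt_text = st.text(alphabet="ACGT", min_size=3, max_size=120)


def test_reverse_complement_examples():
    assert reverse_complement(NucSequence("x", "ATTGC")).residues == "GCAAT"
    assert reverse_complement(NucSequence("x", "NAN")).residues == "NTN"


def test_empty_sequence_rejected():
    with pytest.raises(AlphabetError):
        NucSequence("x", "")
    with pytest.raises(AlphabetError):
        NucSequence("x", "ACGZ")


def test_iupac_ambiguity_normalized_to_n():
    s = NucSequence("x", "ACGRYSWu")
    assert s.residues == "ACGNNNNT"


@settings(derandomize=True, max_examples=100)
@given(nt_text)
def test_revcomp_involution(residues):
    s = NucSequence("x", residues)
    assert reverse_complement(reverse_complement(s)).residues == s.residues


def test_six_frame_translation():
    frags = six_frame_translate(NucSequence("x", "ATGAAATAG"))
    assert len(frags) == 6
    assert frags[0].residues == "MK*"
    # frame 3 equals frame 0 of the reverse complement
    rc = reverse_complement(NucSequence("x", "ATGAAATAG"))
    assert frags[3].residues == translate_str(rc.residues)


@settings(derandomize=True, max_examples=50)
@given(nt_text)
def test_six_frame_residue_count_identity(residues):
    n = len(residues)
    frags = six_frame_translate(NucSequence("x", residues))
    total = sum(len(f) for f in frags)
    assert total == 2 * (n // 3) + 2 * ((n - 1) // 3) + 2 * ((n - 2) // 3)


def test_translation_too_short():
    with pytest.raises(ValueError):
        six_frame_translate(NucSequence("x", "AT"))


def test_map_aa_to_nt_plus_strand():
    frag = AaFragment(seq_id="g", seq_len=300, frame=0, residues="M" * 100)
    iv = map_aa_to_nt(frag, 0, 3)
    assert (iv.start, iv.end, iv.strand) == (0, 9, "+")
    with pytest.raises(IndexError):
        map_aa_to_nt(frag, 90, 101)


@settings(derandomize=True, max_examples=60)
@given(nt_text.filter(lambda s: len(s) >= 12), st.integers(0, 5), st.data())
def test_aa_slice_roundtrip(residues, frame, data):
    """Translating the mapped nucleotide interval reproduces the aa slice."""
    s = NucSequence("g", residues)
    frag = six_frame_translate(s)[frame]
    if len(frag) < 1:
        return
    a = data.draw(st.integers(0, len(frag) - 1))
    b = data.draw(st.integers(a + 1, len(frag)))
    iv = map_aa_to_nt(frag, a, b)
    assert len(iv) == 3 * (b - a)
    nt = s.residues[iv.start : iv.end]
    if iv.strand == "-":
        nt = seqio.revcomp_str(nt)
    assert translate_str(nt) == frag.residues[a:b]


def test_interval_validation():
    with pytest.raises(ValueError):
        Interval("s", 5, 5)
    with pytest.raises(ValueError):
        Interval("s", -1, 5)
    assert len(Interval("s", 2, 10)) == 8


def test_fasta_roundtrip(tmp_path):
    seqs = [NucSequence("a", "ACGT" * 40), NucSequence("b", "TTTTA")]
    path = tmp_path / "x.fasta"
    seqio.write_fasta(path, seqs)
    back = seqio.read_fasta(path)
    assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]


def test_gff3_roundtrip(tmp_path):
    feats = [
        seqio.Gff3Feature("chr1", "t", "gene", 0, 10, None, "+", {"ID": "g1"}),
        seqio.Gff3Feature("chr1", "t", "exon", 3, 7, 1.5, "-", {"Parent": "g1"}),
    ]
    path = tmp_path / "x.gff3"
    seqio.write_gff3(path, feats)
    text = path.read_text()
    assert text.startswith("##gff-version 3")
    assert "\t4\t7\t" in text  # 1-based inclusive on disk
    back = seqio.read_gff3(path)
    assert [(f.seq_id, f.start, f.end, f.strand) for f in back] == [
        ("chr1", 0, 10, "+"),
        ("chr1", 3, 7, "-"),
    ]
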
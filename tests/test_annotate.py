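"""Repeat-architecture annotation: termini, ICRs, junction, ORFs, motifs."""

import numpy as np
import pytest

from dirscan import annotate as A
from dirscan import synth
from dirscan.seqio import NucSequence, reverse_complement
from dirscan.synth import ElementBlueprint


RO_BLUEPRINT = ElementBlueprint(
    seed=5, lE_len=28, lITR_div_len=14, lITR_cons_len=102, rE_len=9,
    junction="AAT", icr_lens=(59, 44), total_size=4274, orf_overlap=True,
)


@pytest.fixture(scope="module")
def ro_element():
    el, truth = synth.make_element(RO_BLUEPRINT)
    rng = np.random.default_rng(17)
    return synth.embed_with_flanks(el.residues, truth, rng, seq_id="RoLike"), truth


def test_published_parameter_closure(ro_element):
    """An element built with the RoDIRS1 row parameters annotates back to them
    exactly: size 4274, termini ATT/ATT, junction AAT, lE 28 / div 14 /
    cons 102 / rE 9, ICRs 59-44."""
    padded, _ = ro_element
    rec, ann, orf = A.annotate_element(padded, "RoLike")
    assert rec.size == 4274
    assert (rec.start_tri, rec.end_tri, rec.circular_junction) == ("ATT", "ATT", "AAT")
    assert (rec.lE, rec.divergent_itr, rec.conserved_itr, rec.rE) == ("28", "14", "102", "9")
    assert rec.icr_sizes == "59-44"
    assert rec.long_orf_overlap == "Yes"
    assert ann.junction_concordant


def test_conserved_itr_is_strict_reverse_complement(ro_element):
    padded, _ = ro_element
    _, ann, _ = A.annotate_element(padded, "x")
    seq = padded.residues
    el0 = ann.element_span.start
    lE, d, c = ann.lE_len, ann.lITR_div_len, ann.lITR_cons_len
    cons_l = seq[el0 + lE + d : el0 + lE + d + c]
    el1 = ann.element_span.end
    cons_r = seq[el1 - (ann.rE_len + d + c) : el1 - (ann.rE_len + d)]
    from dirscan.seqio import revcomp_str

    assert cons_r == revcomp_str(cons_l)
    # and the left ICR is the exact reverse complement of the element prefix
    licr = seq[ann.lICR_span.start : ann.lICR_span.end]
    assert revcomp_str(licr) == seq[el0 : el0 + len(licr)]


def test_reverse_complement_equivariance(ro_element):
    """Annotating the reverse complement swaps left/right roles and preserves
    lengths; the junction maps to its reverse complement."""
    padded, _ = ro_element
    _, ann, _ = A.annotate_element(padded, "f")
    _, ann_rc, _ = A.annotate_element(reverse_complement(padded), "r")
    assert ann_rc is not None
    assert ann_rc.size == ann.size
    assert ann_rc.lE_len == ann.rE_len
    assert ann_rc.rE_len == ann.lE_len
    assert ann_rc.lITR_div_len == ann.lITR_div_len
    assert ann_rc.lITR_cons_len == ann.lITR_cons_len
    assert (len(ann_rc.lICR_span), len(ann_rc.rICR_span)) == (
        len(ann.rICR_span), len(ann.lICR_span),
    )
    from dirscan.seqio import revcomp_str

    assert ann_rc.circular_junction == revcomp_str(ann.circular_junction)


def test_random_sequence_fails_annotation(rng):
    s = NucSequence("r", "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000)))
    rec, ann, orf = A.annotate_element(s, "r")
    assert ann is None
    assert rec.size is None
    assert rec.conserved_itr == "nd"


def test_deleted_icrs_fail_gracefully(ro_element):
    padded, truth = ro_element
    # excise the whole internal complementary block
    flank = padded.residues[: truth.licr_span[0] + 150]
    rest = padded.residues[truth.ricr_span[1] + 150 :]
    broken = NucSequence("b", flank + rest)
    rec, ann, _ = A.annotate_element(broken, "b")
    assert ann is None  # termini alone no longer anchor a consistent geometry
    assert rec.icr_sizes == "nd"


def test_two_mer_junction_recovered():
    bp = ElementBlueprint(
        seed=8, lE_len=0, lITR_div_len=10, lITR_cons_len=120, rE_len=12,
        junction="CG", icr_lens=(40, 46), total_size=4800, orf_overlap=False,
    )
    el, truth = synth.make_element(bp)
    rng = np.random.default_rng(3)
    padded = synth.embed_with_flanks(el.residues, truth, rng)
    rec, ann, _ = A.annotate_element(padded, "x")
    assert rec.circular_junction == "CG"
    assert rec.lE == "-"


# ---------------------------------------------------------------------------
# ORFs


def test_orf_overlap_detected(rng):
    """A dual-frame stop-free block yields two long ORFs in different frames."""
    body = synth._dual_frame_stopfree(1300, rng)
    seq = NucSequence("o", synth._stuffer(90, rng) + synth._STOP_BLOCK + body
                      + synth._STOP_BLOCK + synth._stuffer(90, rng))
    rep = A.detect_orf_overlap(seq, min_orf=600, min_overlap=50)
    assert rep.long_overlap
    assert rep.overlap_len >= 600
    # inclusive >= semantics at the exact boundary
    assert A.detect_orf_overlap(seq, min_orf=600, min_overlap=rep.overlap_len).long_overlap
    assert not A.detect_orf_overlap(seq, min_orf=600, min_overlap=rep.overlap_len + 1).long_overlap


def _single_frame_orf(n_units: int) -> str:
    """Stop-free in its own frame 0; stops recur in the two shifted frames."""
    return ("GCT" * 20 + "CTAACTTATGAC") * n_units


def test_orf_no_overlap_when_separated(rng):
    body = (
        _single_frame_orf(10)
        + synth._STOP_BLOCK * 2
        + synth._stuffer(300, rng)
        + "G"  # shift the second ORF into a different frame
        + _single_frame_orf(10)
    )
    seq = NucSequence("o", synth._STOP_BLOCK + body + synth._STOP_BLOCK)
    rep = A.detect_orf_overlap(seq, min_orf=600, min_overlap=50)
    assert not rep.long_overlap


# ---------------------------------------------------------------------------
# Motifs


@pytest.fixture(scope="module")
def scanned_element(profiles):
    bp = synth.draw_blueprint(42, orf_overlap=False)
    el, truth = synth.make_element(bp)
    from dirscan.profiles import scan_domain

    hits = []
    for kind in ("RT", "YR"):
        hits.extend(scan_domain(el, profiles[kind]))
    return el, truth, hits


def test_canonical_motifs_reported(scanned_element, profiles):
    el, truth, hits = scanned_element
    rep = A.scan_motifs(el, hits, profiles)
    assert rep.rt_motif is not None and rep.rt_canonical
    assert rep.yr_motif == "HSTR" and rep.yr_canonical


def test_variant_motif_reported_verbatim(profiles, consensi):
    """An element whose YR carries SDLK at the HSTR position is reported
    verbatim and flagged non-canonical."""
    rng = np.random.default_rng(9)
    pos = consensi["YR"].find("HSTR")
    variant = consensi["YR"][:pos] + "SDLK" + consensi["YR"][pos + 4 :]
    el = NucSequence("v", synth._stuffer(200, rng) + synth.back_translate(variant, rng) + synth._stuffer(200, rng))
    from dirscan.profiles import scan_domain

    hits = scan_domain(el, profiles["YR"])
    rep = A.scan_motifs(el, hits, profiles)
    assert rep.yr_motif == "SDLK"
    assert not rep.yr_canonical


def test_truncated_hit_motif_absent(profiles, consensi, rng):
    pos = profiles["RT"].consensus.find("Y")  # truncate before any motif
    import re

    m = re.search(r"Y[LI]DD", consensi["RT"])
    truncated = consensi["RT"][: m.start() - 5]
    el = NucSequence("t", synth._stuffer(150, rng) + synth.back_translate(truncated, rng) + synth._stuffer(150, rng))
    from dirscan.profiles import scan_domain

    hits = scan_domain(el, profiles["RT"])
    rep = A.scan_motifs(el, hits, profiles)
    assert rep.rt_motif is None


def test_table3_record_tsv_roundtrip(tmp_path, ro_element):
    padded, _ = ro_element
    rec, _, _ = A.annotate_element(padded, "RoLike")
    from dirscan.seqio import read_tsv, write_tsv

    path = tmp_path / "t3.tsv"
    write_tsv(path, list(A.Table3Record.COLUMNS), [rec.to_row()])
    _, rows = read_tsv(path)
    assert A.Table3Record.from_row(rows[0]) == rec
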
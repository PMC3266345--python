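"""Profile construction, calibration and translated genome search."""

import numpy as np
import pytest

from dirscan import profiles as P
from dirscan import resources, synth
from dirscan.seqio import NucSequence, reverse_complement


def test_identical_pair_consensus_is_max():
    p = P.build_profile([("a", "ACD"), ("b", "ACD")], "RT")
    assert p.length == 3
    assert p.consensus == "ACD"
    for i, aa in enumerate("ACD"):
        col = p.scores[i, :20]
        assert col.argmax() == P.align.AA_CODES[aa]


def test_gap_column_threshold():
    # col0 holds A,A,A,-,- (40% gaps, retained); col1 holds A,-,-,-,- (dropped)
    rows = ["AAR", "A-R", "A-R", "--R", "--R"]
    p = P.build_profile(rows, "RT")
    assert p.length == 2
    rows2 = ["AAR", "AAR", "AAR", "A-R", "A-R"]  # col1 40% gaps retained
    assert P.build_profile(rows2, "RT").length == 3


def test_build_profile_errors():
    with pytest.raises(P.ProfileError):
        P.build_profile([], "RT")
    with pytest.raises(P.ProfileError):
        P.build_profile(["ACD"], "RT")
    with pytest.raises(P.ProfileError):
        P.build_profile(["ACD", "AC"], "RT")


@pytest.mark.parametrize("kind,length", [("RT", 118), ("YR", 282), ("MT", 93)])
def test_packaged_profile_lengths(kind, length):
    assert resources.default_profile(kind, calibrated=False).length == length


def test_calibration_deterministic(profiles):
    p0 = resources.default_profile("MT", calibrated=False)
    c1 = P.calibrate_profile(p0, seed=5).calib
    c2 = P.calibrate_profile(p0, seed=5).calib
    assert (c1.lam, c1.K) == (c2.lam, c2.K)
    assert P.calibrate_profile(p0, seed=6).calib.lam != c1.lam


def test_consensus_scores_overwhelmingly_significant(profiles):
    p = profiles["RT"]
    codes = P.align.encode_aa(p.consensus)
    score = P.align.sw_best_score(p.scores, codes, p.gap_open, p.gap_ext)
    assert p.calib.evalue(score, 3 * p.length) < 1e-10


def test_scan_finds_exact_consensus_once(profiles, rng):
    p = profiles["RT"]
    ins = synth.back_translate(p.consensus, rng)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12000))
    genome = NucSequence("g", bg[:5000] + ins + bg[5000:])
    hits = P.scan_domain(genome, p)
    assert len(hits) == 1
    h = hits[0]
    assert h.profile_span == (0, p.length)
    assert (h.location.start, h.location.end) == (5000, 5000 + len(ins))
    assert h.strand == "+"

    # strand symmetry: scanning the reverse complement mirrors the hit exactly
    rc_hits = P.scan_domain(reverse_complement(genome), p)
    assert len(rc_hits) == 1
    assert rc_hits[0].score == pytest.approx(h.score)
    assert rc_hits[0].strand == "-"
    assert len(rc_hits[0].location) == len(h.location)


def test_nearby_same_strand_hits_merge(profiles, rng):
    p = profiles["MT"]
    ins = synth.back_translate(p.consensus, rng)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8000))
    # two copies 100 nt apart -> one merged hit; 2 kb apart -> two hits
    g1 = NucSequence("g", bg[:3000] + ins + bg[3000:3100] + ins + bg[3100:])
    assert len(P.scan_domain(g1, p)) == 1
    g2 = NucSequence("g", bg[:3000] + ins + bg[3000:5000] + ins + bg[5000:])
    assert len(P.scan_domain(g2, p)) == 2


def test_uncalibrated_profile_refuses_to_scan():
    p = resources.default_profile("RT", calibrated=False)
    with pytest.raises(RuntimeError):
        P.scan_domain(NucSequence("g", "ACGT" * 100), p)


def test_profile_serialization_roundtrip(tmp_path, profiles):
    p = profiles["MT"]
    path = tmp_path / "mt.tsv"
    P.write_profile(path, p)
    back = P.read_profile(path)
    assert back.domain_kind == "MT"
    assert back.length == p.length
    np.testing.assert_allclose(back.scores, p.scores, rtol=1e-4, atol=1e-5)
    assert back.calib.lam == pytest.approx(p.calib.lam)
    assert back.calib.K == pytest.approx(p.calib.K)
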
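"""Structural annotation of called DIRS1-like copies.

The repeat architecture of a DIRS1-like element ties its two termini to two
internal complementary regions (ICRs) near the 3' end:

* the left ICR is the exact reverse complement of the beginning of the left
  terminus (extension lE + divergent ITR + the outer part of the conserved
  ITR);
* the right ICR is the exact reverse complement of the end of the right
  terminus (inner part of the conserved ITR + divergent ITR + extension rE);
* the two ICRs overlap on a 2-3 bp circular junction whose reverse
  complement recurs as the element's terminal trinucleotide (the
  rolling-circle integration model);
* within the inverted terminal repeats, a conserved part is strictly
  reverse-complementary between the termini while a divergent part is only
  partially so (each side being constrained by its own ICR instead).

Annotation therefore proceeds by exact-match anchoring: the conserved ITR is
the maximal exact reverse-complement run between the terminal windows, and
each ICR is the maximal exact reverse-complement match between the interior
and the corresponding terminal window. The divergent/extension split scans
outward from the conserved ITR for the outermost complementary column;
extensions are the terminal residue beyond it. Failures degrade to "nd"
fields rather than aborting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import align
from .config import Config, DEFAULT_CONFIG
from .profiles import DomainHit, DomainProfile
from .seqio import Interval, NucSequence, revcomp_str, translate_str

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class AnnotationFailure(RuntimeError):
    """No inverted-terminal-repeat structure above thresholds."""


@dataclass
class TerminiAnnotation:
    element_span: Interval              # within the analysed copy sequence
    start_tri: str
    end_tri: str
    circular_junction: str | None
    lE_len: int
    rE_len: int
    lITR_div_len: int
    lITR_cons_len: int
    rITR_div_len: int
    rITR_cons_len: int
    lICR_span: Interval
    rICR_span: Interval
    boundary_motif: str | None
    junction_concordant: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.element_span)


@dataclass
class OrfReport:
    orfs: list[tuple[Interval, int]]
    long_overlap: bool
    overlap_len: int


@dataclass
class MotifReport:
    rt_motif: str | None
    rt_canonical: bool
    yr_motif: str | None
    yr_canonical: bool


@dataclass
class Table3Record:
    """One row in the style of the published per-element annotation table."""

    element: str
    size: int | None
    start_tri: str
    end_tri: str
    circular_junction: str
    long_orf_overlap: str   # Yes / No / nd
    lE: str                 # length or "-" (absent) or "nd"
    divergent_itr: str
    conserved_itr: str
    rE: str
    icr_sizes: str          # "59-44" style or "nd"

    COLUMNS = (
        "element", "size", "start", "end", "circular_junction",
        "long_orf_overlap", "lE", "divergent_itr", "conserved_itr", "rE",
        "icr_sizes",
    )

    def to_row(self) -> list[str]:
        return [
            self.element,
            "nd" if self.size is None else str(self.size),
            self.start_tri, self.end_tri, self.circular_junction,
            self.long_orf_overlap, self.lE, self.divergent_itr,
            self.conserved_itr, self.rE, self.icr_sizes,
        ]

    @classmethod
    def from_row(cls, row: list[str]) -> "Table3Record":
        return cls(
            element=row[0],
            size=None if row[1] == "nd" else int(row[1]),
            start_tri=row[2], end_tri=row[3], circular_junction=row[4],
            long_orf_overlap=row[5], lE=row[6], divergent_itr=row[7],
            conserved_itr=row[8], rE=row[9], icr_sizes=row[10],
        )


def _codes(s: str):
    return align.encode_nt(s)


def _itr_candidates(w5: str, w3: str, config: Config) -> list[tuple[int, int, int]]:
    """Conserved-ITR candidates: maximal exact reverse-complement runs between
    the terminal windows, gated by a tolerant local alignment threshold.

    Returns (run_len, start_in_w5, start_in_rc_w3) tuples, longest first. The
    internal complementary regions can fall inside the 3' window and then
    produce exact matches longer than the conserved ITR itself, so callers
    must verify each candidate against the full repeat geometry.
    """
    rc3 = revcomp_str(w3)
    # tolerant seed alignment (divergent ITR parts can be only ~50% identical);
    # spans come from the linear-memory kernel, the path from the spanned
    # subregions only, so large windows stay affordable
    prof = _tolerant_nt_matrix(w5)
    hit = align.sw_best_alignment(prof, _codes(rc3), 2.0, 1.0)
    if hit is None:
        raise AnnotationFailure("no terminal repeat alignment above minimum length")
    sub5 = w5[hit.q_start : hit.q_end]
    sub3 = rc3[hit.s_start : hit.s_end]
    _, path = align.align_path(_tolerant_nt_matrix(sub5), _codes(sub3), 2.0, 1.0)
    if len(path) < config.itr_min_len:
        raise AnnotationFailure("no terminal repeat alignment above minimum length")
    matches = sum(1 for i, j in path if sub5[i] == sub3[j])
    if matches / len(path) < config.itr_min_identity:
        raise AnnotationFailure("terminal repeat alignment below identity threshold")
    cands = align.maximal_exact_matches(_codes(w5), _codes(rc3), config.itr_min_len)
    if not cands:
        raise AnnotationFailure("no exact conserved inverted-repeat block")
    return cands[:8]


def _tolerant_nt_matrix(query: str):
    import numpy as np

    codes = _codes(query)
    prof = np.full((len(codes), align.N_NT_CODES), -1.0)
    for i, c in enumerate(codes):
        if c == 4:
            prof[i, :] = 0.0
        else:
            prof[i, c] = 1.0
    prof[:, 4] = 0.0
    return prof


def _derive_geometry(
    seq: str,
    L: int,
    W: int,
    w5: str,
    w3: str,
    c_len: int,
    a5: int,
    b3: int,
    config: Config,
):
    """Try one conserved-ITR candidate; return the full repeat geometry if it
    is self-consistent, else None.

    Consistency demands that each ICR is an exact reverse complement of its
    terminus reaching into (but not beyond) the conserved block, and that the
    right ICR ends exactly where the right terminus begins.
    """
    cons_l = (a5, a5 + c_len)                       # absolute (w5 starts at 0)
    cons_r = (L - b3 - c_len, L - b3)               # absolute in seq
    if cons_l[1] > cons_r[0]:
        return None
    region = seq[cons_l[1] : cons_r[0]]
    r_off = cons_l[1]
    if len(region) < config.itr_min_len:
        return None

    # left ICR: exact reverse complement of the element prefix
    l_len, rx, wy = align.longest_common_substring(_codes(region), _codes(revcomp_str(w5)))
    if l_len < config.itr_min_len:
        return None
    licr = (r_off + rx, r_off + rx + l_len)
    el_start = W - wy - l_len
    if not (0 <= el_start <= cons_l[0] < el_start + l_len <= cons_l[1]):
        return None

    # right ICR: exact reverse complement of the element suffix
    rr_len, rx2, wy2 = align.longest_common_substring(
        _codes(region), _codes(revcomp_str(w3))
    )
    if rr_len < config.itr_min_len:
        return None
    ricr = (r_off + rx2, r_off + rx2 + rr_len)
    el_end = L - wy2
    if not (cons_r[1] <= el_end <= L):
        return None
    if not (cons_r[0] <= el_end - rr_len < cons_r[1]):
        return None
    # the ICR block abuts one terminus: the right one for an element read in
    # its own 5'->3' orientation, the left one for a reverse-complement copy
    if ricr[1] != cons_r[0] and licr[0] != cons_l[1]:
        return None
    if licr[0] >= ricr[0]:
        return None
    return c_len, cons_l, cons_r, licr, ricr, el_start, el_end


def locate_termini(
    copy_seq: NucSequence,
    search_window: int = 600,
    config: Config = DEFAULT_CONFIG,
) -> TerminiAnnotation:
    """Full repeat annotation of one element-oriented copy sequence.

    ``copy_seq`` must contain the element plus flanking sequence; the termini
    are sought within the first and last ``search_window`` nucleotides.
    """
    seq = copy_seq.residues
    L = len(seq)
    W = min(search_window, L // 2)
    w5, w3 = seq[:W], seq[-W:]
    warnings: list[str] = []

    derived = None
    for c_len, a5, b3 in _itr_candidates(w5, w3, config):
        derived = _derive_geometry(seq, L, W, w5, w3, c_len, a5, b3, config)
        if derived is not None:
            break
    if derived is None:
        raise AnnotationFailure("no self-consistent terminal repeat geometry")
    c_len, cons_l, cons_r, licr, ricr, el_start, el_end = derived

    # circular junction: overlap of the two ICRs
    j_start, j_end = max(licr[0], ricr[0]), min(licr[1], ricr[1])
    junction: str | None = None
    if 2 <= j_end - j_start <= 3:
        junction = seq[j_start:j_end]
    else:
        warnings.append(
            f"ICR overlap of {max(0, j_end - j_start)} nt outside 2-3 bp; junction absent"
        )

    # divergent/extension partition: scan outward from the conserved block for
    # the outermost complementary column between the two termini
    a = cons_l[0] - el_start          # lE + divergent
    b = el_end - cons_r[1]            # divergent + rE
    div = 0
    for k in range(min(a, b)):
        if seq[cons_l[0] - 1 - k] == _COMP[seq[cons_r[1] + k]]:
            div = k + 1
    le_len = a - div
    re_len = b - div
    if le_len == 0 and re_len == 0:
        warnings.append("no extension on either terminus (violates >=1-extension rule)")

    start_tri = seq[el_start : el_start + 3]
    end_tri = seq[el_end - 3 : el_end]
    concordant = junction is not None and revcomp_str(junction) in (
        start_tri[: len(junction)],
        end_tri[3 - len(junction) :],
    )

    motif = _boundary_motif(
        seq[el_start : cons_l[1]],
        revcomp_str(seq[cons_r[0] : el_end]),
        revcomp_str(seq[licr[0] : licr[1]]),
        seq[ricr[0] : ricr[1]],
    )

    return TerminiAnnotation(
        element_span=Interval(copy_seq.id, el_start, el_end, "+"),
        start_tri=start_tri,
        end_tri=end_tri,
        circular_junction=junction,
        lE_len=le_len,
        rE_len=re_len,
        lITR_div_len=div,
        lITR_cons_len=c_len,
        rITR_div_len=div,
        rITR_cons_len=c_len,
        lICR_span=Interval(copy_seq.id, licr[0], licr[1], "+"),
        rICR_span=Interval(copy_seq.id, ricr[0], ricr[1], "+"),
        boundary_motif=motif,
        junction_concordant=concordant,
        warnings=warnings,
    )


def locate_icrs(ann: TerminiAnnotation) -> tuple[Interval, Interval]:
    """ICR spans from a completed annotation (kept for API symmetry)."""
    return ann.lICR_span, ann.rICR_span


def find_circular_junction(ann: TerminiAnnotation) -> str | None:
    return ann.circular_junction


def _boundary_motif(lter: str, rc_rter: str, rc_licr: str, ricr: str) -> str | None:
    """Longest block (>=10 nt) shared by both termini and both ICRs, all read
    in the left-terminus orientation."""
    seqs = [lter, rc_rter, rc_licr, ricr]
    shortest = min(seqs, key=len)
    others = [s for s in seqs if s is not shortest]
    best = ""
    n = len(shortest)
    for length in range(n, len(best), -1):
        found = False
        for i in range(n - length + 1):
            cand = shortest[i : i + length]
            if all(cand in o for o in others):
                best = cand
                found = True
                break
        if found:
            break
    return best if len(best) >= 10 else None


# ---------------------------------------------------------------------------
# ORFs and motifs


def detect_orf_overlap(
    copy_seq: NucSequence, min_orf: int = 600, min_overlap: int = 50
) -> OrfReport:
    """Stop-to-stop open reading frames on the element strand and their
    cross-frame overlaps."""
    seq = copy_seq.residues
    orfs: list[tuple[Interval, int]] = []
    for frame in range(3):
        aa = translate_str(seq[frame:])
        start = 0
        for m in re.finditer(r"\*", aa + "*"):
            end = m.start()
            if (end - start) * 3 >= min_orf:
                orfs.append(
                    (
                        Interval(copy_seq.id, frame + 3 * start, frame + 3 * end, "+"),
                        frame,
                    )
                )
            start = end + 1
    best = 0
    for i, (iv1, f1) in enumerate(orfs):
        for iv2, f2 in orfs[i + 1 :]:
            if f1 == f2:
                continue
            ov = min(iv1.end, iv2.end) - max(iv1.start, iv2.start)
            best = max(best, ov)
    return OrfReport(orfs=orfs, long_overlap=best >= min_overlap, overlap_len=max(best, 0))


RT_MOTIF_RE = re.compile(r"Y[LI]DD")
YR_MOTIF = "HSTR"


def _motif_at_hit(
    seq: str,
    hit: DomainHit,
    profile: DomainProfile,
    motif_pos: int,
    el_offset: int = 0,
) -> str | None:
    """Translate the element region aligned to profile positions
    [motif_pos, motif_pos+4)."""
    loc = hit.location
    start, end = loc.start - el_offset, loc.end - el_offset
    if start < 0 or end > len(seq):
        return None
    region = seq[start:end] if loc.strand == "+" else revcomp_str(seq[start:end])
    aa = translate_str(region)
    if not aa:
        return None
    _, path = align.align_path(
        profile.scores, align.encode_aa(aa), profile.gap_open, profile.gap_ext
    )
    by_prof = {i: j for i, j in path}
    cols = [by_prof.get(motif_pos + k) for k in range(4)]
    if any(c is None for c in cols) or cols != list(range(cols[0], cols[0] + 4)):
        return None
    return aa[cols[0] : cols[0] + 4]


def scan_motifs(
    copy_seq: NucSequence,
    hits: list[DomainHit],
    profiles: dict[str, DomainProfile],
    el_offset: int = 0,
) -> MotifReport:
    """Diagnostic catalytic motifs: the RT Y[LI]DD box and the YR HSTR box.

    The expected position of each motif is taken from the profile consensus;
    the element's residues at that position are reported verbatim, flagged as
    canonical when they match the expected pattern.
    """
    rt_motif = yr_motif = None
    seq = copy_seq.residues
    rt_hits = [h for h in hits if h.domain_kind == "RT"]
    yr_hits = [h for h in hits if h.domain_kind == "YR"]
    if rt_hits and "RT" in profiles:
        m = RT_MOTIF_RE.search(profiles["RT"].consensus)
        if m:
            best = min(rt_hits, key=lambda h: h.evalue)
            rt_motif = _motif_at_hit(seq, best, profiles["RT"], m.start(), el_offset)
    if yr_hits and "YR" in profiles:
        pos = profiles["YR"].consensus.find(YR_MOTIF)
        if pos >= 0:
            best = min(yr_hits, key=lambda h: h.evalue)
            yr_motif = _motif_at_hit(seq, best, profiles["YR"], pos, el_offset)
    return MotifReport(
        rt_motif=rt_motif,
        rt_canonical=bool(rt_motif and RT_MOTIF_RE.fullmatch(rt_motif)),
        yr_motif=yr_motif,
        yr_canonical=yr_motif == YR_MOTIF,
    )


# ---------------------------------------------------------------------------
# Composite record


def annotate_element(
    copy_seq: NucSequence,
    element_id: str = "element",
    search_window: int = 600,
    config: Config = DEFAULT_CONFIG,
) -> tuple[Table3Record, TerminiAnnotation | None, OrfReport | None]:
    """Full per-element record; annotation failures degrade to "nd" fields.

    ``copy_seq`` must be oriented 5'->3' along the element (callers reverse-
    complement minus-strand copies first) and include flanking sequence.
    """
    try:
        ann = locate_termini(copy_seq, search_window=search_window, config=config)
    except AnnotationFailure:
        orf = detect_orf_overlap(copy_seq, config.min_orf, config.min_orf_overlap)
        rec = Table3Record(
            element=element_id,
            size=None,
            start_tri="nd", end_tri="nd", circular_junction="nd",
            long_orf_overlap="Yes" if orf.long_overlap else "No",
            lE="nd", divergent_itr="nd", conserved_itr="nd", rE="nd",
            icr_sizes="nd",
        )
        return rec, None, orf
    el = copy_seq.subseq(ann.element_span.start, ann.element_span.end, seq_id=element_id)
    orf = detect_orf_overlap(el, config.min_orf, config.min_orf_overlap)
    rec = Table3Record(
        element=element_id,
        size=ann.size,
        start_tri=ann.start_tri,
        end_tri=ann.end_tri,
        circular_junction=ann.circular_junction or "nd",
        long_orf_overlap="Yes" if orf.long_overlap else "No",
        lE=str(ann.lE_len) if ann.lE_len > 0 else "-",
        divergent_itr=str(ann.lITR_div_len),
        conserved_itr=str(ann.lITR_cons_len),
        rE=str(ann.rE_len) if ann.rE_len > 0 else "-",
        icr_sizes=f"{len(ann.lICR_span)}-{len(ann.rICR_span)}",
    )
    return rec, ann, orf
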
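"""Position-specific scoring profiles for the RT, MT and YR domains.

A profile is built from a seed multiple alignment of the domain: columns with
more than 50% gaps are dropped and per-column log-odds scores (bits) are
computed from add-one pseudocounted frequencies against a standard background
amino-acid composition. Significance is calibrated empirically per profile: a
Gumbel distribution is fitted to maximal local scores against shuffled
background sequences, after which translated genome searches report
E = K * m * n * exp(-lambda * S) with n the nucleotide length of the searched
region (all six reading frames are counted inside K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import align
from .align import GumbelCalibration, LocalHit
from .seqio import (
    AA_ALPHABET,
    Interval,
    NucSequence,
    map_aa_to_nt,
    six_frame_translate,
)

DOMAIN_KINDS = ("RT", "MT", "YR")

# Standard background amino-acid composition (Robinson & Robinson style,
# order = alphabetical one-letter code as in AA_ALPHABET), normalized on use.
BACKGROUND_AA = np.array(
    [
        0.078, 0.024, 0.052, 0.059, 0.044, 0.083, 0.025, 0.062, 0.056, 0.092,
        0.024, 0.041, 0.043, 0.034, 0.051, 0.059, 0.055, 0.072, 0.014, 0.034,
    ]
)
BACKGROUND_AA = BACKGROUND_AA / BACKGROUND_AA.sum()

STOP_SCORE = -10.0  # bits; keeps local alignments from crossing stop codons

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXT = 1.0


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class DomainProfile:
    """Log-odds profile (bits) over 20 amino acids + X + stop per position."""

    domain_kind: str
    scores: np.ndarray  # (length, 22)
    background: np.ndarray
    source_alignment_id: str
    gap_open: float = DEFAULT_GAP_OPEN
    gap_ext: float = DEFAULT_GAP_EXT
    calib: GumbelCalibration | None = None

    def __post_init__(self) -> None:
        if self.domain_kind not in DOMAIN_KINDS:
            raise ProfileError(f"unknown domain kind {self.domain_kind!r}")
        if self.scores.ndim != 2 or self.scores.shape[1] != align.N_AA_CODES:
            raise ProfileError("profile score matrix must be (length, 22)")
        if self.scores.shape[0] == 0:
            raise ProfileError("empty profile")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    @property
    def consensus(self) -> str:
        idx = np.argmax(self.scores[:, :20], axis=1)
        return "".join(AA_ALPHABET[i] for i in idx)

    def require_calibrated(self) -> GumbelCalibration:
        if self.calib is None:
            raise RuntimeError(
                f"{self.domain_kind} profile is not calibrated; run calibrate_profile first"
            )
        return self.calib


def build_profile(
    msa: list[tuple[str, str]] | list[str], domain_kind: str, source_id: str = ""
) -> DomainProfile:
    """Build a log-odds profile from an aligned set of amino-acid sequences."""
    rows = [r if isinstance(r, str) else r[1] for r in msa]
    if not rows:
        raise ProfileError("empty alignment")
    if len(rows) < 2:
        raise ProfileError("need at least 2 aligned sequences")
    if len({len(r) for r in rows}) != 1:
        raise ProfileError("ragged alignment")
    rows = [r.upper() for r in rows]
    n_seq = len(rows)
    ncols = len(rows[0])
    bg = BACKGROUND_AA
    kept_scores = []
    for c in range(ncols):
        col = [r[c] for r in rows]
        gaps = sum(1 for x in col if x == "-")
        if gaps / n_seq > 0.5:
            continue
        counts = np.zeros(20)
        for x in col:
            if x in align.AA_CODES and align.AA_CODES[x] < 20:
                counts[align.AA_CODES[x]] += 1
        n_obs = counts.sum()
        if n_obs == 0:
            continue  # column of gaps/ambiguity only
        # background-proportional pseudocounts (total prior weight 1): the
        # observed residue always attains the column's maximum log-odds
        p = (counts + bg) / (n_obs + 1.0)
        col_scores = np.empty(align.N_AA_CODES)
        col_scores[:20] = np.log2(p / bg)
        col_scores[20] = 0.0  # X is neutral
        col_scores[21] = STOP_SCORE
        kept_scores.append(col_scores)
    if not kept_scores:
        raise ProfileError("no informative columns after gap filtering")
    return DomainProfile(
        domain_kind=domain_kind,
        scores=np.array(kept_scores),
        background=bg.copy(),
        source_alignment_id=source_id,
    )


def calibrate_profile(
    p: DomainProfile, seed: int, n_seqs: int = 300, seq_len: int = 400
) -> DomainProfile:
    """Fit Gumbel (lambda, K) on maximal scores against the genomic null.

    The null sequences are translations of shuffled random nucleotide
    sequence, so the stop codons that segment every real reading frame (and
    their strongly negative score) are part of the fitted distribution;
    calibrating on clean random amino-acid strings instead overstates the
    attainable null scores several-fold at the E <= 0.01 tail. The stored K
    is expressed per nucleotide of genomic search space: a six-frame scan of
    an n-nt region covers about 2n amino acids, so the amino-acid-level K is
    doubled.
    """
    from .seqio import translate_str

    rng = np.random.default_rng(seed)
    scores = np.empty(n_seqs)
    for k in range(n_seqs):
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3 * seq_len))
        codes = align.encode_aa(translate_str(nt))
        scores[k] = align.sw_best_score(p.scores, codes, p.gap_open, p.gap_ext)
    calib_aa = align.fit_gumbel(scores, p.length, seq_len)
    genomic = GumbelCalibration(
        lam=calib_aa.lam, K=2.0 * calib_aa.K, m=calib_aa.m, n_cal=calib_aa.n_cal
    )
    return replace(p, calib=genomic)


@dataclass(frozen=True)
class DomainHit:
    """A significant translated profile match on genomic sequence."""

    domain_kind: str
    location: Interval
    frame: int
    aa_span: tuple[int, int]
    profile_span: tuple[int, int]
    score: float
    evalue: float

    @property
    def strand(self) -> str:
        return self.location.strand

    def key(self) -> tuple:
        """Identity used for hit sharing between overlapping windows."""
        return (
            self.domain_kind,
            self.location.seq_id,
            self.location.start,
            self.location.end,
            self.location.strand,
        )


def scan_domain(
    genome: NucSequence,
    p: DomainProfile,
    evalue_cutoff: float = 0.01,
    merge_distance: int = 300,
    offset: int = 0,
    seq_id: str | None = None,
) -> list[DomainHit]:
    """Search all six frames of ``genome`` for local profile matches.

    ``offset``/``seq_id`` let callers scan an excised window while reporting
    hits in the parent sequence's coordinate system. The search space for
    E-values is the nucleotide length of the scanned sequence.
    """
    calib = p.require_calibrated()
    n_nt = len(genome)
    min_score = calib.score_for_evalue(evalue_cutoff, n_nt)
    sid = seq_id if seq_id is not None else genome.id
    hits: list[DomainHit] = []
    for frag in six_frame_translate(genome):
        if len(frag) == 0:
            continue
        codes = align.encode_aa(frag.residues)
        for lh in align.sw_local_hits(p.scores, codes, p.gap_open, p.gap_ext, min_score):
            loc = map_aa_to_nt(frag, lh.s_start, lh.s_end)
            loc = Interval(sid, loc.start + offset, loc.end + offset, loc.strand)
            hits.append(
                DomainHit(
                    domain_kind=p.domain_kind,
                    location=loc,
                    frame=frag.frame,
                    aa_span=(lh.s_start, lh.s_end),
                    profile_span=(lh.q_start, lh.q_end),
                    score=lh.score,
                    evalue=calib.evalue(lh.score, n_nt),
                )
            )
    return merge_nearby_hits(hits, merge_distance)


def merge_nearby_hits(hits: list[DomainHit], merge_distance: int) -> list[DomainHit]:
    """Merge same-domain same-strand hits closer than ``merge_distance`` nt.

    The merged hit keeps the best (lowest) E-value's alignment metadata and
    covers the union interval; this absorbs frameshift-split matches in
    slightly degenerate copies.
    """
    out: list[DomainHit] = []
    by_group: dict[tuple, list[DomainHit]] = {}
    for h in hits:
        by_group.setdefault((h.domain_kind, h.location.seq_id, h.strand), []).append(h)
    for group in by_group.values():
        group.sort(key=lambda h: h.location.start)
        chain: list[DomainHit] = [group[0]]
        for h in group[1:]:
            if h.location.start - chain[-1].location.end < merge_distance:
                chain.append(h)
            else:
                out.append(_merge_chain(chain))
                chain = [h]
        out.append(_merge_chain(chain))
    out.sort(key=lambda h: (h.location.seq_id, h.location.start, h.domain_kind))
    return out


def _merge_chain(chain: list[DomainHit]) -> DomainHit:
    if len(chain) == 1:
        return chain[0]
    best = min(chain, key=lambda h: h.evalue)
    loc = Interval(
        best.location.seq_id,
        min(h.location.start for h in chain),
        max(h.location.end for h in chain),
        best.strand,
    )
    return replace(best, location=loc)


# ---------------------------------------------------------------------------
# Serialization


def write_profile(path: str | Path, p: DomainProfile) -> None:
    calib = p.calib
    with open(path, "w") as fh:
        fh.write(f"#domain_kind\t{p.domain_kind}\n")
        fh.write(f"#length\t{p.length}\n")
        fh.write(f"#source\t{p.source_alignment_id}\n")
        fh.write(f"#gap_open\t{p.gap_open}\n#gap_ext\t{p.gap_ext}\n")
        if calib is not None:
            fh.write(f"#lambda\t{calib.lam!r}\n#K\t{calib.K!r}\n#n_cal\t{calib.n_cal}\n")
        fh.write("pos\t" + "\t".join(AA_ALPHABET + "X*") + "\n")
        for i in range(p.length):
            fh.write(str(i) + "\t" + "\t".join(f"{x:.6f}" for x in p.scores[i]) + "\n")


def read_profile(path: str | Path) -> DomainProfile:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].rstrip("\n").partition("\t")
                meta[k] = v
            elif line.startswith("pos"):
                continue
            elif line.strip():
                rows.append([float(x) for x in line.split("\t")[1:]])
    scores = np.array(rows)
    calib = None
    if "lambda" in meta:
        calib = GumbelCalibration(
            lam=float(meta["lambda"]),
            K=float(meta["K"]),
            m=scores.shape[0],
            n_cal=int(meta["n_cal"]),
        )
    return DomainProfile(
        domain_kind=meta["domain_kind"],
        scores=scores,
        background=BACKGROUND_AA.copy(),
        source_alignment_id=meta.get("source", ""),
        gap_open=float(meta.get("gap_open", DEFAULT_GAP_OPEN)),
        gap_ext=float(meta.get("gap_ext", DEFAULT_GAP_EXT)),
        calib=calib,
    )
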
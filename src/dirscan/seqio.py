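"""Sequence containers, coordinate conventions, translation and file IO.

Internal coordinates are 0-based half-open throughout; GFF3 output is 1-based
inclusive. IUPAC ambiguity codes other than N are normalized to N on input and
behave as mismatches everywhere downstream.

Six-frame convention: frames 0-2 are offsets 0, 1, 2 on the forward strand;
frames 3-5 are offsets 0, 1, 2 of the reverse complement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = set("ACGTN")
_IUPAC = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_WITH_X = AA_ALPHABET + "X*"


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the nucleotide alphabet."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"sequence {self.id!r} is empty")
        res = self.residues.upper().replace("U", "T")
        if not set(res) <= _IUPAC:
            bad = sorted(set(res) - _IUPAC)
            raise AlphabetError(f"sequence {self.id!r} has non-IUPAC characters: {bad}")
        # normalize every ambiguity code except N itself to N
        res = "".join(c if c in NUC_ALPHABET else "N" for c in res)
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int, seq_id: str | None = None) -> "NucSequence":
        if not (0 <= start < end <= len(self)):
            raise IndexError(f"[{start},{end}) out of range for length {len(self)}")
        return NucSequence(seq_id or f"{self.id}:{start}-{end}", self.residues[start:end])


def reverse_complement(s: NucSequence) -> NucSequence:
    """Watson-Crick reverse complement; N maps to N."""
    return NucSequence(s.id, s.residues.translate(_COMPLEMENT)[::-1])


def revcomp_str(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open stranded genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AaFragment:
    """One frame of a six-frame translation, tied back to its genomic footprint.

    ``parent`` is the interval of the translated nucleotide region on the
    forward strand of the genome; ``offset`` is the frame offset (0-2) within
    the strand-oriented sequence.
    """

    seq_id: str
    seq_len: int
    frame: int
    residues: str

    @property
    def strand(self) -> str:
        return "+" if self.frame < 3 else "-"

    @property
    def offset(self) -> int:
        return self.frame % 3

    def __len__(self) -> int:
        return len(self.residues)


def translate_str(nt: str) -> str:
    """Standard-code translation of a frame-0 nucleotide string.

    Trailing 1-2 nt are dropped; internal stops are kept as '*'; codons with
    ambiguity translate to X when the amino acid is not determined.
    """
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate(table=1))


def six_frame_translate(s: NucSequence) -> list[AaFragment]:
    """Translate a nucleotide sequence in all six frames."""
    if len(s) < 3:
        raise ValueError(f"sequence {s.id!r} shorter than 3 nt cannot be translated")
    frags = []
    rc = revcomp_str(s.residues)
    for frame in range(6):
        src = s.residues if frame < 3 else rc
        off = frame % 3
        frags.append(
            AaFragment(
                seq_id=s.id,
                seq_len=len(s),
                frame=frame,
                residues=translate_str(src[off:]),
            )
        )
    return frags


def map_aa_to_nt(frag: AaFragment, aa_start: int, aa_end: int) -> Interval:
    """Genomic footprint (forward-strand coordinates) of an amino-acid slice."""
    if not (0 <= aa_start < aa_end <= len(frag)):
        raise IndexError(
            f"aa slice [{aa_start},{aa_end}) out of range for fragment of {len(frag)} aa"
        )
    off = frag.offset
    if frag.frame < 3:
        start = off + 3 * aa_start
        end = off + 3 * aa_end
        return Interval(frag.seq_id, start, end, "+")
    # minus strand: coordinates are on the reverse complement
    rc_start = off + 3 * aa_start
    rc_end = off + 3 * aa_end
    return Interval(frag.seq_id, frag.seq_len - rc_end, frag.seq_len - rc_start, "-")


# ---------------------------------------------------------------------------
# File IO


def read_fasta(path: str | Path) -> list[NucSequence]:
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, seqs: Iterable[NucSequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Aligned amino-acid FASTA as (id, row) pairs; '-' and '.' are gaps."""
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in SeqIO.parse(str(path), "fasta")]
    if rows and len({len(r) for _, r in rows}) != 1:
        raise ValueError(f"ragged alignment in {path}")
    return rows


@dataclass
class Gff3Feature:
    seq_id: str
    source: str
    ftype: str
    start: int  # 0-based half-open internally
    end: int
    score: float | None
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(path: str | Path, features: Sequence[Gff3Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            score = "." if f.score is None else f"{f.score:.3g}"
            fh.write(
                f"{f.seq_id}\t{f.source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t"
                f"{score}\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            feats.append(
                Gff3Feature(
                    seq_id=cols[0],
                    source=cols[1],
                    ftype=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    score=None if cols[5] == "." else float(cols[5]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return feats


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = list(r)
    if not rows:
        raise ValueError(f"empty table {path}")
    return rows[0], rows[1:]
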
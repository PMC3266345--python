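"""Synthetic genomes with planted DIRS1-like elements and ground truth.

The generator emits elements with the full repeat architecture (left/right
termini = extension + divergent ITR + conserved ITR, two internal
complementary regions overlapping on a 2-3 bp circular junction whose
reverse complement recurs at the termini) around back-translated domain
cassettes laid out YR - RT - MT on one strand, plus the decoy and degenerate
copies needed to exercise every pipeline filter (Ngaro-like architectures
without MT, frameshifted relics, PAT-like elements bounded by split direct
repeats).

Ground truth is only meaningful when the planted repeat boundaries are the
unique maximal ones, so the generator actively disambiguates: extension
columns are generated non-complementary to the opposite terminus, the
outermost divergent column is complementary (anchoring the divergent/
extension split), and the single bases flanking each repeat are chosen so
that no exact match extends past its planted end. Every element is verified
by round-tripping through the annotation module before being returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from . import resources
from .annotate import annotate_element
from .seqio import Interval, NucSequence, revcomp_str, translate_str

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOP_BLOCK = "TTAATTAATTAA"  # stop codons in all three forward frames
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
    _CODONS_BY_AA.setdefault(translate_str(_c), []).append(_c)
_STOPS = set(_CODONS_BY_AA["*"])


class BlueprintError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


def _rand_nt(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def _pick_base(rng: np.random.Generator, forbidden: set[str]) -> str:
    choices = [b for b in _BASES if b not in forbidden]
    return choices[rng.integers(0, len(choices))]


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue."""
    return "".join(
        _CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))] for a in aa
    )


def mutate_aa(
    aa: str, identity: float, rng: np.random.Generator, keep: set[int] | None = None
) -> str:
    """Substitute residues down to the target fractional identity."""
    out = list(aa)
    pool = [i for i in range(len(aa)) if not keep or i not in keep]
    n_mut = min(len(pool), round((1.0 - identity) * len(aa)))
    for i in rng.choice(len(pool), size=n_mut, replace=False):
        p = pool[i]
        out[p] = _pick_base_aa(rng, out[p])
    return "".join(out)


def _pick_base_aa(rng: np.random.Generator, avoid: str) -> str:
    choices = [c for c in _AA20 if c != avoid]
    return choices[rng.integers(0, len(choices))]


def mutate_nt(nt: str, identity: float, rng: np.random.Generator) -> str:
    out = list(nt)
    n_mut = round((1.0 - identity) * len(nt))
    for i in rng.choice(len(nt), size=n_mut, replace=False):
        out[i] = _pick_base(rng, {out[i]})
    return "".join(out)


def _stuffer(n: int, rng: np.random.Generator) -> str:
    """Random filler with stop codons in all frames every ~90 nt."""
    out: list[str] = []
    while len(out) < n:
        chunk = min(90, n - len(out))
        out.extend(_rand_nt(rng, chunk))
        if n - len(out) >= len(_STOP_BLOCK):
            out.extend(_STOP_BLOCK)
    return "".join(out[:n])


def _dual_frame_stopfree(n: int, rng: np.random.Generator) -> str:
    """A segment with no stop codon in its own frames 0 and 1.

    A base completes at most one of the two frames' codons at a time, so a
    greedy draw avoiding the <=2 stop-completing bases always succeeds.
    """
    out: list[str] = []
    for pos in range(n):
        forbidden: set[str] = set()
        for frame in (0, 1):
            if pos >= 2 and (pos - frame) % 3 == 2:
                prefix = out[pos - 2] + out[pos - 1]
                for b in _BASES:
                    if prefix + b in _STOPS:
                        forbidden.add(b)
        out.append(_pick_base(rng, forbidden))
    return "".join(out)


# ---------------------------------------------------------------------------
# Blueprints


@dataclass(frozen=True)
class ElementBlueprint:
    """Everything needed to emit one element deterministically."""

    seed: int
    rt_id: float = 0.9
    mt_id: float = 0.9
    yr_id: float = 0.9
    lE_len: int = 0
    lITR_div_len: int = 14
    lITR_cons_len: int = 102
    rE_len: int = 9
    junction: str = "AAT"
    icr_lens: tuple[int, int] = (59, 44)
    div_identity: float = 0.75
    orf_overlap: bool = False
    total_size: int = 4274
    preserve_motifs: bool = True

    def validate(self) -> None:
        e_l, d, c, e_r = self.lE_len, self.lITR_div_len, self.lITR_cons_len, self.rE_len
        icr_l, icr_r = self.icr_lens
        jlen = len(self.junction)
        if jlen not in (2, 3) or any(b not in _BASES for b in self.junction):
            raise BlueprintError("junction must be a 2-3 nt ACGT string")
        if d < 3 or c < 20:
            raise BlueprintError("divergent ITR must be >=3 nt, conserved >=20 nt")
        ov_l = icr_l - e_l - d
        ov_r = icr_r - e_r - d
        if not (1 <= ov_l < c and 1 <= ov_r < c):
            raise BlueprintError(
                "each ICR must reach into, but not beyond, the conserved ITR"
            )
        if (0 < e_l < jlen) or (0 < e_r < jlen):
            raise BlueprintError("a non-zero extension must be at least junction-sized")
        if e_l == 0 and e_r == 0:
            raise BlueprintError("at least one extension is required")
        if not (0.5 <= self.div_identity <= 0.9):
            raise BlueprintError("divergent ITR identity outside supported range")

    @property
    def overlap_into_cons(self) -> tuple[int, int]:
        return (
            self.icr_lens[0] - self.lE_len - self.lITR_div_len,
            self.icr_lens[1] - self.rE_len - self.lITR_div_len,
        )


def draw_blueprint(seed: int, orf_overlap: bool | None = None) -> ElementBlueprint:
    """A random blueprint within the observed per-element annotation ranges
    (ITR 66-316 nt, ICR sum 85-130 nt, rE 9-75 nt, size 3974-6283 nt)."""
    rng = np.random.default_rng([seed, 91])
    for _ in range(200):
        d = int(rng.integers(8, 31))
        c = int(rng.integers(40, 200))
        has_le = rng.random() < 0.35
        e_l = int(rng.integers(8, 40)) if has_le else 0
        e_r = int(rng.integers(9, 60))
        ov_l = int(rng.integers(2, 26))
        ov_r = int(rng.integers(2, 26))
        icr_l = e_l + d + ov_l
        icr_r = e_r + d + ov_r
        if not (85 <= icr_l + icr_r <= 130) or min(icr_l, icr_r) < 24:
            continue
        if not (1 <= ov_l < c and 1 <= ov_r < c):
            continue
        start_n = _BASES[rng.integers(0, 4)]
        junction = revcomp_str(start_n + "TT")
        bp = ElementBlueprint(
            seed=seed,
            lE_len=e_l,
            lITR_div_len=d,
            lITR_cons_len=c,
            rE_len=e_r,
            junction=junction,
            icr_lens=(icr_l, icr_r),
            div_identity=float(rng.uniform(0.6, 0.85)),
            orf_overlap=bool(rng.random() < 0.5) if orf_overlap is None else orf_overlap,
            total_size=int(rng.integers(3974, 6284)),
        )
        try:
            bp.validate()
        except BlueprintError:
            continue
        return bp
    raise GenerationError(f"could not draw a valid blueprint for seed {seed}")


@dataclass
class ElementTruth:
    """Ground-truth annotation of a generated element (element coordinates)."""

    size: int
    start_tri: str
    end_tri: str
    junction: str
    lE_len: int
    rE_len: int
    div_len: int
    cons_len: int
    icr_lens: tuple[int, int]
    licr_span: tuple[int, int]
    ricr_span: tuple[int, int]
    yr_span: tuple[int, int]
    rt_span: tuple[int, int]
    mt_span: tuple[int, int]
    orf_overlap: bool
    boundary_motif_len: int
    safe_insert_pos: int          # inside the 3' stuffer; nesting-safe
    left_flank_forbidden: str     # base the 5' neighbour must NOT be
    right_flank_forbidden: str


def _enforce_pairing(
    lter: list[str],
    rter: list[str],
    bp: ElementBlueprint,
    rng: np.random.Generator,
) -> None:
    """Impose the inter-terminus complementarity pattern column by column.

    Column k counts outward from the conserved block; the left partner is
    lter[a-1-k], the right partner rter[c+k]. Divergent columns follow the
    blueprint identity with the outermost column complementary and the
    innermost mismatching (so the conserved block cannot extend); extension
    columns never match.
    """
    e_l, d, c = bp.lE_len, bp.lITR_div_len, bp.lITR_cons_len
    a = e_l + d
    b = d + bp.rE_len
    jlen = len(bp.junction)
    forced_left = {i for i in range(jlen)}            # lter[:jlen] carries rc(junction)
    forced_right = {len(rter) - 1 - i for i in range(jlen)}
    n_mismatch = max(1, round((1.0 - bp.div_identity) * d))
    interior = list(range(1, d - 1))
    extra = rng.choice(interior, size=min(len(interior), n_mismatch - 1), replace=False) if n_mismatch > 1 and interior else []
    mismatch_cols = {0} | {int(k) for k in extra}
    for k in range(min(a, b)):
        li = a - 1 - k
        ri = c + k
        want_match = (k < d) and (k not in mismatch_cols) if k != d - 1 else True
        if k >= d:
            want_match = False
        is_match = lter[li] == _COMP[rter[ri]]
        if is_match == want_match:
            continue
        if ri not in forced_right:
            rter[ri] = _COMP[lter[li]] if want_match else _pick_base(rng, {_COMP[lter[li]]})
        elif li not in forced_left:
            lter[li] = _COMP[rter[ri]] if want_match else _pick_base(rng, {_COMP[rter[ri]]})
        else:
            raise BlueprintError(
                "junction-forced terminal bases are incompatible with the "
                "extension/divergent pairing pattern"
            )


def _build_element(
    bp: ElementBlueprint, rng: np.random.Generator, consensi: dict[str, str]
) -> tuple[str, ElementTruth]:
    bp.validate()
    e_l, d, c, e_r = bp.lE_len, bp.lITR_div_len, bp.lITR_cons_len, bp.rE_len
    icr_l, icr_r = bp.icr_lens
    jlen = len(bp.junction)
    ov_l, ov_r = bp.overlap_into_cons

    cons_l = _rand_nt(rng, c)
    # keep the right-ICR match from extending into the right terminus
    if ov_r < c and cons_l[ov_r] == _COMP[cons_l[c - 1]]:
        cons_l[ov_r] = _pick_base(rng, {_COMP[cons_l[c - 1]]})
    lter = _rand_nt(rng, e_l + d) + cons_l
    lter[:jlen] = list(revcomp_str(bp.junction))
    cons_r = list(revcomp_str("".join(cons_l)))
    div_r = [_COMP[lter[e_l + d - 1 - k]] for k in range(d)]
    rter = cons_r + div_r + _rand_nt(rng, e_r)
    rter[-jlen:] = list(revcomp_str(bp.junction))
    _enforce_pairing(lter, rter, bp, rng)

    # domain cassettes (amino-acid level mutation, then back-translation)
    keep: dict[str, set[int]] = {k: set() for k in ("RT", "YR", "MT")}
    if bp.preserve_motifs:
        import re

        m = re.search(r"Y[LI]DD", consensi["RT"])
        if m:
            keep["RT"] = set(range(m.start(), m.end()))
        p = consensi["YR"].find("HSTR")
        if p >= 0:
            keep["YR"] = set(range(p, p + 4))
    cassette = {
        k: back_translate(mutate_aa(consensi[k], getattr(bp, f"{k.lower()}_id"), rng, keep[k]), rng)
        for k in ("YR", "RT", "MT")
    }

    licr = revcomp_str("".join(lter[:icr_l]))
    ricr = revcomp_str("".join(rter[-icr_r:]))
    assert licr[-jlen:] == bp.junction and ricr[:jlen] == bp.junction
    icr_region = licr + ricr[jlen:]

    orf_seg = (_STOP_BLOCK + _dual_frame_stopfree(1280, rng) + _STOP_BLOCK) if bp.orf_overlap else ""
    fixed = (
        len(lter) + len(rter) + len(icr_region) + len(orf_seg)
        + sum(len(v) for v in cassette.values())
    )
    budget = bp.total_size - fixed
    if budget < 90:
        raise BlueprintError(
            f"total_size {bp.total_size} too small for the requested architecture"
        )
    n_gag = int(budget * 0.4)
    n_rh = int(budget * 0.4)
    n_post = budget - n_gag - n_rh
    gag = list(_stuffer(n_gag, rng))
    rh = _stuffer(n_rh, rng)
    post = list(_stuffer(n_post, rng))
    # single-base disambiguation of repeat boundaries
    gag[0] = _pick_base(rng, {_COMP[cons_l[ov_r - 1]]})
    post[-1] = _pick_base(rng, {_COMP[cons_l[ov_l]]})

    parts = [
        "".join(lter),
        "".join(gag),
        cassette["YR"],
        cassette["RT"],
        rh[: n_rh // 2],
        orf_seg,
        rh[n_rh // 2 :],
        cassette["MT"],
        "".join(post),
        icr_region,
        "".join(rter),
    ]
    pos = np.cumsum([0] + [len(p) for p in parts])
    element = "".join(parts)
    assert len(element) == bp.total_size
    truth = ElementTruth(
        size=bp.total_size,
        start_tri=element[:3],
        end_tri=element[-3:],
        junction=bp.junction,
        lE_len=e_l,
        rE_len=e_r,
        div_len=d,
        cons_len=c,
        icr_lens=(icr_l, icr_r),
        licr_span=(int(pos[9]), int(pos[9]) + icr_l),
        ricr_span=(int(pos[9]) + icr_l - jlen, int(pos[10])),
        yr_span=(int(pos[2]), int(pos[3])),
        rt_span=(int(pos[3]), int(pos[4])),
        mt_span=(int(pos[7]), int(pos[8])),
        orf_overlap=bp.orf_overlap,
        boundary_motif_len=min(ov_l, ov_r),
        safe_insert_pos=int(pos[8]) + n_post // 2,
        left_flank_forbidden=_COMP[ricr[jlen]],
        right_flank_forbidden=_COMP[licr[icr_l - jlen - 1]],
    )
    return element, truth


def embed_with_flanks(
    element: str,
    truth: ElementTruth,
    rng: np.random.Generator,
    flank: int = 150,
    seq_id: str = "element",
) -> NucSequence:
    """Element with random flanks whose boundary bases cannot extend a repeat."""
    left = _rand_nt(rng, flank)
    right = _rand_nt(rng, flank)
    left[-1] = _pick_base(rng, {truth.left_flank_forbidden})
    right[0] = _pick_base(rng, {truth.right_flank_forbidden})
    return NucSequence(seq_id, "".join(left) + element + "".join(right))


def make_element(
    bp: ElementBlueprint,
    consensi: dict[str, str] | None = None,
    verify: bool = True,
    max_attempts: int = 30,
) -> tuple[NucSequence, ElementTruth]:
    """Emit one element; deterministic in the blueprint (including its seed).

    With ``verify`` (the default), the element is round-tripped through the
    annotation module on a padded copy and re-drawn (from a derived stream)
    until every planted repeat length is the unique recoverable one.
    """
    if consensi is None:
        consensi = {k: resources.domain_consensus(k) for k in ("RT", "YR", "MT")}
    last = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([bp.seed, 7, attempt])
        try:
            element, truth = _build_element(bp, rng, consensi)
        except BlueprintError:
            raise
        if not verify:
            return NucSequence(f"el{bp.seed}", element), truth
        padded = embed_with_flanks(element, truth, rng, seq_id=f"el{bp.seed}")
        if _matches_truth(padded, bp, truth):
            return NucSequence(f"el{bp.seed}", element), truth
        last = truth
    raise GenerationError(
        f"could not build an unambiguous element for seed {bp.seed} "
        f"after {max_attempts} attempts (last truth: {last})"
    )


def _matches_truth(padded: NucSequence, bp: ElementBlueprint, truth: ElementTruth) -> bool:
    rec, ann, orf = annotate_element(padded, search_window=600)
    if ann is None:
        return False
    return (
        ann.size == truth.size
        and ann.start_tri == truth.start_tri
        and ann.end_tri == truth.end_tri
        and ann.circular_junction == truth.junction
        and ann.lE_len == truth.lE_len
        and ann.rE_len == truth.rE_len
        and ann.lITR_div_len == truth.div_len
        and ann.lITR_cons_len == truth.cons_len
        and (len(ann.lICR_span), len(ann.rICR_span)) == truth.icr_lens
        and orf is not None
        and orf.long_overlap == truth.orf_overlap
    )


# ---------------------------------------------------------------------------
# Decoys


def make_decoys(
    kind: str, seed: int, consensi: dict[str, str] | None = None
) -> NucSequence:
    """Sequences the pipeline must reject (or, for PAT, accept but label PAT).

    * ``ngaro_order``: YR + RT cassettes with no MT, the architecture of
      Ngaro-like elements.
    * ``missing_mt_relic``: a lone RT cassette degraded by 5 frameshifts.
    * ``pat_like``: a full YR-RT-MT cassette built from the PAT paralog
      consensus, bounded by split direct repeats instead of ITR/ICR
      structure; detectable, separable only by superfamily classification.
    """
    if consensi is None:
        consensi = {k: resources.domain_consensus(k) for k in ("RT", "YR", "MT")}
    rng = np.random.default_rng([seed, 13])
    if kind == "ngaro_order":
        yr = back_translate(mutate_aa(consensi["YR"], 0.9, rng), rng)
        rt = back_translate(mutate_aa(consensi["RT"], 0.9, rng), rng)
        return NucSequence(
            f"ngaro{seed}",
            _stuffer(300, rng) + yr + _stuffer(200, rng) + rt + _stuffer(300, rng),
        )
    if kind == "missing_mt_relic":
        rt = back_translate(mutate_aa(consensi["RT"], 0.9, rng), rng)
        rt_l = list(rt)
        for pos in sorted(rng.choice(len(rt_l) - 10, size=5, replace=False), reverse=True):
            if rng.random() < 0.5:
                rt_l.insert(int(pos), _BASES[rng.integers(0, 4)])
            else:
                del rt_l[int(pos)]
        return NucSequence(
            f"relic{seed}", _stuffer(300, rng) + "".join(rt_l) + _stuffer(300, rng)
        )
    if kind == "pat_like":
        pat = {k: resources.pat_consensus(k) for k in ("RT", "YR", "MT")}
        yr = back_translate(mutate_aa(pat["YR"], 0.95, rng), rng)
        rt = back_translate(mutate_aa(pat["RT"], 0.95, rng), rng)
        mt = back_translate(mutate_aa(pat["MT"], 0.95, rng), rng)
        sdr_a = "".join(_rand_nt(rng, 60))
        sdr_b = "".join(_rand_nt(rng, 40))
        core = (
            _stuffer(250, rng) + yr + rt + _stuffer(150, rng) + mt + _stuffer(150, rng)
        )
        return NucSequence(f"pat{seed}", sdr_a + sdr_b + core + sdr_a + sdr_b)
    raise ValueError(f"unknown decoy kind {kind!r}")


# ---------------------------------------------------------------------------
# Genome planting


@dataclass
class PlantingRecord:
    element_id: str
    status: str        # intact | relic | nested-parent | nested-child |
                       # ngaro_decoy | pat_decoy
    start: int         # final genome coordinates after all insertions
    end: int
    strand: str
    family_id: str = ""
    truth: ElementTruth | None = None


@dataclass
class PlantingManifest:
    genome_id: str
    seed: int
    records: list[PlantingRecord] = field(default_factory=list)

    def by_status(self, *statuses: str) -> list[PlantingRecord]:
        return [r for r in self.records if r.status in statuses]


@dataclass(frozen=True)
class PlantingSpec:
    status: str
    position: int                       # site in background coordinates
    strand: str = "+"
    blueprint: ElementBlueprint | None = None
    decoy_seed: int = 0
    family_id: str = ""
    child: "PlantingSpec | None" = None  # for nested-parent


def plant_elements(
    background_len: int,
    gc: float,
    specs: list[PlantingSpec],
    seed: int,
    genome_id: str = "synth",
    consensi: dict[str, str] | None = None,
) -> tuple[NucSequence, PlantingManifest]:
    """Insert elements/decoys into an i.i.d. background of the given GC.

    Insertion positions refer to the original background; they are applied in
    ascending order with coordinate shifts tracked, and the manifest records
    final coordinates. Non-nested insertions must not share a site.
    """
    if consensi is None:
        consensi = {k: resources.domain_consensus(k) for k in ("RT", "YR", "MT")}
    rng = np.random.default_rng([seed, 29])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bg = rng.choice(list(_BASES), size=background_len, p=p)
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise ValueError("non-nested insertions must use distinct sites")
    ordered = sorted(specs, key=lambda s: s.position)
    pieces: list[str] = []
    records: list[PlantingRecord] = []
    cursor = 0
    offset = 0
    for k, spec in enumerate(ordered):
        if not (0 <= spec.position <= background_len):
            raise ValueError("insertion site outside background")
        pieces.append("".join(bg[cursor : spec.position]))
        offset += spec.position - cursor
        cursor = spec.position
        ins, recs = _materialize(spec, k, rng, consensi)
        for r in recs:
            r.start += offset
            r.end += offset
        records.extend(recs)
        pieces.append(ins)
        offset += len(ins)
    pieces.append("".join(bg[cursor:]))
    genome_str = list("".join(pieces))
    # boundary disambiguation for annotatable plantings
    for r in records:
        if r.truth is None:
            continue
        forb_l, forb_r = r.truth.left_flank_forbidden, r.truth.right_flank_forbidden
        if r.strand == "-":
            forb_l, forb_r = _COMP[forb_r], _COMP[forb_l]
        if r.start > 0 and genome_str[r.start - 1] == forb_l:
            genome_str[r.start - 1] = _pick_base(rng, {forb_l})
        if r.end < len(genome_str) and genome_str[r.end] == forb_r:
            genome_str[r.end] = _pick_base(rng, {forb_r})
    genome = NucSequence(genome_id, "".join(genome_str))
    manifest = PlantingManifest(genome_id=genome_id, seed=seed, records=records)
    return genome, manifest


def _materialize(
    spec: PlantingSpec, k: int, rng: np.random.Generator, consensi: dict[str, str]
) -> tuple[str, list[PlantingRecord]]:
    if spec.status in ("ngaro_decoy", "pat_decoy", "relic"):
        kind = {
            "ngaro_decoy": "ngaro_order",
            "pat_decoy": "pat_like",
            "relic": "missing_mt_relic",
        }[spec.status]
        seq = make_decoys(kind, spec.decoy_seed, consensi)
        s = seq.residues if spec.strand == "+" else revcomp_str(seq.residues)
        return s, [
            PlantingRecord(seq.id, spec.status, 0, len(s), spec.strand, spec.family_id)
        ]
    if spec.status == "intact":
        el, truth = make_element(spec.blueprint, consensi)
        s = el.residues if spec.strand == "+" else revcomp_str(el.residues)
        return s, [
            PlantingRecord(el.id, "intact", 0, len(s), spec.strand, spec.family_id, truth)
        ]
    if spec.status == "nested-parent":
        parent, pt = make_element(spec.blueprint, consensi)
        child_spec = spec.child
        child, ct = make_element(child_spec.blueprint, consensi)
        cseq = child.residues if child_spec.strand == spec.strand else revcomp_str(child.residues)
        at = pt.safe_insert_pos
        combined = parent.residues[:at] + cseq + parent.residues[at:]
        if spec.strand == "-":
            combined = revcomp_str(combined)
            c_start = len(combined) - (at + len(cseq))
        else:
            c_start = at
        recs = [
            PlantingRecord(parent.id, "nested-parent", 0, len(combined), spec.strand, spec.family_id, None),
            PlantingRecord(child.id, "nested-child", c_start, c_start + len(cseq),
                           child_spec.strand if spec.strand == "+" else ("-" if child_spec.strand == "+" else "+"),
                           child_spec.family_id, None),
        ]
        return combined, recs
    raise ValueError(f"unknown planting status {spec.status!r}")


# ---------------------------------------------------------------------------
# RT-fragment families


def make_family_set(
    n_families: int,
    copies_per_family: int,
    within_id: float,
    between_id: float,
    seed: int,
    fragment_len: int = 360,
) -> tuple[list[NucSequence], list[set[str]]]:
    """Nucleotide RT-fragment families with a known partition.

    Family ancestors diverge from a common root to the between-family
    identity; copies diverge from their ancestor to the within-family
    identity. Requires within_id > between_id.
    """
    if not within_id > between_id:
        raise ValueError("within-family identity must exceed between-family identity")
    rng = np.random.default_rng([seed, 41])
    root = "".join(_rand_nt(rng, fragment_len))
    fragments: list[NucSequence] = []
    truth: list[set[str]] = []
    for f in range(n_families):
        anc = mutate_nt(root, between_id, rng)
        fam = set()
        for c in range(copies_per_family):
            frag_id = f"fam{f}_copy{c}"
            fragments.append(NucSequence(frag_id, mutate_nt(anc, within_id, rng)))
            fam.add(frag_id)
        truth.append(fam)
    return fragments, truth


# ---------------------------------------------------------------------------
# Benchmark genome


def demo_specs(seed: int, background_len: int) -> list[PlantingSpec]:
    """The standard benchmark layout: 10 intact elements (3 families), 3
    Ngaro-order decoys, 2 MT-less relics and one nested pair."""
    n_sites = 16
    gap = background_len // (n_sites + 1)
    sites = [gap * (i + 1) for i in range(n_sites)]
    specs: list[PlantingSpec] = []
    for i in range(10):
        specs.append(
            PlantingSpec(
                status="intact",
                position=sites[i],
                strand="+" if i % 3 else "-",
                blueprint=draw_blueprint(seed * 1000 + i),
                family_id=f"fam{i % 3}",
            )
        )
    for i in range(3):
        specs.append(
            PlantingSpec(status="ngaro_decoy", position=sites[10 + i], decoy_seed=seed * 100 + i)
        )
    for i in range(2):
        specs.append(
            PlantingSpec(status="relic", position=sites[13 + i], decoy_seed=seed * 100 + 50 + i)
        )
    specs.append(
        PlantingSpec(
            status="nested-parent",
            position=sites[15],
            blueprint=draw_blueprint(seed * 1000 + 90),
            family_id="fam0",
            child=PlantingSpec(
                status="intact",
                position=0,
                blueprint=draw_blueprint(seed * 1000 + 91),
                family_id="fam1",
            ),
        )
    )
    return specs


def demo_genome(
    seed: int, background_len: int = 2_000_000, gc: float = 0.42
) -> tuple[NucSequence, PlantingManifest]:
    return plant_elements(background_len, gc, demo_specs(seed, background_len), seed)
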
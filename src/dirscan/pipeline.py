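"""Six-step detection of DIRS1-like elements by domain architecture.

The pipeline anchors on reverse-transcriptase (RT) profile hits, excises each
hit with 5-kb flanks, searches the resulting ~10-kb window for tyrosine
recombinase (YR) and methyltransferase (MT) matches, and accepts a window
only when one strand carries all three domains in the order YR < RT < MT
along the element's own 5'->3' direction. Windows sharing hits are merged;
a merged locus with two or more occurrences of any domain is counted as a
single "complex" copy (nested or rearranged elements).

Rejection at the order or orientation check is what discriminates other
tyrosine-recombinase retrotransposons (Ngaro-like architectures, which also
lack MT; PAT-like elements pass this filter and are only separable at the
superfamily-classification stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .config import Config, DEFAULT_CONFIG
from .profiles import DomainHit, DomainProfile, scan_domain
from .seqio import Interval, NucSequence

ACCEPT = "accept"
REJECT_MISSING = "reject_missing_domain"
REJECT_ORDER = "reject_order"
REJECT_ORIENTATION = "reject_orientation"


@dataclass
class CandidateLocus:
    window: Interval
    anchor: DomainHit
    hits: list[DomainHit] = field(default_factory=list)

    def hits_of(self, kind: str, strand: str | None = None) -> list[DomainHit]:
        return [
            h
            for h in self.hits
            if h.domain_kind == kind and (strand is None or h.strand == strand)
        ]


@dataclass
class ElementCopy:
    locus: CandidateLocus
    strand: str
    ordered_domains: tuple[DomainHit, DomainHit, DomainHit]  # (YR, RT, MT)
    complex_flag: bool
    copy_id: str

    def rough_span(self, seq_len: int, margin: int = 1500) -> Interval:
        """Outermost domain hit extended by ``margin`` nt on both sides."""
        start = min(h.location.start for h in self.ordered_domains)
        end = max(h.location.end for h in self.ordered_domains)
        return Interval(
            self.ordered_domains[0].location.seq_id,
            max(0, start - margin),
            min(seq_len, end + margin),
            self.strand,
        )


def extract_windows(
    rt_hits: list[DomainHit], genome: NucSequence, flank: int = 5000
) -> list[CandidateLocus]:
    """One candidate window per RT anchor, clipped at sequence boundaries."""
    loci = []
    for h in rt_hits:
        start = max(0, h.location.start - flank)
        end = min(len(genome), h.location.end + flank)
        loci.append(
            CandidateLocus(
                window=Interval(genome.id, start, end, "+"),
                anchor=h,
                hits=[h],
            )
        )
    return loci


def find_secondary_domains(
    locus: CandidateLocus,
    genome: NucSequence,
    yr_profile: DomainProfile,
    mt_profile: DomainProfile,
    evalue_cutoff: float = 0.01,
    merge_distance: int = 300,
) -> CandidateLocus:
    """Search YR and MT inside the window only; E-values use the window length."""
    sub = genome.subseq(locus.window.start, locus.window.end, seq_id="w")
    extra: list[DomainHit] = []
    for prof in (yr_profile, mt_profile):
        extra.extend(
            scan_domain(
                sub,
                prof,
                evalue_cutoff=evalue_cutoff,
                merge_distance=merge_distance,
                offset=locus.window.start,
                seq_id=genome.id,
            )
        )
    locus.hits = [locus.anchor] + extra
    return locus


def _ordered_ok(yr: DomainHit, rt: DomainHit, mt: DomainHit, strand: str) -> bool:
    if strand == "+":
        return yr.location.start < rt.location.start < mt.location.start
    return yr.location.start > rt.location.start > mt.location.start


def check_architecture(locus: CandidateLocus) -> str:
    """Classify a window by domain presence, co-orientation and order."""
    kinds = {h.domain_kind for h in locus.hits}
    if kinds != {"RT", "MT", "YR"}:
        return REJECT_MISSING
    strands = [
        s
        for s in "+-"
        if all(locus.hits_of(k, s) for k in ("RT", "MT", "YR"))
    ]
    if not strands:
        return REJECT_ORIENTATION
    # evaluate the anchor strand first, then any other qualifying strand
    strands.sort(key=lambda s: s != locus.anchor.strand)
    for s in strands:
        yr = min(locus.hits_of("YR", s), key=lambda h: h.evalue)
        rt = min(locus.hits_of("RT", s), key=lambda h: h.evalue)
        mt = min(locus.hits_of("MT", s), key=lambda h: h.evalue)
        if _ordered_ok(yr, rt, mt, s):
            return ACCEPT
    # a window holding several occurrences of a domain (nested or rearranged
    # elements) is kept if ANY one-hit-per-domain selection is ordered; such
    # loci are resolved to a single complex copy downstream
    for s in strands:
        yrs, rts, mts = (locus.hits_of(k, s) for k in ("YR", "RT", "MT"))
        if max(len(yrs), len(rts), len(mts)) < 2:
            continue
        for yr in yrs:
            for rt in rts:
                for mt in mts:
                    if _ordered_ok(yr, rt, mt, s):
                        return ACCEPT
    return REJECT_ORDER


def resolve_multidomain(loci: list[CandidateLocus]) -> list[ElementCopy]:
    """Merge windows sharing hits; each merged locus yields exactly one copy.

    A locus (merged or not) whose window holds >= 2 occurrences of any domain
    is flagged complex and still counted once, which is how nested or
    tandem-rearranged elements enter the copy number.
    """
    if not loci:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(loci)))
    key_map: dict[tuple, list[int]] = {}
    for idx, locus in enumerate(loci):
        for h in locus.hits:
            key_map.setdefault(h.key(), []).append(idx)
    for indices in key_map.values():
        for a, b in zip(indices, indices[1:]):
            g.add_edge(a, b)
    copies: list[ElementCopy] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        hits: dict[tuple, DomainHit] = {}
        for i in members:
            for h in loci[i].hits:
                hits[h.key()] = h
        merged_hits = sorted(hits.values(), key=lambda h: h.location.start)
        anchor = min(
            (loci[i].anchor for i in members), key=lambda h: (h.evalue, h.location.start)
        )
        strand = anchor.strand
        window = Interval(
            loci[members[0]].window.seq_id,
            min(loci[i].window.start for i in members),
            max(loci[i].window.end for i in members),
            "+",
        )
        locus = CandidateLocus(window=window, anchor=anchor, hits=merged_hits)
        counts = {
            k: len(locus.hits_of(k, strand)) for k in ("RT", "MT", "YR")
        }
        complex_flag = any(c >= 2 for c in counts.values())
        picked = {}
        for kind in ("YR", "RT", "MT"):
            cands = locus.hits_of(kind, strand) or locus.hits_of(kind)
            picked[kind] = min(cands, key=lambda h: h.evalue)
        copy_id = f"{window.seq_id}:{window.start}-{window.end}:{strand}"
        copies.append(
            ElementCopy(
                locus=locus,
                strand=strand,
                ordered_domains=(picked["YR"], picked["RT"], picked["MT"]),
                complex_flag=complex_flag,
                copy_id=copy_id,
            )
        )
    copies.sort(key=lambda c: c.locus.window.start)
    return copies


def run_pipeline(
    genome: NucSequence,
    profiles: dict[str, DomainProfile],
    config: Config = DEFAULT_CONFIG,
) -> tuple[list[ElementCopy], dict]:
    """Full six-step detection on one sequence; returns copies and a step log."""
    rt_hits = scan_domain(
        genome,
        profiles["RT"],
        evalue_cutoff=config.evalue_cutoff,
        merge_distance=config.merge_distance,
    )
    loci = extract_windows(rt_hits, genome, flank=config.flank)
    for locus in loci:
        find_secondary_domains(
            locus,
            genome,
            profiles["YR"],
            profiles["MT"],
            evalue_cutoff=config.evalue_cutoff,
            merge_distance=config.merge_distance,
        )
    with_yr = sum(1 for l in loci if l.hits_of("YR"))
    with_all = sum(1 for l in loci if l.hits_of("YR") and l.hits_of("MT"))
    verdicts = {id(l): check_architecture(l) for l in loci}
    accepted = [l for l in loci if verdicts[id(l)] == ACCEPT]
    copies = resolve_multidomain(accepted)
    summary = {
        "seq_id": genome.id,
        "seq_len": len(genome),
        "step1_rt_hits": len(rt_hits),
        "step2_windows": len(loci),
        "step3_with_yr": with_yr,
        "step4_with_all_domains": with_all,
        "step5_architecture_ok": len(accepted),
        "step6_copies": len(copies),
        "rejected_missing_domain": sum(
            1 for v in verdicts.values() if v == REJECT_MISSING
        ),
        "rejected_order": sum(1 for v in verdicts.values() if v == REJECT_ORDER),
        "rejected_orientation": sum(
            1 for v in verdicts.values() if v == REJECT_ORIENTATION
        ),
        "complex_copies": sum(1 for c in copies if c.complex_flag),
    }
    return copies, summary
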
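"""Published-table fixtures and the summary statistics reported over them."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as ir

import numpy as np

from .annotate import Table3Record
from .clustering import FamilyPartition
from .seqio import read_tsv


@dataclass(frozen=True)
class Table2Row:
    higher_taxon: str
    species: str
    copy_number: int
    family_number: int
    pat_family_count: int
    min_family_size: int | None
    max_family_size: int | None

    def __post_init__(self):
        if self.copy_number < self.family_number or self.family_number < 1:
            raise ValueError(
                f"{self.species}: copy number must be >= family number >= 1"
            )


@dataclass(frozen=True)
class Table3Row:
    element: str
    host: str
    taxon: str
    size: int
    start_tri: str
    end_tri: str
    junction: str
    long_orf_overlap: str
    lE: str
    div_itr: str
    cons_itr: str
    rE: str
    icr_sizes: str


def load_table2(path=None) -> list[Table2Row]:
    from . import resources

    src = path if path is not None else resources.table2_path()
    with ir.as_file(src) if path is None else _noop(src) as p:
        header, rows = read_tsv(p)
    out = []
    for r in rows:
        out.append(
            Table2Row(
                higher_taxon=r[0],
                species=r[1],
                copy_number=int(r[2]),
                family_number=int(r[3]),
                pat_family_count=int(r[4]),
                min_family_size=int(r[5]) if r[5] else None,
                max_family_size=int(r[6]) if r[6] else None,
            )
        )
    return out


def load_table3(path=None) -> list[Table3Row]:
    from . import resources

    src = path if path is not None else resources.table3_path()
    with ir.as_file(src) if path is None else _noop(src) as p:
        header, rows = read_tsv(p)
    return [
        Table3Row(
            element=r[0], host=r[1], taxon=r[2], size=int(r[3]),
            start_tri=r[4], end_tri=r[5], junction=r[6], long_orf_overlap=r[7],
            lE=r[8], div_itr=r[9], cons_itr=r[10], rE=r[11], icr_sizes=r[12],
        )
        for r in rows
    ]


class _noop:
    def __init__(self, v):
        self.v = v

    def __enter__(self):
        return self.v

    def __exit__(self, *a):
        return False


def table2_summary(rows: list[Table2Row]) -> dict:
    """Totals over the per-species detection table."""
    return {
        "total_copies": sum(r.copy_number for r in rows),
        "species_count": len(rows),
        "species_ge_100_copies": sum(1 for r in rows if r.copy_number >= 100),
        "species_10_to_60_copies": sum(1 for r in rows if 10 <= r.copy_number <= 60),
        "total_families": sum(r.family_number for r in rows),
    }


def table3_summary(rows: list[Table3Row]) -> dict:
    """Size statistics and feature counts over the per-element table."""
    if not rows:
        return {
            "n": 0, "size_min": 0, "size_max": 0, "size_mean": 0,
            "long_orf_overlap_yes": 0, "junction_length_histogram": {},
        }
    sizes = [r.size for r in rows]
    hist: dict[int, int] = {}
    for r in rows:
        if r.junction != "nd":
            hist[len(r.junction)] = hist.get(len(r.junction), 0) + 1
    return {
        "n": len(rows),
        "size_min": min(sizes),
        "size_max": max(sizes),
        "size_mean": round(sum(sizes) / len(sizes)),
        "long_orf_overlap_yes": sum(1 for r in rows if r.long_orf_overlap == "Yes"),
        "junction_length_histogram": hist,
    }


def family_size_report(partition: FamilyPartition) -> dict:
    """Family sizes in decreasing order with dispersion statistics."""
    if not partition.families:
        raise ValueError("empty partition")
    sizes = sorted((len(f) for f in partition.families), reverse=True)
    total = sum(sizes)
    return {
        "sizes": sizes,
        "mean": float(np.mean(sizes)),
        "std": float(np.std(sizes)),
        "top1_fraction": sizes[0] / total,
        "total_copies": total,
    }


def records_to_table3_rows(records: list[Table3Record], host: str = "synthetic",
                           taxon: str = "synthetic") -> list[Table3Row]:
    return [
        Table3Row(
            element=rec.element, host=host, taxon=taxon,
            size=rec.size if rec.size is not None else 0,
            start_tri=rec.start_tri, end_tri=rec.end_tri,
            junction=rec.circular_junction, long_orf_overlap=rec.long_orf_overlap,
            lE=rec.lE, div_itr=rec.divergent_itr, cons_itr=rec.conserved_itr,
            rE=rec.rE, icr_sizes=rec.icr_sizes,
        )
        for rec in records
    ]
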
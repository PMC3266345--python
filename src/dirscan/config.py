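"""Declarative configuration for every tunable threshold in the toolkit."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    # profile search
    evalue_cutoff: float = 0.01
    gap_open: float = 11.0          # bits, affine open penalty for protein search
    gap_ext: float = 1.0
    merge_distance: int = 300       # nt; same-domain hit merging on one strand
    calib_n_seqs: int = 300
    calib_seq_len: int = 400
    # structure pipeline
    flank: int = 5000               # nt added on each side of an RT anchor
    boundary_margin: int = 2500     # rough element boundary = outer hits +/- this;
                                    # must exceed the largest distance from a domain
                                    # hit to its element terminus (GAG region ~2 kb)
    # nucleotide similarity (family clustering, termini alignment)
    nt_match: float = 1.0
    nt_mismatch: float = -2.0
    nt_gap_open: float = 5.0
    nt_gap_ext: float = 2.0
    # family clustering
    inflation: float = 1.2
    edge_weight_cap: float = 200.0
    mcl_max_iter: int = 200
    mcl_tol: float = 1e-6
    # superfamily classification
    classify_evalue: float = 1e-20
    classify_separation: float = 1e10   # multiplicative E-value separation
    # annotation
    termini_window: int = 600
    itr_min_len: int = 20
    itr_min_identity: float = 0.60
    icr_min_identity: float = 0.90
    min_orf: int = 600              # nt; ORFs considered for overlap calls
    min_orf_overlap: int = 50       # nt; "long" overlap threshold
    # phylogeny
    gamma_alpha: float = 1.0
    gamma_categories: int = 4
    bootstrap_reps: int = 100

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CONFIG = Config()
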
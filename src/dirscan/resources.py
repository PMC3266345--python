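"""Packaged data: seed alignments, reference elements, published table fixtures.

The seed multiple alignments for the RT, YR and MT domains and the DIRS/PAT
reference element sequences are synthetic stand-ins generated by this package
(see scripts in the repository): they reproduce the published profile lengths
(RT 118, YR 282, MT 93 aligned positions) and carry the canonical catalytic
motifs (Y[LI]DD in RT, HSTR in YR), but are not the original curated
alignments. The two table fixtures transcribe the published per-species
detection results (32 species) and per-element annotations (28 elements).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as ir

import numpy as np

from .profiles import DomainProfile, build_profile, calibrate_profile
from .seqio import NucSequence, read_aligned_fasta, read_fasta

_CALIBRATION_SEEDS = {"RT": 101, "YR": 102, "MT": 103}

PROFILE_LENGTHS = {"RT": 118, "YR": 282, "MT": 93}


def _data_path(name: str):
    return ir.files("dirscan").joinpath("data", name)


@lru_cache(maxsize=None)
def seed_alignment(kind: str) -> tuple[tuple[str, str], ...]:
    with ir.as_file(_data_path(f"{kind.lower()}_seed.synthetic.afa")) as p:
        return tuple(read_aligned_fasta(p))


@lru_cache(maxsize=None)
def default_profile(kind: str, calibrated: bool = True) -> DomainProfile:
    """Profile built from the packaged seed alignment, optionally calibrated
    with the fixed per-domain seed (deterministic across runs)."""
    prof = build_profile(
        list(seed_alignment(kind)), kind, source_id=f"{kind.lower()}_seed.synthetic"
    )
    if calibrated:
        prof = calibrate_profile(prof, seed=_CALIBRATION_SEEDS[kind])
    return prof


def default_profiles() -> dict[str, DomainProfile]:
    return {k: default_profile(k) for k in ("RT", "YR", "MT")}


@lru_cache(maxsize=None)
def domain_consensus(kind: str) -> str:
    return default_profile(kind, calibrated=False).consensus


def pat_consensus(kind: str, seed: int = 777, identity: float = 0.55) -> str:
    """Deterministic diverged paralog of a domain consensus, emulating the
    corresponding domain of the PAT sister superfamily."""
    rng = np.random.default_rng([seed, ord(kind[0])])
    aa = list(domain_consensus(kind))
    n_mut = round((1.0 - identity) * len(aa))
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for i in rng.choice(len(aa), size=n_mut, replace=False):
        choices = [c for c in alphabet if c != aa[i]]
        aa[i] = choices[rng.integers(0, len(choices))]
    return "".join(aa)


@lru_cache(maxsize=None)
def reference_elements(superfamily: str) -> tuple[NucSequence, ...]:
    """Packaged DIRS-like or PAT-like reference element nucleotide sequences."""
    name = {"DIRS": "dirs_refs.synthetic.fasta", "PAT": "pat_refs.synthetic.fasta"}[
        superfamily
    ]
    with ir.as_file(_data_path(name)) as p:
        return tuple(read_fasta(p))


def table2_path():
    return _data_path("table2_species.tsv")


def table3_path():
    return _data_path("table3_elements.tsv")
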
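"""Regenerate the synthetic packaged data files under src/dirscan/data/.

The seed alignments and reference element sequences shipped with the package
are synthetic stand-ins with the documented domain profile lengths (RT 118,
YR 282, MT 93) and canonical catalytic motifs (Y[LI]DD in RT, HSTR in YR).
Running this script reproduces them byte-identically.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dirscan.seqio import NucSequence, write_fasta  # noqa: E402

AA20 = "ACDEFGHIKLMNPQRSTVWY"
OUT = Path(__file__).resolve().parents[1] / "src" / "dirscan" / "data"

DOMAINS = {
    "rt": (118, 1001, {55: "Y", 56: "L", 57: "D", 58: "D"}),
    "yr": (282, 1002, {140: "H", 141: "S", 142: "T", 143: "R"}),
    "mt": (93, 1003, {}),
}


def make_seed_alignment(name: str, length: int, seed: int, motif: dict[int, str], n_seqs: int = 8):
    rng = np.random.default_rng(seed)
    cons = [AA20[i] for i in rng.integers(0, 20, size=length)]
    for pos, aa in motif.items():
        cons[pos] = aa
    keep = set(motif)
    rows = []
    for k in range(n_seqs):
        row = list(cons)
        n_mut = round(0.10 * length)
        sites = [i for i in rng.choice(length, size=length, replace=False) if i not in keep][:n_mut]
        for i in sites:
            choices = [c for c in AA20 if c != row[i]]
            row[i] = choices[rng.integers(0, len(choices))]
        rows.append((f"{name}_seed_{k}", "".join(row)))
    path = OUT / f"{name}_seed.synthetic.afa"
    with open(path, "w") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")
    print("wrote", path)


def make_reference_sets():
    from dirscan import resources, synth

    dirs_cons = {k: resources.domain_consensus(k) for k in ("YR", "RT", "MT")}
    pat_cons = {k: resources.pat_consensus(k) for k in ("YR", "RT", "MT")}
    for label, cons, seed in (("dirs", dirs_cons, 2001), ("pat", pat_cons, 2002)):
        rng = np.random.default_rng(seed)
        seqs = []
        for k in range(3):
            nt = "".join(
                synth.back_translate(synth.mutate_aa(cons[d], 0.97, rng), rng)
                + "".join(synth._rand_nt(rng, 30))
                for d in ("YR", "RT", "MT")
            )
            seqs.append(NucSequence(f"{label}_ref_{k}_synthetic", nt))
        path = OUT / f"{label}_refs.synthetic.fasta"
        write_fasta(path, seqs)
        print("wrote", path)


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (length, seed, motif) in DOMAINS.items():
        make_seed_alignment(name, length, seed, motif)
    make_reference_sets()
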
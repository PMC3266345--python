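"""The synthetic-genome generator: determinism, planting fidelity, decoys."""

import numpy as np
import pytest

from dirscan import synth
from dirscan.seqio import revcomp_str
from dirscan.synth import (
    BlueprintError,
    ElementBlueprint,
    PlantingSpec,
    draw_blueprint,
    make_element,
    plant_elements,
)


def test_make_element_deterministic():
    bp = draw_blueprint(12)
    e1, t1 = make_element(bp)
    e2, t2 = make_element(bp)
    assert e1.residues == e2.residues
    assert t1 == t2


def test_blueprint_validation():
    with pytest.raises(BlueprintError):
        ElementBlueprint(seed=1, junction="AATT").validate()
    with pytest.raises(BlueprintError):
        ElementBlueprint(seed=1, lE_len=0, rE_len=0).validate()
    with pytest.raises(BlueprintError):
        # ICR shorter than extension + divergent part
        ElementBlueprint(seed=1, lE_len=30, lITR_div_len=20, icr_lens=(40, 44)).validate()
    with pytest.raises(BlueprintError):
        # total size cannot hold the cassettes
        make_element(ElementBlueprint(seed=1, total_size=1600), verify=False)


def test_element_repeat_relations():
    """Planted complementarities hold literally in the emitted sequence."""
    bp = draw_blueprint(33)
    el, t = make_element(bp)
    s = el.residues
    icr_l, icr_r = t.icr_lens
    licr = s[t.licr_span[0] : t.licr_span[1]]
    ricr = s[t.ricr_span[0] : t.ricr_span[1]]
    assert licr == revcomp_str(s[:icr_l])              # left ICR vs element start
    assert ricr == revcomp_str(s[-icr_r:])             # right ICR vs element end
    jlen = len(t.junction)
    assert licr[-jlen:] == ricr[:jlen] == t.junction   # overlap = junction
    assert s[:jlen] == revcomp_str(t.junction)         # integration-model termini
    # conserved ITR strictly reverse-complementary
    a = t.lE_len + t.div_len
    cons_l = s[a : a + t.cons_len]
    b = t.rE_len + t.div_len
    cons_r = s[len(s) - b - t.cons_len : len(s) - b]
    assert cons_r == revcomp_str(cons_l)


def test_background_gc_concentration():
    genome, _ = plant_elements(200_000, 0.5, [], seed=4)
    gc = sum(1 for c in genome.residues if c in "GC") / len(genome)
    assert abs(gc - 0.5) < 0.01
    genome2, _ = plant_elements(100_000, 0.3, [], seed=4)
    gc2 = sum(1 for c in genome2.residues if c in "GC") / len(genome2)
    assert abs(gc2 - 0.3) < 0.02


def test_manifest_coordinates_match_sequences():
    """Re-extracting each planted interval reproduces the element sequence."""
    bps = [draw_blueprint(100 + i) for i in range(3)]
    specs = [
        PlantingSpec(status="intact", position=20_000, blueprint=bps[0], strand="+"),
        PlantingSpec(status="intact", position=60_000, blueprint=bps[1], strand="-"),
        PlantingSpec(status="intact", position=90_000, blueprint=bps[2], strand="+"),
    ]
    genome, manifest = plant_elements(120_000, 0.42, specs, seed=8)
    assert len(manifest.records) == 3
    for rec, bp in zip(manifest.records, bps):
        el, _ = make_element(bp)
        got = genome.residues[rec.start : rec.end]
        expect = el.residues if rec.strand == "+" else revcomp_str(el.residues)
        assert got == expect


def test_nested_child_strictly_inside_parent():
    spec = PlantingSpec(
        status="nested-parent", position=30_000, blueprint=draw_blueprint(200),
        child=PlantingSpec(status="intact", position=0, blueprint=draw_blueprint(201)),
    )
    genome, manifest = plant_elements(80_000, 0.42, [spec], seed=9)
    parent = next(r for r in manifest.records if r.status == "nested-parent")
    child = next(r for r in manifest.records if r.status == "nested-child")
    assert parent.start < child.start < child.end < parent.end


def test_overlapping_sites_rejected():
    bp = draw_blueprint(1)
    specs = [
        PlantingSpec(status="intact", position=1000, blueprint=bp),
        PlantingSpec(status="intact", position=1000, blueprint=bp),
    ]
    with pytest.raises(ValueError):
        plant_elements(10_000, 0.5, specs, seed=1)


def test_family_set_edges():
    frags, truth = synth.make_family_set(1, 4, 0.9, 0.6, seed=2)
    assert len(truth) == 1 and len(frags) == 4
    frags, truth = synth.make_family_set(4, 1, 0.9, 0.6, seed=2)
    assert all(len(t) == 1 for t in truth)
    with pytest.raises(ValueError):
        synth.make_family_set(2, 2, 0.6, 0.9, seed=2)


def test_decoy_kinds(consensi):
    ng = synth.make_decoys("ngaro_order", 1, consensi)
    relic = synth.make_decoys("missing_mt_relic", 1, consensi)
    pat = synth.make_decoys("pat_like", 1, consensi)
    assert len(ng) > 1000 and len(relic) > 500 and len(pat) > 2000
    with pytest.raises(ValueError):
        synth.make_decoys("bogus", 1, consensi)


def test_rt_identity_one_reproduces_consensus(consensi):
    bp = ElementBlueprint(seed=4, rt_id=1.0, total_size=4800)
    el, t = make_element(bp, verify=False)
    from dirscan.seqio import translate_str

    rt_nt = el.residues[t.rt_span[0] : t.rt_span[1]]
    assert translate_str(rt_nt) == consensi["RT"]
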
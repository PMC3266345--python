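"""Similarity graph construction, Markov clustering and superfamily labels."""

import math

import pytest

from dirscan import clustering as C
from dirscan import resources, synth
from dirscan.clustering import FamilyPartition, SimilarityGraph
from dirscan.seqio import NucSequence


def _clique_graph(groups, weight=50.0):
    nodes = [n for g in groups for n in g]
    g = SimilarityGraph(nodes=nodes)
    for grp in groups:
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                g.edges[(min(grp[i], grp[j]), max(grp[i], grp[j]))] = weight
    return g


def test_identical_fragments_edge_at_cap(rng):
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=360))
    g = C.pairwise_nt_similarity([NucSequence("a", s), NucSequence("b", s)])
    assert g.weight("a", "b") == pytest.approx(200.0)
    assert g.weight("b", "a") == g.weight("a", "b")


def test_dissimilar_fragments_no_edge(rng):
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=360))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=360))
    g = C.pairwise_nt_similarity([NucSequence("a", a), NucSequence("b", b)])
    assert g.weight("a", "b") == 0.0


def test_mcl_edgeless_gives_singletons():
    g = SimilarityGraph(nodes=[f"n{i}" for i in range(5)])
    part = C.mcl_cluster(g, 1.2)
    assert sorted(len(f) for f in part.families) == [1] * 5


def test_mcl_disjoint_cliques():
    g = _clique_graph([[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]])
    part = C.mcl_cluster(g, 1.2)
    assert part.as_sets() == {
        frozenset(f"a{i}" for i in range(4)),
        frozenset(f"b{i}" for i in range(4)),
    }


def test_mcl_input_order_invariance(rng):
    frags, _ = synth.make_family_set(2, 4, 0.9, 0.6, seed=5)
    g = C.pairwise_nt_similarity(frags)
    part1 = C.mcl_cluster(g, 1.2)
    shuffled = SimilarityGraph(
        nodes=list(reversed(g.nodes)), edges=dict(reversed(list(g.edges.items())))
    )
    part2 = C.mcl_cluster(shuffled, 1.2)
    assert part1.as_sets() == part2.as_sets()


def test_mcl_recovers_planted_families():
    frags, truth = synth.make_family_set(3, 5, 0.90, 0.60, seed=11)
    part = C.mcl_cluster(C.pairwise_nt_similarity(frags), 1.2)
    assert part.as_sets() == {frozenset(t) for t in truth}


def test_lower_inflation_never_more_clusters():
    frags, _ = synth.make_family_set(3, 4, 0.9, 0.6, seed=21)
    g = C.pairwise_nt_similarity(frags)
    ns = [len(C.mcl_cluster(g, r).families) for r in (1.2, 2.0, 5.0)]
    assert ns[0] <= ns[1] <= ns[2]


@pytest.mark.parametrize(
    "bd,bp,expected",
    [
        (1e-50, 1e-20, C.DIRS),
        (1e-15, 1.0, C.UNCERTAIN),      # absolute threshold fails
        (1e-25, 1e-22, C.UNCERTAIN),    # separation under 10 orders
        (1e-20, 1e-50, C.PAT),
        (1e-40, 1e-30, C.DIRS),       # exactly 10 orders of separation passes
        (1e-39, 1e-30, C.UNCERTAIN),  # 9 orders does not
    ],
)
def test_superfamily_threshold_rule(bd, bp, expected):
    assert C.classify_from_evalues(bd, bp) == expected


def test_classify_requires_references(rng):
    s = NucSequence("x", "".join("ACGT"[i] for i in rng.integers(0, 4, size=300)))
    with pytest.raises(ValueError):
        C.classify_superfamily(s, [], [s])


def test_reference_elements_classify_as_themselves():
    dirs_refs = list(resources.reference_elements("DIRS"))
    pat_refs = list(resources.reference_elements("PAT"))
    assert C.classify_superfamily(dirs_refs[0], dirs_refs[1:], pat_refs) == C.DIRS
    assert C.classify_superfamily(pat_refs[0], dirs_refs, pat_refs[1:]) == C.PAT


def test_global_vs_per_genome_partitions_agree():
    """Clustering fragments of several genomes jointly or separately yields the
    same within-genome families."""
    frags_a, _ = synth.make_family_set(2, 4, 0.9, 0.6, seed=31)
    frags_b, _ = synth.make_family_set(2, 4, 0.9, 0.6, seed=32)
    frags_b = [NucSequence("gB_" + f.id, f.residues) for f in frags_b]
    frags_a = [NucSequence("gA_" + f.id, f.residues) for f in frags_a]
    joint = C.mcl_cluster(C.pairwise_nt_similarity(frags_a + frags_b), 1.2)
    solo_a = C.mcl_cluster(C.pairwise_nt_similarity(frags_a), 1.2)
    solo_b = C.mcl_cluster(C.pairwise_nt_similarity(frags_b), 1.2)
    joint_within = {
        frozenset(n for n in fam if n.startswith(tag))
        for fam in joint.families
        for tag in ("gA_", "gB_")
        if any(n.startswith(tag) for n in fam)
    }
    assert solo_a.as_sets() | solo_b.as_sets() == joint_within
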
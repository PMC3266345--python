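"""JTT+Gamma distances, neighbor joining, bootstrap supports."""

import numpy as np
import pytest

from dirscan import phylo as P


from helpers_trees import random_tree


def test_identical_sequences_distance_zero():
    assert P.jtt_gamma_distance("ACDEFGHIKL" * 10, "ACDEFGHIKL" * 10) == 0.0


def test_distance_symmetric(rng):
    a, b = P.simulate_jtt_pair(0.4, 300, rng)
    assert P.jtt_gamma_distance(a, b) == pytest.approx(P.jtt_gamma_distance(b, a), rel=1e-6)


def test_pairwise_deletion_and_errors():
    d_full = P.jtt_gamma_distance("AAAA", "AAAA")
    assert d_full == 0.0
    assert P.jtt_gamma_distance("A-CD", "AE-D") >= 0.0  # only cols 0 and 3 shared
    with pytest.raises(P.DistanceError):
        P.jtt_gamma_distance("A-", "-A")
    with pytest.raises(P.DistanceError):
        P.jtt_gamma_distance("AA", "AAA")


def test_distance_monotone_in_time(rng):
    means = []
    for t in (0.1, 0.5, 1.0):
        ests = [P.jtt_gamma_distance(*P.simulate_jtt_pair(t, 600, rng)) for _ in range(6)]
        means.append(np.mean(ests))
    assert means[0] < means[1] < means[2]


def test_simulation_parameter_recovery(rng):
    ests = [P.jtt_gamma_distance(*P.simulate_jtt_pair(0.5, 1000, rng)) for _ in range(12)]
    assert abs(np.mean(ests) - 0.5) < 0.05


def test_three_taxon_closed_form():
    labels = ["a", "b", "c"]
    d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = P.nj_tree(P.DistanceMatrix(labels, d))
    bl = {c.name: l for c, l in tree.children}
    assert bl["a"] == pytest.approx(0.5 * (0.4 + 0.6 - 0.8))
    assert bl["b"] == pytest.approx(0.5 * (0.4 + 0.8 - 0.6))
    assert bl["c"] == pytest.approx(0.5 * (0.6 + 0.8 - 0.4))


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        P.nj_tree(P.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


@pytest.mark.parametrize("seed", range(25))
def test_nj_inverts_additive_matrices(seed):
    """On exactly additive distances NJ recovers the generating tree."""
    rng = np.random.default_rng(500 + seed)
    n = int(rng.integers(5, 13))
    tree = random_tree(rng, n)
    dm = P.tree_distances(tree)
    rebuilt = P.nj_tree(dm)
    assert P.bipartitions(rebuilt) == P.bipartitions(tree)
    dm2 = P.tree_distances(rebuilt)
    np.testing.assert_allclose(dm2.d, dm.d, atol=1e-9)


def test_nj_label_order_invariance(rng):
    tree = random_tree(rng, 8)
    dm = P.tree_distances(tree)
    perm = rng.permutation(len(dm.labels))
    dm_p = P.DistanceMatrix([dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
    assert P.bipartitions(P.nj_tree(dm)) == P.bipartitions(P.nj_tree(dm_p))


def test_nj_agrees_with_reference_implementation(rng):
    """Cross-check topology against the scikit-bio NJ implementation."""
    import skbio

    tree = random_tree(rng, 9)
    dm = P.tree_distances(tree)
    ours = P.nj_tree(dm)
    sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
    sk_splits = set()
    all_ids = frozenset(dm.labels)
    for node in sk.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_ids) - 1:
            sk_splits.add(min(below, all_ids - below, key=lambda s: (len(s), sorted(s))))
    assert P.bipartitions(ours) == sk_splits


def test_bootstrap_deterministic_and_bounded(rng):
    aln = []
    for clade, base_t in (("A", 0.05), ("B", 0.05)):
        anc, der = P.simulate_jtt_pair(1.5 if clade == "B" else 0.0, 400, rng)
        seqs = anc if clade == "A" else der
        for k in range(3):
            _, leaf = P.simulate_jtt_pair(base_t, 400, np.random.default_rng([k, ord(clade)]))
            mixed = "".join(a if np.random.default_rng([k, ord(clade), i]).random() < 0.9 else b
                            for i, (a, b) in enumerate(zip(seqs, leaf)))
            aln.append((f"{clade}{k}", mixed))
    t1 = P.bootstrap_support(aln, n_reps=20, seed=7)
    t2 = P.bootstrap_support(aln, n_reps=20, seed=7)

    def supports(t):
        out = []

        def walk(n):
            if n.support is not None:
                out.append(round(n.support, 6))
            for c, _ in n.children:
                walk(c)

        walk(t)
        return out

    assert supports(t1) == supports(t2)
    assert all(0.0 <= s <= 1.0 for s in supports(t1))


def test_bootstrap_strong_signal_high_support(rng):
    """Two clearly separated simulated clades get near-full support."""
    anc, far = P.simulate_jtt_pair(2.0, 500, rng)
    aln = []
    for name, base in (("a1", anc), ("a2", anc), ("b1", far), ("b2", far)):
        _, leaf = P.simulate_jtt_pair(0.05, 500, rng)
        mutated = "".join(l if rng.random() < 0.03 else b for b, l in zip(base, leaf))
        aln.append((name, mutated))
    tree = P.bootstrap_support(aln, n_reps=50, seed=3)
    sups = []

    def walk(n):
        if n.support is not None:
            sups.append(n.support)
        for c, _ in n.children:
            walk(c)

    walk(tree)
    assert sups and min(sups) >= 0.9


def test_zero_reps_leaves_supports_absent():
    aln = [("a", "ACDE" * 30), ("b", "ACDF" * 30), ("c", "ACEF" * 30)]
    tree = P.bootstrap_support(aln, n_reps=0, seed=1)

    def walk(n):
        assert n.support is None
        for c, _ in n.children:
            walk(c)

    walk(tree)


def test_newick_roundtrip_through_dendropy(rng):
    import dendropy

    tree = random_tree(rng, 6)
    nwk = tree.newick()
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(tree.leaves())
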
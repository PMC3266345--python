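"""Shared test helper: random binary trees for additivity oracles."""

from dirscan import phylo as P


def random_tree(rng, n_taxa):
    """A random binary tree over t0..t{n-1} with exponential branch lengths."""
    nodes = [P.TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = P.TreeNode(
            children=[
                (nodes[i], 0.05 + rng.exponential(0.3)),
                (nodes[j], 0.05 + rng.exponential(0.3)),
            ]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return P.TreeNode(children=[(n, 0.05 + rng.exponential(0.3)) for n in nodes])
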
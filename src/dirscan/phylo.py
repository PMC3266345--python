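"""Family-level phylogeny: JTT+Gamma distances, neighbor-joining, bootstrap.

Pairwise distances are maximum-likelihood estimates under the JTT empirical
amino-acid replacement model with discrete-gamma rate variation (4 categories)
and pairwise deletion of gap columns. Trees are built with the Saitou-Nei
neighbor-joining algorithm (deterministic, lexicographic tie-breaking) and
internal-edge support is assessed by nonparametric bootstrap over alignment
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._jtt import AA_ORDER, FREQS, exchangeability_matrix

GAP_CHARS = set("-.xX?")


class DistanceError(ValueError):
    pass


@lru_cache(maxsize=1)
def _jtt_eigen():
    """Eigendecomposition of the normalized JTT rate matrix (cached).

    Q[i, j] = S[i, j] * pi[j], scaled so the expected rate at stationarity is
    one substitution per site per unit time.
    """
    s = exchangeability_matrix()
    pi = FREQS / FREQS.sum()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    q /= scale
    # symmetrize for a stable eigendecomposition: B = D^1/2 Q D^-1/2
    d = np.sqrt(pi)
    b = q * d[:, None] / d[None, :]
    w, v = np.linalg.eigh((b + b.T) / 2)
    left = v / d[None, :].T  # D^-1/2 V
    right = v.T * d[None, :]  # V^T D^1/2
    return pi, w, left, right


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) under normalized JTT."""
    _, w, left, right = _jtt_eigen()
    return (left * np.exp(w * t)[None, :]) @ right


@lru_cache(maxsize=64)
def gamma_rates(alpha: float, categories: int = 4) -> tuple[float, ...]:
    """Discrete-gamma category rates (equal-probability quantile midpoints,
    normalized to mean one)."""
    qs = (2 * np.arange(categories) + 1) / (2 * categories)
    rates = gamma_dist.ppf(qs, a=alpha, scale=1.0 / alpha)
    return tuple(rates / rates.mean())


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        k = AA_ORDER.find(c)
        out[i] = k
    return out


def jtt_gamma_distance(
    a: str, b: str, alpha: float = 1.0, categories: int = 4
) -> float:
    """ML distance (substitutions/site) between two aligned aa sequences.

    Columns where either sequence has a gap or an unknown residue are dropped
    (pairwise deletion) before the likelihood is optimized over t in
    [1e-6, 10].
    """
    if len(a) != len(b):
        raise DistanceError("aligned sequences must have equal length")
    ca, cb = _encode(a), _encode(b)
    keep = (ca >= 0) & (cb >= 0)
    if not keep.any():
        raise DistanceError("no shared ungapped columns")
    ca, cb = ca[keep], cb[keep]
    if np.array_equal(ca, cb):
        return 0.0
    pairs, counts = np.unique(ca * 20 + cb, return_counts=True)
    pi, w, left, right = _jtt_eigen()
    rates = gamma_rates(alpha, categories)
    ia, ib = pairs // 20, pairs % 20
    log_pi = np.log(pi[ia])

    def neg_loglik(t: float) -> float:
        like = np.zeros(len(pairs))
        for r in rates:
            p = (left * np.exp(w * (t * r))[None, :]) @ right
            like += np.maximum(p[ia, ib], 1e-300)
        return -float(np.sum(counts * (log_pi + np.log(like / len(rates)))))

    res = minimize_scalar(neg_loglik, bounds=(1e-6, 10.0), method="bounded")
    return float(res.x)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.d = d


def distance_matrix(
    alignment: list[tuple[str, str]], alpha: float = 1.0
) -> DistanceMatrix:
    labels = [name for name, _ in alignment]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_gamma_distance(alignment[i][1], alignment[j][1], alpha)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{c._nwk(ws)}:{bl:.6g}" for c, bl in self.children
        )
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:.2f}"
        return f"({inner}){label}"


def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with non-negative branch lengths.

    Ties in the Q criterion are broken toward the lexicographically smallest
    pair of cluster labels, so the result is independent of input order. A
    negative branch length is clamped to zero and the excess moved to its
    sister edge, preserving the path length between the joined taxa.
    """
    if len(m.labels) < 3:
        raise ValueError("need at least 3 taxa")
    order = np.argsort(np.array(m.labels, dtype=object))
    labels = [m.labels[i] for i in order]
    d = m.d[np.ix_(order, order)].astype(float)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    names = list(labels)  # current cluster names for tie-breaking
    active = list(range(len(labels)))
    dist = {(i, j): d[i, j] for i in active for j in active if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = len(labels)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * get(i, j) - r[i] - r[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        names.append(min(names[i], names[j]))
        k_new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, k_new), max(k, k_new))] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [k_new]
    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    return TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (the additivity oracle's inverse map)."""
    leaves = sorted(tree.leaves())
    idx = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node: TreeNode, acc: list[tuple[str, float]]):
        if not node.children:
            return [(node.name, 0.0)]
        below = []
        for child, bl in node.children:
            sub = [(name, dist + bl) for name, dist in walk(child, acc)]
            for na, da in sub:
                for nb, db in below:
                    d[idx[na], idx[nb]] = d[idx[nb], idx[na]] = da + db
            below.extend(sub)
        return below

    walk(tree, [])
    return DistanceMatrix(leaves, d)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each as the smaller-or-lexicographic leaf set."""
    all_leaves = frozenset(tree.leaves())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                other = all_leaves - sub
                splits.add(min(sub, other, key=lambda s: (len(s), sorted(s))))
            below = below | sub
        return below

    walk(tree)
    return splits


def _annotate_supports(tree: TreeNode, freq: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(tree.leaves())

    def walk(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below = below | walk(child)
        if 1 < len(below) < len(all_leaves) - 1:
            key = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            node.support = freq.get(key, 0.0)
        return below

    walk(tree)


def bootstrap_support(
    alignment: list[tuple[str, str]],
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports on internal edges."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    tree = nj_tree(distance_matrix(alignment, alpha))
    if n_reps <= 0:
        return tree
    ncols = len(alignment[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = [(name, "".join(row[c] for c in cols)) for name, row in alignment]
        try:
            rep_tree = nj_tree(distance_matrix(rep, alpha))
        except DistanceError:
            continue
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    freq = {k: v / n_reps for k, v in counts.items()}
    _annotate_supports(tree, freq)
    return tree


def simulate_jtt_pair(
    t: float,
    n_sites: int,
    rng: np.random.Generator,
    alpha: float = 1.0,
    categories: int = 4,
) -> tuple[str, str]:
    """Simulate one aligned pair at divergence t under JTT+Gamma."""
    pi, _, _, _ = _jtt_eigen()
    rates = gamma_rates(alpha, categories)
    cat = rng.integers(0, categories, size=n_sites)
    anc = rng.choice(20, size=n_sites, p=pi)
    ps = {r: jtt_transition_matrix(t * r) for r in set(rates)}
    der = np.empty(n_sites, dtype=np.int64)
    for k in range(n_sites):
        row = ps[rates[cat[k]]][anc[k]]
        row = np.maximum(row, 0)
        der[k] = rng.choice(20, p=row / row.sum())
    to_str = lambda codes: "".join(AA_ORDER[c] for c in codes)
    return to_str(anc), to_str(der)
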
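"""Family clustering of RT fragments and DIRS/PAT superfamily classification.

Families are Markov-Cluster (MCL) clusters of an all-vs-all nucleotide
similarity graph: gapped local alignments with megablast-like scoring
(match +1, mismatch -2, gap open 5, extend 2), empirically calibrated
E-values, an edge kept when E <= 0.01, and edge weight min(200, -log10 E)
(the TribeMCL convention). MCL iterates expansion (matrix squaring) and
inflation (entrywise power, here 1.2) on the column-stochastic flow matrix
until convergence; clusters are read from the attractor systems.

Superfamily labels follow a translated (six-frame vs six-frame) comparison of
a family representative against reference element sets: DIRS when the best
DIRS E-value is below 1e-20 AND at least 10 orders of magnitude better than
the best PAT E-value; PAT by the mirrored rule; otherwise uncertain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import align
from .align import GumbelCalibration
from .config import Config, DEFAULT_CONFIG
from .seqio import NucSequence, six_frame_translate

DIRS = "DIRS"
PAT = "PAT"
UNCERTAIN = "uncertain"


class ConvergenceError(RuntimeError):
    pass


def nt_query_matrix(query: str, config: Config = DEFAULT_CONFIG) -> np.ndarray:
    """Positional score rows for a nucleotide query; N is neutral."""
    codes = align.encode_nt(query)
    prof = np.full((len(codes), align.N_NT_CODES), config.nt_mismatch)
    for i, c in enumerate(codes):
        if c == 4:
            prof[i, :] = 0.0
        else:
            prof[i, c] = config.nt_match
    prof[:, 4] = 0.0
    return prof


@lru_cache(maxsize=8)
def _nt_calibration(m0: int, n0: int, params: tuple, seed: int = 3141) -> GumbelCalibration:
    """Empirical Gumbel for the nucleotide scoring system at given sizes."""
    match, mismatch, go, ge = params
    rng = np.random.default_rng(seed)
    scores = np.empty(200)
    cfg = Config(nt_match=match, nt_mismatch=mismatch, nt_gap_open=go, nt_gap_ext=ge)
    for k in range(200):
        q = "".join(rng.choice(list("ACGT"), size=m0))
        s = rng.integers(0, 4, size=n0).astype(np.int8)
        scores[k] = align.sw_best_score(nt_query_matrix(q, cfg), s, go, ge)
    return align.fit_gumbel(scores, m0, n0)


def nt_evalue(
    score: float, m: int, n: int, config: Config = DEFAULT_CONFIG, seed: int = 3141
) -> float:
    """E-value for a nucleotide local alignment score between lengths m and n."""
    m0 = min(512, max(64, 1 << (m - 1).bit_length()))
    n0 = min(512, max(64, 1 << (n - 1).bit_length()))
    calib = _nt_calibration(
        m0, n0,
        (config.nt_match, config.nt_mismatch, config.nt_gap_open, config.nt_gap_ext),
        seed,
    )
    return calib.K * m * n * math.exp(-calib.lam * score)


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    evalue_cutoff: float = 0.01

    def weight(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError("self-edges are not stored")
        key = (min(a, b), max(a, b))
        return self.edges.get(key, 0.0)


def pairwise_nt_similarity(
    fragments: list[NucSequence],
    cutoff: float = 0.01,
    config: Config = DEFAULT_CONFIG,
    seed: int = 3141,
) -> SimilarityGraph:
    """All-vs-all gapped local alignment graph over nucleotide fragments.

    ``seed`` drives the empirical E-value calibration of the nucleotide
    scoring system; the graph is deterministic given (fragments, seed).
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fragment ids")
    graph = SimilarityGraph(nodes=sorted(ids), evalue_cutoff=cutoff)
    mats = {f.id: nt_query_matrix(f.residues, config) for f in fragments}
    codes = {f.id: align.encode_nt(f.residues) for f in fragments}
    lens = {f.id: len(f) for f in fragments}
    for i, a in enumerate(fragments):
        for b in fragments[i + 1 :]:
            score = align.sw_best_score(
                mats[a.id], codes[b.id], config.nt_gap_open, config.nt_gap_ext
            )
            ev = nt_evalue(score, lens[a.id], lens[b.id], config, seed=seed)
            if ev <= cutoff:
                w = min(config.edge_weight_cap, -math.log10(max(ev, 1e-200)))
                graph.edges[(min(a.id, b.id), max(a.id, b.id))] = w
    return graph


@dataclass
class FamilyPartition:
    families: list[list[str]]           # sorted node lists, largest first
    inflation: float
    labels: dict[int, str] = field(default_factory=dict)  # family index -> label

    def family_of(self, node: str) -> int:
        for i, fam in enumerate(self.families):
            if node in fam:
                return i
        raise KeyError(node)

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(f) for f in self.families}


def mcl_cluster(
    g: SimilarityGraph,
    inflation: float = 1.2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FamilyPartition:
    """Canonical Markov clustering of the similarity graph.

    Self-loop weight is the maximum incident edge weight (1 for isolated
    nodes); the flow matrix is column-normalized and iterated through
    expansion (squaring) and inflation until the max entry change falls below
    ``tol``. Node input order does not matter: nodes are sorted internally.
    """
    if not g.nodes:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in g.edges.items():
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = M @ M
        new = np.power(new, inflation)
        new[new < 1e-12] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        delta = np.abs(new - M).max()
        M = new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"MCL did not converge; residual {delta:.2e}")
    return _read_clusters(M, nodes, inflation)


def _read_clusters(M: np.ndarray, nodes: list[str], inflation: float) -> FamilyPartition:
    n = len(nodes)
    thr = 1e-6
    attractors = [i for i in range(n) if M[i, i] > thr]
    if not attractors:  # pathological; fall back to strongest row per column
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))
    # attractor systems: attractors sharing any supported column
    import networkx as nx

    ag = nx.Graph()
    ag.add_nodes_from(attractors)
    for j in range(n):
        sup = [i for i in attractors if M[i, j] > thr]
        for a, b in zip(sup, sup[1:]):
            ag.add_edge(a, b)
    systems = [sorted(c) for c in nx.connected_components(ag)]
    systems.sort(key=lambda s: nodes[s[0]])
    assignment: dict[int, int] = {}
    for j in range(n):
        masses = [sum(M[i, j] for i in sys) for sys in systems]
        best = max(masses)
        if best <= thr and j in [a for sys in systems for a in sys]:
            # attractor of its own system
            assignment[j] = next(k for k, sys in enumerate(systems) if j in sys)
            continue
        # largest attractor mass; ties toward the lexicographically first system
        assignment[j] = int(np.argmax(masses))
    fams: dict[int, list[str]] = {}
    for j, k in assignment.items():
        fams.setdefault(k, []).append(nodes[j])
    families = sorted(
        (sorted(f) for f in fams.values()), key=lambda f: (-len(f), f[0])
    )
    return FamilyPartition(families=families, inflation=inflation)


# ---------------------------------------------------------------------------
# Superfamily classification


@lru_cache(maxsize=1)
def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 recast onto the internal 22-letter amino-acid code order."""
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    letters = "ACDEFGHIKLMNPQRSTVWYX*"
    mat = np.zeros((22, 22))
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            mat[i, j] = bl[a][b]
    return mat


@lru_cache(maxsize=1)
def _aa_calibration(seed: int = 2718) -> GumbelCalibration:
    rng = np.random.default_rng(seed)
    bg = np.full(20, 0.05)
    scores = np.empty(200)
    bm = _blosum62_matrix()
    for k in range(200):
        q = align.sample_background_aa(rng, 300, bg)
        s = align.sample_background_aa(rng, 300, bg)
        prof = bm[q.astype(int)]
        scores[k] = align.sw_best_score(prof, s, 11.0, 1.0)
    return align.fit_gumbel(scores, 300, 300)


def translated_best_evalue(a: NucSequence, b: NucSequence) -> float:
    """Best E-value over all 36 frame pairs of a TBLASTX-like comparison."""
    bm = _blosum62_matrix()
    calib = _aa_calibration()
    best = math.inf
    frames_a = [f for f in six_frame_translate(a) if len(f) >= 10]
    frames_b = [f for f in six_frame_translate(b) if len(f) >= 10]
    for fa in frames_a:
        qa = align.encode_aa(fa.residues)
        prof = bm[qa.astype(int)]
        for fb in frames_b:
            sb = align.encode_aa(fb.residues)
            score = align.sw_best_score(prof, sb, 11.0, 1.0)
            ev = calib.K * len(qa) * len(sb) * math.exp(-calib.lam * score)
            best = min(best, ev)
    return best


def classify_superfamily(
    family_representative: NucSequence,
    dirs_refs: list[NucSequence],
    pat_refs: list[NucSequence],
    evalue_threshold: float = 1e-20,
    separation: float = 1e10,
) -> str:
    """Label a family by its best translated match to reference elements."""
    if not dirs_refs or not pat_refs:
        raise ValueError("reference sets must be non-empty")
    best_dirs = min(translated_best_evalue(family_representative, r) for r in dirs_refs)
    best_pat = min(translated_best_evalue(family_representative, r) for r in pat_refs)
    return classify_from_evalues(best_dirs, best_pat, evalue_threshold, separation)


def classify_from_evalues(
    best_dirs: float,
    best_pat: float,
    evalue_threshold: float = 1e-20,
    separation: float = 1e10,
) -> str:
    """Threshold rule on the two best E-values (testable in isolation)."""
    if best_dirs < evalue_threshold and best_dirs * separation <= best_pat:
        return DIRS
    if best_pat < evalue_threshold and best_pat * separation <= best_dirs:
        return PAT
    return UNCERTAIN
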
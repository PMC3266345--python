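"""Local alignment engine and empirical E-value statistics.

One Smith-Waterman kernel serves every search in the package: a query is
always presented as a position x alphabet score matrix, so a PSSM search, a
protein-vs-protein comparison (rows taken from a substitution matrix) and a
nucleotide-vs-nucleotide comparison (rows from a match/mismatch matrix) all
run through the same affine-gap DP. The kernel tracks alignment origins
through the recurrence, so spans are recovered without a stored traceback
matrix; multiple non-overlapping local hits are obtained by masking the
subject span of each reported hit and re-running.

Significance is assessed with an empirical Gumbel fit: maximal local scores
against shuffled background sequences are collected and (lambda, K) estimated
by the method of moments, giving E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import AA_ALPHABET

# amino-acid encoding: 20 canonical, X=20, *=21
AA_CODES = {aa: i for i, aa in enumerate(AA_ALPHABET)}
AA_CODES["X"] = 20
AA_CODES["*"] = 21
N_AA_CODES = 22

NT_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_NT_CODES = 5

EULER_GAMMA = 0.5772156649015329


def encode_aa(residues: str) -> np.ndarray:
    return np.array([AA_CODES.get(c, 20) for c in residues], dtype=np.int8)


def encode_nt(residues: str) -> np.ndarray:
    return np.array([NT_CODES.get(c, 4) for c in residues], dtype=np.int8)


@njit(cache=False)
def _sw_best(prof, seq, gap_open, gap_ext, banned):  # pragma: no cover - jitted
    """Best local alignment of a positional score matrix against a sequence.

    Returns (score, i0, i1, j0, j1): profile span [i0, i1] and subject span
    [j0, j1], both inclusive. Score 0 means no positive-scoring alignment.
    """
    m = prof.shape[0]
    NEG = -1.0e30
    # previous column state (subject position j-1)
    Hp = np.zeros(m, dtype=np.float64)
    Ep = np.full(m, NEG, dtype=np.float64)
    Hp_oj = np.zeros(m, dtype=np.int64)
    Hp_oi = np.zeros(m, dtype=np.int64)
    Ep_oj = np.zeros(m, dtype=np.int64)
    Ep_oi = np.zeros(m, dtype=np.int64)
    Hc = np.zeros(m, dtype=np.float64)
    Ec = np.full(m, NEG, dtype=np.float64)
    Hc_oj = np.zeros(m, dtype=np.int64)
    Hc_oi = np.zeros(m, dtype=np.int64)
    Ec_oj = np.zeros(m, dtype=np.int64)
    Ec_oi = np.zeros(m, dtype=np.int64)

    best = 0.0
    b_i0 = b_i1 = b_j0 = b_j1 = -1

    n = seq.shape[0]
    for j in range(n):
        if banned[j]:
            for i in range(m):
                Hc[i] = 0.0
                Ec[i] = NEG
            tmp = Hp; Hp = Hc; Hc = tmp
            tmp = Ep; Ep = Ec; Ec = tmp
            tmp2 = Hp_oj; Hp_oj = Hc_oj; Hc_oj = tmp2
            tmp2 = Hp_oi; Hp_oi = Hc_oi; Hc_oi = tmp2
            tmp2 = Ep_oj; Ep_oj = Ec_oj; Ec_oj = tmp2
            tmp2 = Ep_oi; Ep_oi = Ec_oi; Ec_oi = tmp2
            continue
        c = seq[j]
        F = NEG
        F_oj = 0
        F_oi = 0
        for i in range(m):
            s = prof[i, c]
            # diagonal: H(j-1, i-1) + s, restart if that H is zero
            if i > 0 and Hp[i - 1] > 0.0:
                hval = Hp[i - 1] + s
                h_oj = Hp_oj[i - 1]
                h_oi = Hp_oi[i - 1]
            else:
                hval = s
                h_oj = j
                h_oi = i
            # E: gap consuming subject (same i, previous j)
            e_open = Hp[i] - gap_open
            e_ext = Ep[i] - gap_ext
            if e_open >= e_ext:
                eval_ = e_open
                e_oj = Hp_oj[i]
                e_oi = Hp_oi[i]
            else:
                eval_ = e_ext
                e_oj = Ep_oj[i]
                e_oi = Ep_oi[i]
            # F: gap consuming profile (same j, previous i)
            if i > 0:
                f_open = Hc[i - 1] - gap_open
                if Hc[i - 1] <= 0.0:
                    f_open = NEG
                f_ext = F - gap_ext
                if f_open >= f_ext:
                    F = f_open
                    F_oj = Hc_oj[i - 1]
                    F_oi = Hc_oi[i - 1]
                else:
                    F = f_ext
            else:
                F = NEG
            h = hval
            oj = h_oj
            oi = h_oi
            if eval_ > h:
                h = eval_
                oj = e_oj
                oi = e_oi
            if F > h:
                h = F
                oj = F_oj
                oi = F_oi
            if h < 0.0:
                h = 0.0
                oj = j
                oi = i
            Hc[i] = h
            Hc_oj[i] = oj
            Hc_oi[i] = oi
            Ec[i] = eval_
            Ec_oj[i] = e_oj
            Ec_oi[i] = e_oi
            if h > best:
                best = h
                b_i0 = oi
                b_i1 = i
                b_j0 = oj
                b_j1 = j
        tmp = Hp; Hp = Hc; Hc = tmp
        tmp = Ep; Ep = Ec; Ec = tmp
        tmp2 = Hp_oj; Hp_oj = Hc_oj; Hc_oj = tmp2
        tmp2 = Hp_oi; Hp_oi = Hc_oi; Hc_oi = tmp2
        tmp2 = Ep_oj; Ep_oj = Ec_oj; Ec_oj = tmp2
        tmp2 = Ep_oi; Ep_oi = Ec_oi; Ec_oi = tmp2
    return best, b_i0, b_i1, b_j0, b_j1


@njit(cache=False)
def _lcs(a, b):  # pragma: no cover - jitted
    """Longest exact common substring of two code arrays.

    Returns (length, a_start, b_start). Ties resolved toward the smallest
    (a_start, b_start).
    """
    n = a.shape[0]
    m = b.shape[0]
    prev = np.zeros(m, dtype=np.int64)
    cur = np.zeros(m, dtype=np.int64)
    best = 0
    ba = -1
    bb = -1
    for i in range(n):
        for jj in range(m):
            if a[i] == b[jj]:
                if i > 0 and jj > 0:
                    cur[jj] = prev[jj - 1] + 1
                else:
                    cur[jj] = 1
                if cur[jj] > best:
                    best = cur[jj]
                    ba = i - best + 1
                    bb = jj - best + 1
            else:
                cur[jj] = 0
        tmp = prev
        prev = cur
        cur = tmp
    return best, ba, bb


@njit(cache=False)
def _maximal_matches(a, b, min_len, cap):  # pragma: no cover - jitted
    """All maximal exact common substrings of length >= min_len.

    Returns parallel arrays (lengths, a_starts, b_starts), unsorted, at most
    ``cap`` entries (longest-first is applied by the caller)."""
    n = a.shape[0]
    m = b.shape[0]
    prev = np.zeros(m, dtype=np.int64)
    cur = np.zeros(m, dtype=np.int64)
    lens = np.empty(cap, dtype=np.int64)
    astarts = np.empty(cap, dtype=np.int64)
    bstarts = np.empty(cap, dtype=np.int64)
    k = 0
    for i in range(n):
        for jj in range(m):
            if a[i] == b[jj]:
                if i > 0 and jj > 0:
                    cur[jj] = prev[jj - 1] + 1
                else:
                    cur[jj] = 1
                run = cur[jj]
                ended = (
                    i == n - 1
                    or jj == m - 1
                    or a[i + 1] != b[jj + 1]
                )
                if ended and run >= min_len and k < cap:
                    lens[k] = run
                    astarts[k] = i - run + 1
                    bstarts[k] = jj - run + 1
                    k += 1
            else:
                cur[jj] = 0
        tmp = prev
        prev = cur
        cur = tmp
    return lens[:k], astarts[:k], bstarts[:k]


def maximal_exact_matches(
    a: np.ndarray, b: np.ndarray, min_len: int, cap: int = 512
) -> list[tuple[int, int, int]]:
    lens, astarts, bstarts = _maximal_matches(a, b, min_len, cap)
    out = sorted(
        zip(lens.tolist(), astarts.tolist(), bstarts.tolist()),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    return out


@dataclass(frozen=True)
class LocalHit:
    """One local alignment: query (profile) span and subject span, half-open."""

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int


def sw_local_hits(
    prof: np.ndarray,
    seq: np.ndarray,
    gap_open: float,
    gap_ext: float,
    min_score: float,
    max_hits: int = 10_000,
) -> list[LocalHit]:
    """All non-overlapping local hits scoring at least ``min_score``.

    Greedy maximal-first: the best alignment is reported, its subject span is
    masked, and the search repeats until the best score drops below the
    threshold.
    """
    if seq.size == 0 or min_score <= 0:
        if min_score <= 0:
            raise ValueError("min_score must be positive")
        return []
    banned = np.zeros(seq.shape[0], dtype=np.bool_)
    hits: list[LocalHit] = []
    for _ in range(max_hits):
        score, i0, i1, j0, j1 = _sw_best(prof, seq, gap_open, gap_ext, banned)
        if score < min_score or j0 < 0:
            break
        hits.append(LocalHit(float(score), int(i0), int(i1) + 1, int(j0), int(j1) + 1))
        banned[j0 : j1 + 1] = True
    return hits


def sw_best_score(prof: np.ndarray, seq: np.ndarray, gap_open: float, gap_ext: float) -> float:
    banned = np.zeros(seq.shape[0], dtype=np.bool_)
    score, *_ = _sw_best(prof, seq, gap_open, gap_ext, banned)
    return float(score)


def sw_best_alignment(
    prof: np.ndarray, seq: np.ndarray, gap_open: float, gap_ext: float
) -> LocalHit | None:
    """Best local alignment with spans (no path), linear memory."""
    banned = np.zeros(seq.shape[0], dtype=np.bool_)
    score, i0, i1, j0, j1 = _sw_best(prof, seq, gap_open, gap_ext, banned)
    if j0 < 0:
        return None
    return LocalHit(float(score), int(i0), int(i1) + 1, int(j0), int(j1) + 1)


def longest_common_substring(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    length, a0, b0 = _lcs(a, b)
    return int(length), int(a0), int(b0)


def align_path(
    prof: np.ndarray, seq: np.ndarray, gap_open: float, gap_ext: float
) -> tuple[float, list[tuple[int, int]]]:
    """Best local alignment with its full path, for small inputs.

    The path is a list of (query_pos, subject_pos) matched pairs (gap steps
    omitted). Quadratic memory; intended for hit-sized regions only.
    """
    m, n = prof.shape[0], seq.shape[0]
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 E(left), 3 F(up)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            diag = H[i - 1, j - 1] + prof[i - 1, seq[j - 1]]
            best = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = best
            if best == 0.0:
                ptr[i, j] = 0
            elif best == diag:
                ptr[i, j] = 1
            elif best == E[i, j]:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = float(H[i, j])
    path: list[tuple[int, int]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        p = ptr[i, j]
        if p == 1:
            path.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif p == 2:
            j -= 1
        elif p == 3:
            i -= 1
        else:
            break
    path.reverse()
    return score, path


# ---------------------------------------------------------------------------
# Empirical Gumbel statistics


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GumbelCalibration:
    """Gumbel parameters fitted to maximal local scores on random sequences.

    ``n_cal`` is the subject length used during calibration; E-values for a
    search of effective size N then follow E = K * m * N * exp(-lambda * S).
    """

    lam: float
    K: float
    m: int
    n_cal: int

    def evalue(self, score: float, search_space: int) -> float:
        return self.K * self.m * search_space * math.exp(-self.lam * score)

    def score_for_evalue(self, evalue: float, search_space: int) -> float:
        return math.log(self.K * self.m * search_space / evalue) / self.lam


def fit_gumbel(max_scores: np.ndarray, m: int, n_cal: int) -> GumbelCalibration:
    """Method-of-moments Gumbel fit to a sample of maximal local scores."""
    mu = float(np.mean(max_scores))
    sd = float(np.std(max_scores))
    if sd < 1e-9:
        raise CalibrationError("degenerate score distribution (zero variance)")
    lam = math.pi / (sd * math.sqrt(6.0))
    K = math.exp(lam * mu - EULER_GAMMA) / (m * n_cal)
    return GumbelCalibration(lam=lam, K=K, m=m, n_cal=n_cal)


def sample_background_aa(rng: np.random.Generator, length: int, freqs: np.ndarray) -> np.ndarray:
    codes = rng.choice(20, size=length, p=freqs / freqs.sum())
    return codes.astype(np.int8)


def calibrate_matrix(
    prof: np.ndarray,
    freqs: np.ndarray,
    gap_open: float,
    gap_ext: float,
    seed: int,
    n_seqs: int = 300,
    seq_len: int = 400,
) -> GumbelCalibration:
    """Calibrate any positional score matrix against i.i.d. background."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_seqs)
    for k in range(n_seqs):
        seq = sample_background_aa(rng, seq_len, freqs)
        scores[k] = sw_best_score(prof, seq, gap_open, gap_ext)
    return fit_gumbel(scores, prof.shape[0], seq_len)
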
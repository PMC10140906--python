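"""Independent brute-force oracles used to validate the package algorithms.

These deliberately share no code with pbmine's implementations: plain
O(n*m) dynamic programming and O(n^2 * L) enumeration, fast enough only
for the small instances the tests use.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

NEG = float("-inf")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(c, "N") for c in reversed(seq))


def smith_waterman_score(a: str, b: str, open_gap: float = -11.0,
                         extend_gap: float = -1.0) -> float:
    """Affine-gap local alignment score (Gotoh), BLOSUM62."""
    n, m = len(a), len(b)
    best = 0.0
    H = [0.0] * (m + 1)  # previous row
    E = [NEG] * (m + 1)
    for i in range(1, n + 1):
        F = NEG
        Hrow = [0.0] * (m + 1)
        for j in range(1, m + 1):
            E[j] = max(E[j] + extend_gap, H[j] + open_gap)
            F = max(F + extend_gap, Hrow[j - 1] + open_gap)
            s = _B62[a[i - 1]][b[j - 1]]
            Hrow[j] = max(0.0, H[j - 1] + s, E[j], F)
            best = max(best, Hrow[j])
        H = Hrow
    return best


def needleman_wunsch(a: str, b: str, open_gap: float = -11.0,
                     extend_gap: float = -1.0):
    """Affine-gap global alignment; returns (score, aligned_a, aligned_b)."""
    n, m = len(a), len(b)
    go = open_gap  # score of the first gap column (PairwiseAligner convention)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = go + extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1]][b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + extend_gap,
                          Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + extend_gap,
                          X[i][j - 1] + go)
    # traceback
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    A, B = [], []
    while i > 0 or j > 0:
        if state == "M":
            A.append(a[i - 1])
            B.append(b[j - 1])
            prev = max(("M", "X", "Y"),
                       key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1][j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            A.append(a[i - 1])
            B.append("-")
            cands = []
            if M[i - 1][j] + go == X[i][j]:
                cands.append("M")
            if X[i - 1][j] + extend_gap == X[i][j]:
                cands.append("X")
            if Y[i - 1][j] + go == X[i][j]:
                cands.append("Y")
            i, state = i - 1, cands[0]
        else:
            A.append("-")
            B.append(b[j - 1])
            cands = []
            if M[i][j - 1] + go == Y[i][j]:
                cands.append("M")
            if Y[i][j - 1] + extend_gap == Y[i][j]:
                cands.append("Y")
            if X[i][j - 1] + go == Y[i][j]:
                cands.append("X")
            j, state = j - 1, cands[0]
    return score, "".join(reversed(A)), "".join(reversed(B))


def global_identity(a: str, b: str) -> float:
    """Identity (% of alignment columns) from the affine NW oracle."""
    _, x, y = needleman_wunsch(a, b)
    matches = sum(1 for p, q in zip(x, y) if p == q and p != "-")
    return 100.0 * matches / len(x)


def brute_tir_pairs(seq: str, min_len: int = 10, max_len: int = 500,
                    max_mismatch: int = 2, search_window: int | None = None,
                    mismatch_frac: float | None = None):
    """Exhaustive enumeration of maximal TIR pairs: for every (i, j), the
    largest arm length L whose final position matches, with cumulative
    mismatches within budget and non-overlapping arms."""
    n = len(seq)
    w = search_window if search_window is not None else max(n // 4, min_len)
    w = min(w, n)

    def budget(length: int) -> int:
        if mismatch_frac is None:
            return max_mismatch
        return max(max_mismatch, int(mismatch_frac * length))

    out = []
    for i in range(0, w):
        for j in range(n - w + 1, n + 1):
            best_l = 0
            best_mm = 0
            mm = 0
            for d in range(min(max_len, n // 2)):
                if i + d >= j - 1 - d:  # arms would overlap
                    break
                left = seq[i + d]
                right = COMPLEMENT.get(seq[j - 1 - d], "X")
                match = left == right and left in "ACGT"
                if not match:
                    mm += 1
                if mm > budget(min(max_len, n // 2)):
                    if mismatch_frac is None:
                        break
                if match and mm <= budget(d + 1):
                    best_l = d + 1
                    best_mm = mm
            if best_l >= min_len:
                out.append((i, j, best_l, best_mm))
    return sorted(out)


def kimura_closed_form(P: float, Q: float) -> float:
    """Independent high-precision evaluation of the K2P closed form."""
    return -0.5 * math.log((1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q)) * 100.0


def tally_alignment(a: str, b: str):
    """Position-by-position substitution tally on an explicit alignment."""
    sites = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if {x, y} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    return sites, ts, tv


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle preserving approximate dinucleotide content (Eulerian-walk
    style shuffle on the dinucleotide graph, simplified: shuffle of
    non-overlapping dinucleotide blocks)."""
    blocks = [seq[i : i + 2] for i in range(0, len(seq) - 1, 2)]
    order = rng.permutation(len(blocks))
    tail = seq[len(blocks) * 2 :]
    return "".join(blocks[i] for i in order) + tail
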
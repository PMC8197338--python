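"""Independent alignment oracles for the test suite.

Two layers, both independent of the package's alignment engine:

* ``gotoh_global_score`` / ``sw_local_score`` — plain pure-Python affine-gap
  dynamic programming (no traceback, no shared code with the engine);
* ``enumerate_global_best`` — literal enumeration of every global alignment
  path, feasible only for tiny sequences, used to validate the DP oracles
  themselves.

Gap convention matches the package: a gap of length k costs
open + (k - 1) * extend.
"""

from __future__ import annotations

from cypcensus.pairwise import substitution_score

NEG = float("-inf")


def gotoh_global_score(a: str, b: str, open_: float = 12.0, ext: float = 1.0,
                       matrix: str = "BLOSUM62") -> float:
    """Optimal global affine-gap score (terminal gaps penalised)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = substitution_score(a[i - 1], b[j - 1], matrix)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext,
                          Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext,
                          X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


def sw_local_score(a: str, b: str, open_: float = 12.0, ext: float = 1.0,
                   matrix: str = "BLOSUM62") -> float:
    """Optimal local affine-gap (Smith-Waterman) score; 0 when nothing
    scores positively."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_, E[i][j - 1] - ext)
            F[i][j] = max(H[i - 1][j] - open_, F[i - 1][j] - ext)
            s = substitution_score(a[i - 1], b[j - 1], matrix)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _score_path(a: str, b: str, moves: tuple[str, ...], open_: float,
                ext: float, matrix: str) -> float:
    """Affine score of one explicit alignment path (D/U/L moves)."""
    score = 0.0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == "D":
            score += substitution_score(a[i], b[j], matrix)
            i += 1
            j += 1
        elif mv == "U":  # consume a, gap in b
            score -= ext if prev == "U" else open_
            i += 1
        else:  # "L": consume b, gap in a
            score -= ext if prev == "L" else open_
            j += 1
        prev = mv
    return score


def enumerate_global_best(a: str, b: str, open_: float = 12.0, ext: float = 1.0,
                          matrix: str = "BLOSUM62") -> float:
    """Best global score by enumerating every monotone alignment path.

    Exponential; intended for sequences of length <= 4 only.
    """
    n, m = len(a), len(b)
    best = NEG

    def walk(i: int, j: int, moves: tuple[str, ...]) -> None:
        nonlocal best
        if i == n and j == m:
            best = max(best, _score_path(a, b, moves, open_, ext, matrix))
            return
        if i < n and j < m:
            walk(i + 1, j + 1, moves + ("D",))
        if i < n:
            walk(i + 1, j, moves + ("U",))
        if j < m:
            walk(i, j + 1, moves + ("L",))

    walk(0, 0, ())
    return best


def enumerate_local_best(a: str, b: str, open_: float = 12.0, ext: float = 1.0,
                         matrix: str = "BLOSUM62") -> float:
    """Best local score: max global-path score over all substring pairs
    (including the empty alignment at 0).  Tiny inputs only."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, enumerate_global_best(
                        a[i1:i2], b[j1:j2], open_, ext, matrix))
    return best
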
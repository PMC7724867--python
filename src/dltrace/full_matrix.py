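"""Full-matrix dynamic programming references for the DL distance.

Two recurrences over the (m+1) x (n+1) matrix H, where H[i][j] is the weighted
DL distance between the prefixes A[1:i] and B[1:j]:

* the original four-case recurrence (substitution / insertion / deletion /
  transposition-with-gap), valid whenever I + D <= 2T, and
* the refined recurrence, which restricts the transposition case to
  a_i != b_j with min(i - k, j - l) = 1, valid whenever 2S <= I + D <= 2T.

In the transposition case, k is the rightmost occurrence of b_j in A before
position i and l is the rightmost occurrence of a_i in B before position j;
the case contributes H[k-1][l-1] + (i-k-1)*D + T + (j-l-1)*I (the characters
between the transposed pair are deleted, the pair is swapped, and the gap is
refilled by insertions). With unit costs this is the familiar
H[k-1][l-1] + (i-k-1) + 1 + (j-l-1).

These O(mn)-space implementations are the package's internal references; the
linear-space algorithms are checked against them.
"""

from __future__ import annotations

from typing import List, NamedTuple

from .costs import CostModel, UNIT_COSTS, require_valid
from .encoding import EncodedPair, as_pair

__all__ = ["FullMatrixResult", "lw_full_matrix", "refined_full_matrix"]


class FullMatrixResult(NamedTuple):
    H: List[List[float]]
    distance: float


def _boundary(m: int, n: int, costs: CostModel) -> List[List[float]]:
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        H[i][0] = i * costs.D
    for j in range(1, n + 1):
        H[0][j] = j * costs.I
    return H


def lw_full_matrix(pair, B=None, costs: CostModel = UNIT_COSTS) -> FullMatrixResult:
    """Original four-case recurrence, filled row-major left to right.

    Requires I + D <= 2T. The transposition case is skipped whenever k or l
    does not exist.
    """
    pair = as_pair(pair, B)
    require_valid(costs, "lw")
    A, Bc, s = pair.A, pair.B, pair.s
    m, n = pair.m, pair.n
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    H = _boundary(m, n, costs)
    lastA = [0] * s  # rightmost row < i with A[row] == symbol
    for i in range(1, m + 1):
        a = A[i - 1]
        l = 0  # rightmost column < j with B[col] == a
        for j in range(1, n + 1):
            b = Bc[j - 1]
            best = H[i - 1][j - 1] + (0 if a == b else S)
            left = H[i][j - 1] + I
            if left < best:
                best = left
            up = H[i - 1][j] + D
            if up < best:
                best = up
            k = lastA[b]
            if k and l:
                cand = H[k - 1][l - 1] + (i - k - 1) * D + T + (j - l - 1) * I
                if cand < best:
                    best = cand
            H[i][j] = best
            if b == a:
                l = j
        lastA[a] = i
    return FullMatrixResult(H, H[m][n])


def refined_full_matrix(pair, B=None, costs: CostModel = UNIT_COSTS) -> FullMatrixResult:
    """Refined recurrence: transposition only when adjacent to the occurrence.

    Requires 2S <= I + D <= 2T. The transposition case applies only when
    a_i != b_j and either j - l = 1 (contributing H[k-1][j-2] + (i-k-1)*D + T)
    or i - k = 1 (contributing H[i-2][l-1] + (j-l-1)*I + T); with unit costs
    these reduce to H[k-1][j-2] + (i-k) and H[i-2][l-1] + (j-l).
    """
    pair = as_pair(pair, B)
    require_valid(costs, "refined")
    A, Bc, s = pair.A, pair.B, pair.s
    m, n = pair.m, pair.n
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    H = _boundary(m, n, costs)
    lastA = [0] * s  # rightmost row < i with A[row] == symbol
    for i in range(1, m + 1):
        a = A[i - 1]
        l = 0  # rightmost column < j with B[col] == a
        for j in range(1, n + 1):
            b = Bc[j - 1]
            if a == b:
                best = H[i - 1][j - 1]
                d = H[i][j - 1] + I
                if d < best:
                    best = d
                d = H[i - 1][j] + D
                if d < best:
                    best = d
                l = j
            else:
                best = H[i - 1][j - 1] + S
                d = H[i][j - 1] + I
                if d < best:
                    best = d
                d = H[i - 1][j] + D
                if d < best:
                    best = d
                k = lastA[b]
                if l and j - l == 1 and k:
                    cand = H[k - 1][j - 2] + (i - k - 1) * D + T
                    if cand < best:
                        best = cand
                if k and i - k == 1 and l:
                    cand = H[i - 2][l - 1] + (j - l - 1) * I + T
                    if cand < best:
                        best = cand
            H[i][j] = best
        lastA[a] = i
    return FullMatrixResult(H, H[m][n])
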
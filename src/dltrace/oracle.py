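"""Independent correctness references.

``bfs_dl`` realises the *definition* of the weighted DL distance — the
minimum-cost sequence of single-character substitutions, insertions,
deletions and adjacent swaps applied to an evolving string — by cost-ordered
search over string space. It shares no code or recurrence with the dynamic
programming implementations, which makes it the ground truth for tiny
instances.

``enumerate_center_crossings`` exhaustively lists the candidate center
crossings of a bisected instance and prices each directly from full forward
and backward DP matrices, for validating the divide-and-conquer combiners.
"""

from __future__ import annotations

import heapq
from itertools import count
from typing import Dict, List, Optional, Tuple

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

from .costs import CostModel, UNIT_COSTS
from .encoding import as_pair
from .full_matrix import lw_full_matrix

__all__ = ["bfs_dl", "enumerate_center_crossings"]

_MAX_LEN = 8


def _levenshtein(a: str, b: str) -> int:
    if edlib is not None and a and b:
        return edlib.align(a, b)["editDistance"]
    # Tiny fallback (also covers empty strings, which edlib rejects).
    if not a or not b:
        return max(len(a), len(b))
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def bfs_dl(
    A: str,
    B: str,
    costs: CostModel = UNIT_COSTS,
    cost_bound: Optional[float] = None,
) -> float:
    """Exact minimum edit-sequence cost by search over evolving strings.

    Moves from a state string: substitute any position to any alphabet
    character (cost S when different; identical substitutions are no-ops),
    insert any alphabet character anywhere (I), delete any position (D), swap
    any adjacent pair (T). The search is cost-ordered (Dijkstra / A*) with an
    admissible Levenshtein-based lower bound: a transposition can stand in
    for at most two plain edits, so any state at Levenshtein distance L from
    B still costs at least L * min(S, I, D, T/2).

    Restricted to strings of length <= 8 and strictly positive costs — the
    state space is intentionally not managed beyond that. Returns ``inf``
    when ``cost_bound`` is exceeded.
    """
    if len(A) > _MAX_LEN or len(B) > _MAX_LEN:
        raise ValueError(f"bfs_dl is limited to strings of length <= {_MAX_LEN}")
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    if min(S, I, D, T) <= 0:
        raise ValueError("bfs_dl requires strictly positive costs")
    if A == B:
        return 0
    alphabet = sorted(set(A) | set(B))
    m, n = len(A), len(B)
    factor = min(S, I, D, T / 2)
    max_len = m + n + 2

    # Any-state upper bound: rewrite the common-length prefix by substitutions
    # and make up the length difference, or delete-all + insert-all.
    aligned = sum(S for x, y in zip(A, B) if x != y) + (
        (n - m) * I if n >= m else (m - n) * D
    )
    upper = min(aligned, m * D + n * I)
    if cost_bound is not None and upper > cost_bound:
        upper = cost_bound

    h0 = factor * _levenshtein(A, B)
    tie = count()
    heap: List[Tuple[float, int, float, str]] = [(h0, next(tie), 0, A)]
    best_g: Dict[str, float] = {A: 0}
    while heap:
        f, _, g, state = heapq.heappop(heap)
        if state == B:
            return g
        if g > best_g.get(state, -1):
            continue  # stale entry
        L = len(state)
        moves: List[Tuple[float, str]] = []
        for p in range(L - 1):
            moves.append((T, state[:p] + state[p + 1] + state[p] + state[p + 2:]))
        for p in range(L):
            moves.append((D, state[:p] + state[p + 1:]))
            for c in alphabet:
                if c != state[p]:
                    moves.append((S, state[:p] + c + state[p + 1:]))
        if L < max_len:
            for p in range(L + 1):
                for c in alphabet:
                    moves.append((I, state[:p] + c + state[p:]))
        for step, nxt in moves:
            g2 = g + step
            if g2 > upper:
                continue
            old = best_g.get(nxt)
            if old is not None and old <= g2:
                continue
            h = factor * _levenshtein(nxt, B)
            if g2 + h > upper:
                continue
            best_g[nxt] = g2
            heapq.heappush(heap, (g2 + h, next(tie), g2, nxt))
    # Unreachable within the bound.
    return float("inf")


def enumerate_center_crossings(
    pair,
    B=None,
    mid: Optional[int] = None,
    costs: CostModel = UNIT_COSTS,
) -> List[Tuple[int, int, int, int, float]]:
    """All candidate center crossings of a bisected instance, with costs.

    A center crossing is a crossing pair of balanced lines
    {(u1, v1), (u2, v2)} with v2 <= mid < v1 such that u1 is the rightmost
    occurrence of B[v1] in A before u2 and v2 the rightmost occurrence of
    A[u2] in B before v1. Each candidate is priced directly from full-matrix
    forward and backward DP:

        H[u1-1][v2-1] + H'[u2+1][v1+1] + (u2-u1-1)*D + T + (v1-v2-1)*I

    Returns (u1, v1, u2, v2, cost) tuples. Small instances only (m, n <= 20).
    """
    pair = as_pair(pair, B)
    A, Bs = pair.A, pair.B
    m, n = pair.m, pair.n
    if m > 20 or n > 20:
        raise ValueError("enumerate_center_crossings is limited to m, n <= 20")
    if mid is None:
        mid = n // 2
    I, D, T = costs.I, costs.D, costs.T
    Hf = lw_full_matrix(pair, costs=costs).H
    Hr = lw_full_matrix(A[::-1], Bs[::-1], costs=costs).H

    def suffix_cost(i: int, j: int) -> float:  # cost of A[i:m] vs B[j:n]
        return Hr[m - i + 1][n - j + 1]

    out = []
    for u1 in range(1, m + 1):
        for u2 in range(u1 + 1, m + 1):
            # condition (a): u1 is the rightmost occurrence of A[u1] before u2
            if any(A[i - 1] == A[u1 - 1] for i in range(u1 + 1, u2)):
                continue
            for v2 in range(1, mid + 1):
                if A[u2 - 1] != Bs[v2 - 1]:
                    continue
                for v1 in range(mid + 1, n + 1):
                    if A[u1 - 1] != Bs[v1 - 1]:
                        continue
                    # condition (b): v2 rightmost occurrence of B[v2] before v1
                    if any(Bs[j - 1] == Bs[v2 - 1] for j in range(v2 + 1, v1)):
                        continue
                    cost = (
                        Hf[u1 - 1][v2 - 1]
                        + suffix_cost(u2 + 1, v1 + 1)
                        + (u2 - u1 - 1) * D
                        + T
                        + (v1 - v2 - 1) * I
                    )
                    out.append((u1, v1, u2, v2, cost))
    return out
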
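"""Edit traces and linear-space optimal-trace computation.

A *trace* for strings A (length m) and B (length n) is a set of lines (u, v)
joining position u of A to position v of B, such that no two lines share a u
or share a v. A line is *balanced* iff A[u] = B[v]; two lines (u1, v1) and
(u2, v2) *cross* iff u1 < u2 and v1 > v2. A trace encodes an edit sequence:

* an unattached A position is deleted, an unattached B position inserted;
* an unbalanced line is a substitution, a non-crossing balanced line retains
  its character at zero cost;
* a crossing pair of balanced lines is a transposition: the A characters
  strictly between u1 and u2 are deleted, a_u1 and a_u2 (now adjacent) are
  swapped, and the B characters strictly between v2 and v1 are inserted into
  the gap.

The optimal (minimum-cost) trace is computed in linear space by bisecting B
at column mid = floor(n/2) and combining a forward pass over B[1:mid] with a
backward pass over the reversed suffix, in the style of Hirschberg's
divide-and-conquer. Unlike the transposition-free case, an optimal trace may
contain a *center crossing* — a crossing pair straddling the bisection column
— which cannot be split cleanly; such a crossing can however always be
normalised so that either its B endpoints are the two columns adjacent to the
bisection, or its A endpoints are adjacent rows. Each recursion node therefore
takes the cheapest of three combination rules (no crossing, B-adjacent
crossing, A-adjacent crossing) evaluated from the boundary arrays that the
linear-space distance algorithm already maintains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

from .costs import CostModel, UNIT_COSTS, require_valid
from .encoding import EncodedPair, as_pair
from .full_matrix import lw_full_matrix
from .linear import EdgeArray, default_sentinel, ls_dl2
from .strips import strip_dl2

__all__ = [
    "Line",
    "Trace",
    "EditOp",
    "EditScript",
    "SplitDecision",
    "is_valid_trace",
    "classify_lines",
    "crossing_pairs",
    "trace_to_edit_script",
    "combine_no_cc",
    "combine_cc_adjacent_B",
    "combine_cc_adjacent_A",
    "ls_trace2",
    "strip_trace2",
]

_INF = math.inf


class Line(NamedTuple):
    """A trace line joining A position ``u`` to B position ``v`` (1-based)."""

    u: int
    v: int


@dataclass(frozen=True)
class Trace:
    lines: FrozenSet[Line]
    m: int
    n: int

    @staticmethod
    def of(lines, m: int, n: int) -> "Trace":
        return Trace(frozenset(Line(u, v) for u, v in lines), m, n)


class LinePartition(NamedTuple):
    balanced: FrozenSet[Line]
    unbalanced: FrozenSet[Line]


def _seqs(pair, B=None) -> Tuple[Sequence, Sequence]:
    if isinstance(pair, EncodedPair):
        return pair.A, pair.B
    if B is None:
        raise TypeError("two sequences (or an EncodedPair) required")
    return pair, B


def is_valid_trace(T: Trace) -> bool:
    """True iff every line is in bounds and u's and v's are each distinct."""
    us = set()
    vs = set()
    for u, v in T.lines:
        if not (1 <= u <= T.m and 1 <= v <= T.n):
            return False
        if u in us or v in vs:
            return False
        us.add(u)
        vs.add(v)
    return True


def classify_lines(T: Trace, pair, B=None) -> LinePartition:
    """Partition lines into balanced (A[u] = B[v]) and unbalanced."""
    A, Bs = _seqs(pair, B)
    balanced = frozenset(l for l in T.lines if A[l.u - 1] == Bs[l.v - 1])
    return LinePartition(balanced, frozenset(T.lines - balanced))


def crossing_pairs(T: Trace) -> FrozenSet[FrozenSet[Line]]:
    """All unordered pairs of lines that cross (u1 < u2 and v1 > v2)."""
    lines = sorted(T.lines)
    out = set()
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            l1, l2 = lines[a], lines[b]  # l1.u < l2.u (u's distinct)
            if l1.v > l2.v:
                out.add(frozenset((l1, l2)))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Edit scripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditOp:
    """One edit operation.

    ``op`` is one of delete/insert/substitute/retain/transpose. ``u``/``v``
    are 1-based positions in A/B (for a transposition, (u, v) = (u1, v1) and
    (u2, v2) the partner line). ``char`` carries the character the operation
    contributes to the output (for a transposition, ``char`` = A[u2], emitted
    first, and ``char2`` = A[u1], emitted after the gap insertions).
    """

    op: str
    u: Optional[int] = None
    v: Optional[int] = None
    u2: Optional[int] = None
    v2: Optional[int] = None
    char: Optional[object] = None
    char2: Optional[object] = None


@dataclass(frozen=True)
class EditScript:
    """An ordered, applicable list of edit operations with its total cost.

    Operations are ordered left to right by B coordinate, with deletions
    positioned where their A character falls, so the script can be applied in
    a single left-to-right pass.
    """

    ops: Tuple[EditOp, ...]
    total_cost: float
    m: int
    n: int

    def apply(self, A: Sequence):
        """Apply the script to A, returning the transformed sequence."""
        if len(A) != self.m:
            raise ValueError(f"script built for |A| = {self.m}, got {len(A)}")
        out: List = []
        pending: Optional[Tuple[object, int]] = None  # (char2, inserts left)
        for op in self.ops:
            if op.op == "delete":
                continue
            if op.op == "insert":
                out.append(op.char)
                if pending is not None:
                    char2, left = pending
                    left -= 1
                    pending = (char2, left)
                    if left == 0:
                        out.append(char2)
                        pending = None
                continue
            if op.op in ("retain", "substitute"):
                out.append(op.char)
            elif op.op == "transpose":
                out.append(op.char)  # A[u2]
                gap = op.v - op.v2 - 1
                if gap == 0:
                    out.append(op.char2)  # A[u1]
                else:
                    pending = (op.char2, gap)
            else:  # pragma: no cover
                raise ValueError(f"unknown op {op.op!r}")
        if pending is not None:
            raise ValueError("dangling transposition gap in script")
        if isinstance(A, str):
            return "".join(out)
        return type(A)(out) if not isinstance(A, tuple) else tuple(out)

    def to_trace(self) -> Trace:
        lines = []
        for op in self.ops:
            if op.op in ("retain", "substitute"):
                lines.append((op.u, op.v))
            elif op.op == "transpose":
                lines.append((op.u, op.v))
                lines.append((op.u2, op.v2))
        return Trace.of(lines, self.m, self.n)


def trace_to_edit_script(T: Trace, pair, B=None, costs: CostModel = UNIT_COSTS) -> EditScript:
    """Convert a trace into its ordered edit script.

    Crossing pairs must be pairwise disjoint (no line in two crossings) and
    each crossing pair must consist of two balanced lines; other traces have
    no edit interpretation and are rejected with ``ValueError``.
    """
    A, Bs = _seqs(pair, B)
    if T.m != len(A) or T.n != len(Bs):
        raise ValueError("trace dimensions do not match the sequences")
    if not is_valid_trace(T):
        raise ValueError("invalid trace: out-of-bounds or duplicated endpoints")
    balanced, _ = classify_lines(T, A, Bs)
    crossings = crossing_pairs(T)
    seen: Dict[Line, int] = {}
    for pairset in crossings:
        for line in pairset:
            seen[line] = seen.get(line, 0) + 1
            if seen[line] > 1:
                raise ValueError(
                    f"line {tuple(line)} participates in more than one crossing"
                )
        for line in pairset:
            if line not in balanced:
                raise ValueError(
                    f"crossing pair {sorted(map(tuple, pairset))} contains an "
                    "unbalanced line and has no transposition interpretation"
                )

    # Blocks (transpositions) and plain lines, both totally ordered once the
    # disjointness check has passed.
    blocks = []  # (u1, v1, u2, v2) with u1 < u2, v1 > v2
    for pairset in crossings:
        l1, l2 = sorted(pairset)
        blocks.append((l1.u, l1.v, l2.u, l2.v))
    crossing_lines = set(seen)
    plain = sorted(T.lines - crossing_lines)
    anchors = sorted(
        [("line", l.u, l.v) for l in plain]
        + [("block", u1, v1, u2, v2) for (u1, v1, u2, v2) in blocks],
        key=lambda t: t[1],
    )

    S, I, D, Tc = costs.S, costs.I, costs.D, costs.T
    ops: List[EditOp] = []
    total = 0
    pa, pb = 1, 1  # next unemitted positions of A and B

    def flush_gap(ua: int, vb: int) -> None:
        nonlocal pa, pb, total
        for u in range(pa, ua):
            ops.append(EditOp("delete", u=u, char=A[u - 1]))
        total += (ua - pa) * D
        for v in range(pb, vb):
            ops.append(EditOp("insert", v=v, char=Bs[v - 1]))
        total += (vb - pb) * I
        pa, pb = ua, vb

    for anchor in anchors:
        if anchor[0] == "line":
            _, u, v = anchor
            if v < pb:
                raise ValueError("trace lines are inconsistently ordered")
            flush_gap(u, v)
            if A[u - 1] == Bs[v - 1]:
                ops.append(EditOp("retain", u=u, v=v, char=A[u - 1]))
            else:
                ops.append(EditOp("substitute", u=u, v=v, char=Bs[v - 1]))
                total += S
            pa, pb = u + 1, v + 1
        else:
            _, u1, v1, u2, v2 = anchor
            if v2 < pb:
                raise ValueError("trace lines are inconsistently ordered")
            flush_gap(u1, v2)
            for u in range(u1 + 1, u2):
                ops.append(EditOp("delete", u=u, char=A[u - 1]))
            total += (u2 - u1 - 1) * D
            ops.append(
                EditOp(
                    "transpose",
                    u=u1, v=v1, u2=u2, v2=v2,
                    char=A[u2 - 1], char2=A[u1 - 1],
                )
            )
            total += Tc
            for v in range(v2 + 1, v1):
                ops.append(EditOp("insert", v=v, char=Bs[v - 1]))
            total += (v1 - v2 - 1) * I
            pa, pb = u2 + 1, v1 + 1
    flush_gap(len(A) + 1, len(Bs) + 1)

    return EditScript(ops=tuple(ops), total_cost=total, m=len(A), n=len(Bs))


# ---------------------------------------------------------------------------
# Divide-and-conquer combiners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitDecision:
    """Outcome of one recursion node's three-way combination."""

    kind: str  # 'no_crossing' | 'cc_adjacent_B' | 'cc_adjacent_A'
    cost: float
    i: Optional[int] = None
    u1: Optional[int] = None
    u2: Optional[int] = None
    v1: Optional[int] = None
    v2: Optional[int] = None


def combine_no_cc(Rf, Rb, m: Optional[int] = None) -> Tuple[float, Optional[int]]:
    """min over 0 <= i <= m of Rf[i] + Rb[i+1]; ties broken by smallest i.

    ``Rf[i]`` is the optimal cost for A[1:i] against the left half of B;
    ``Rb[i+1]`` (already re-indexed into original coordinates) the cost for
    A[i+1:m] against the right half.
    """
    if m is None:
        m = Rf.last_index if isinstance(Rf, EdgeArray) else len(Rf) - 1
    if len(Rb) < m + 2:
        raise ValueError("forward/backward array lengths are inconsistent")
    best, best_i = _INF, None
    for i in range(0, m + 1):
        tot = Rf[i] + Rb[i + 1]
        if tot < best:
            best, best_i = tot, i
    return best, best_i


def combine_cc_adjacent_B(
    R1f,
    R1b,
    m: Optional[int] = None,
    costs: CostModel = UNIT_COSTS,
    valid_u1: Optional[Sequence[int]] = None,
    valid_u2: Optional[Sequence[int]] = None,
) -> Tuple[float, Optional[int], Optional[int]]:
    """Center crossing with B endpoints adjacent to the bisection column.

    Evaluates min over u1 < u2 of R1f[u1-1] + R1b[u2+1] + (u2-u1-1)*D + T,
    the cost of a trace whose crossing is {(u1, mid+1), (u2, mid)}. When
    ``valid_u1``/``valid_u2`` are given, candidates are restricted to those
    index sets (the trace algorithm passes the positions whose A character
    matches B[mid+1] / B[mid], which a realizable transposition requires).
    Ties prefer the smallest u1, then the smallest u2.
    """
    if m is None:
        m = R1f.last_index if isinstance(R1f, EdgeArray) else len(R1f) - 1
    if len(R1b) < m + 2:
        raise ValueError("forward/backward array lengths are inconsistent")
    D, T = costs.D, costs.T
    u1_ok = set(range(1, m + 1)) if valid_u1 is None else set(valid_u1)
    u2_ok = set(range(1, m + 1)) if valid_u2 is None else set(valid_u2)
    # Suffix minima over u2 of R1b[u2+1] + u2*D (smallest u2 on ties).
    suf_val = [_INF] * (m + 3)
    suf_idx: List[Optional[int]] = [None] * (m + 3)
    for u2 in range(m, 1, -1):
        v, idx = suf_val[u2 + 1], suf_idx[u2 + 1]
        if u2 in u2_ok:
            cand = R1b[u2 + 1] + u2 * D
            if cand <= v:
                v, idx = cand, u2
        suf_val[u2], suf_idx[u2] = v, idx
    best, bu1, bu2 = _INF, None, None
    for u1 in range(1, m):
        if u1 not in u1_ok or suf_idx[u1 + 1] is None:
            continue
        tot = R1f[u1 - 1] - u1 * D + suf_val[u1 + 1] - D + T
        if tot < best:
            best, bu1, bu2 = tot, u1, suf_idx[u1 + 1]
    return best, bu1, bu2


def combine_cc_adjacent_A(
    FRf,
    FRb,
    pair,
    B=None,
    mid: Optional[int] = None,
    costs: CostModel = UNIT_COSTS,
) -> Tuple[float, Optional[int], Optional[int], Optional[int]]:
    """Center crossing with A endpoints adjacent (u2 = u1 + 1).

    For each u1, v2 is the rightmost occurrence of A[u2] in B[1:mid] and v1
    the leftmost occurrence of A[u1] in B[mid+1:n]; the candidate cost is
    FRf[u2] + FRb[u1] + (v1 - v2 - 1)*I + T, using the transposition-helper
    arrays of the forward and (re-indexed) backward passes. Returns
    (cost, u1, v1, v2); sentinel cost when no candidate exists.
    """
    A, Bs = _seqs(pair, B)
    m, n = len(A), len(Bs)
    if mid is None:
        mid = n // 2
    I, T = costs.I, costs.T
    last_le: Dict[object, int] = {}
    for v in range(1, mid + 1):
        last_le[Bs[v - 1]] = v
    first_gt: Dict[object, int] = {}
    for v in range(n, mid, -1):
        first_gt[Bs[v - 1]] = v
    best, bu1, bv1, bv2 = _INF, None, None, None
    for u1 in range(1, m):
        u2 = u1 + 1
        v2 = last_le.get(A[u2 - 1])
        v1 = first_gt.get(A[u1 - 1])
        if v2 is None or v1 is None:
            continue
        tot = FRf[u2] + FRb[u1] + (v1 - v2 - 1) * I + T
        if tot < best:
            best, bu1, bv1, bv2 = tot, u1, v1, v2
    return best, bu1, bv1, bv2


# ---------------------------------------------------------------------------
# Linear-space optimal trace
# ---------------------------------------------------------------------------


def _full_matrix_lines(A, B, s, costs):
    """Base case: tiny subproblem solved by full-matrix DP with backtrack."""
    pair = EncodedPair(tuple(A), tuple(B), s)
    H = lw_full_matrix(pair, costs=costs).H
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    lines: List[Tuple[int, int]] = []
    i, j = len(A), len(B)
    while i > 0 or j > 0:
        h = H[i][j]
        if i > 0 and j > 0 and h == H[i - 1][j - 1] + (0 if A[i - 1] == B[j - 1] else S):
            lines.append((i, j))
            i, j = i - 1, j - 1
            continue
        if j > 0 and h == H[i][j - 1] + I:
            j -= 1
            continue
        if i > 0 and h == H[i - 1][j] + D:
            i -= 1
            continue
        k = next((p for p in range(i - 1, 0, -1) if A[p - 1] == B[j - 1]), 0)
        l = next((p for p in range(j - 1, 0, -1) if B[p - 1] == A[i - 1]), 0)
        if (
            k
            and l
            and h == H[k - 1][l - 1] + (i - k - 1) * D + T + (j - l - 1) * I
        ):
            lines.append((k, j))
            lines.append((i, l))
            i, j = k - 1, l - 1
            continue
        raise AssertionError("full-matrix backtrack failed")  # pragma: no cover
    return H[len(A)][len(B)], lines


def _forward_pass(A, Bleft, s, costs, max_val, engine, q):
    """Boundary arrays over A positions for A-prefixes vs B[1:mid].

    The row-oriented engine runs the DP transposed (rows = B half, columns =
    A) with insertion/deletion roles swapped, so its final row arrays are
    indexed by A position; the strip engine runs untransposed (rows = A) and
    its column arrays C/C1/FC are the same quantities directly.
    """
    if engine == "ls":
        res = ls_dl2(
            EncodedPair(tuple(Bleft), tuple(A), s),
            costs=costs.swap_indel(),
            max_val=max_val,
        )
        return res.R, res.R1, res.FR
    res = strip_dl2(
        EncodedPair(tuple(A), tuple(Bleft), s), costs=costs, q=q, max_val=max_val
    )
    return res.C, res.C1, res.FC


def _backward_pass(A, Bright, s, costs, max_val, engine, q):
    """Same as the forward pass on the reversed suffixes, re-indexed.

    Returned lists are addressed by original A position p: slot p holds the
    value for the suffix subproblem starting at p (Rb), at p against
    B[mid+2:] (R1b), or the transposition helper for the pair (p, p+1) (FRb).
    """
    m = len(A)
    Rr, R1r, FRr = _forward_pass(A[::-1], Bright[::-1], s, costs, max_val, engine, q)
    Rb = [max_val] * (m + 3)
    R1b = [max_val] * (m + 3)
    FRb = [max_val] * (m + 3)
    for p in range(1, m + 2):
        Rb[p] = Rr[m + 1 - p]
        R1b[p] = R1r[m + 1 - p]
    for p in range(1, m + 1):
        FRb[p] = FRr[m + 1 - p]
    return Rb, R1b, FRb


def _decide_split(A, B, s, costs, max_val, engine, q) -> SplitDecision:
    m = len(A)
    mid = len(B) // 2
    Rf, R1f, FRf = _forward_pass(A, B[:mid], s, costs, max_val, engine, q)
    Rb, R1b, FRb = _backward_pass(A, B[mid:], s, costs, max_val, engine, q)
    c0, i0 = combine_no_cc(Rf, Rb, m)
    # Balancedness restriction: line (u1, mid+1) needs A[u1] = B[mid+1] and
    # line (u2, mid) needs A[u2] = B[mid].
    valid_u1 = [u for u in range(1, m + 1) if A[u - 1] == B[mid]]
    valid_u2 = [u for u in range(1, m + 1) if A[u - 1] == B[mid - 1]]
    c1, u1b, u2b = combine_cc_adjacent_B(R1f, R1b, m, costs, valid_u1, valid_u2)
    c2, u1a, v1a, v2a = combine_cc_adjacent_A(FRf, FRb, A, B, mid, costs)
    best = min(c0, c1, c2)
    if best >= max_val:
        raise AssertionError("no feasible split found")  # pragma: no cover
    if c0 == best:
        return SplitDecision("no_crossing", c0, i=i0)
    if c1 == best:
        return SplitDecision("cc_adjacent_B", c1, u1=u1b, u2=u2b, v1=mid + 1, v2=mid)
    return SplitDecision("cc_adjacent_A", c2, u1=u1a, u2=u1a + 1, v1=v1a, v2=v2a)


def _solve(A, B, s, costs, max_val, engine, q):
    m, n = len(A), len(B)
    if m <= 1 or n <= 2:
        return _full_matrix_lines(A, B, s, costs)
    mid = n // 2
    split = _decide_split(A, B, s, costs, max_val, engine, q)
    if split.kind == "no_crossing":
        i = split.i
        lc, ll = _solve(A[:i], B[:mid], s, costs, max_val, engine, q)
        rc, rl = _solve(A[i:], B[mid:], s, costs, max_val, engine, q)
        return lc + rc, ll + [(u + i, v + mid) for (u, v) in rl]
    u1, u2, v1, v2 = split.u1, split.u2, split.v1, split.v2
    lc, ll = _solve(A[: u1 - 1], B[: v2 - 1], s, costs, max_val, engine, q)
    rc, rl = _solve(A[u2:], B[v1:], s, costs, max_val, engine, q)
    local = (u2 - u1 - 1) * costs.D + costs.T + (v1 - v2 - 1) * costs.I
    lines = ll + [(u1, v1), (u2, v2)] + [(u + u2, v + v1) for (u, v) in rl]
    return lc + rc + local, lines


def ls_trace2(pair, B=None, costs: CostModel = UNIT_COSTS) -> Tuple[float, Trace]:
    """Optimal trace (and its cost, the DL distance) in Theta(m + n) space.

    Recursion bisects B at floor(n/2); subproblems with m <= 1 or n <= 2 are
    solved by full-matrix backtracking on the (constant-width) subinstance.
    Ties between split kinds prefer no-crossing, then B-adjacent, then
    A-adjacent center crossings; within a kind, the smallest index.
    """
    return _trace(pair, B, costs, engine="ls", q=None)


def strip_trace2(
    pair, B=None, costs: CostModel = UNIT_COSTS, q: int = 64
) -> Tuple[float, Trace]:
    """Same as :func:`ls_trace2` with passes run by the strip algorithm."""
    if q < 1:
        raise ValueError(f"strip width must be >= 1, got {q}")
    return _trace(pair, B, costs, engine="strip", q=q)


def _trace(pair, B, costs, engine, q):
    pair = as_pair(pair, B)
    require_valid(costs, "refined")
    max_val = default_sentinel(pair.m, pair.n, costs)
    cost, lines = _solve(
        list(pair.A), list(pair.B), pair.s, costs, max_val, engine, q
    )
    return cost, Trace.of(lines, pair.m, pair.n)
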
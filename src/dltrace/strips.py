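"""Strip (cache-blocked) computation of the DL distance (Strip_DL2).

The DP matrix is partitioned into ceil(n / q) vertical strips of q consecutive
columns (the last strip may be narrower). Each strip is filled top-to-bottom
with the same inner loop as the linear-space row algorithm, restricted to the
strip's columns, so that the working set — a handful of (q+2)-length row
arrays — stays cache-resident regardless of n.

Strips communicate through three m-length column arrays carried left to right:

* ``C``  — H values of the rightmost column of the strips processed so far,
* ``C1`` — H values of the next-to-rightmost column,
* ``FC`` — the transposition helper ``FC[i] = H[i-2][l-1]`` where l is the
  rightmost column processed so far with B[l] = A[i] (``maxVal`` if none).

``C`` and ``C1`` seed the first two columns of the next strip (the diagonal,
left and FR-write accesses that would fall off the strip's left edge); ``FC``
seeds the per-row transposition scalar. An auxiliary array of the column
indices l themselves is carried alongside ``FC`` so the weighted gap term
(j - l - 1) * I can be charged across strip boundaries.
"""

from __future__ import annotations

from typing import Optional

from .costs import CostModel, UNIT_COSTS, require_valid
from .encoding import as_pair
from .linear import DLResult, EdgeArray, default_sentinel

__all__ = ["strip_dl2", "choose_strip_width"]

_OFF = 1


def strip_dl2(
    pair,
    B=None,
    costs: CostModel = UNIT_COSTS,
    q: int = 64,
    max_val: Optional[float] = None,
) -> DLResult:
    """Weighted DL distance computed by vertical strips of width ``q``.

    Produces the same distance as :func:`~dltrace.linear.ls_dl2` for every
    q >= 1. The returned arrays are column-oriented: ``C`` is the final column
    H[.][n], ``C1`` the column H[.][n-1] and ``FC`` the transposition helper —
    exactly the boundary state the divide-and-conquer trace algorithm needs.
    """
    pair = as_pair(pair, B)
    require_valid(costs, "refined")
    if q < 1:
        raise ValueError(f"strip width must be >= 1, got {q}")
    A, Bc, s = pair.A, pair.B, pair.s
    m, n = pair.m, pair.n
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    if max_val is None:
        max_val = default_sentinel(m, n, costs)
    elif max_val <= (m + n) * costs.max_cost:
        raise ValueError("max_val does not dominate the largest reachable cost")

    # Column arrays, conceptual index -1..m in slot i+1.
    C = [max_val] * (m + 2)  # starts as column 0: H[i][0] = i*D
    for i in range(m + 1):
        C[i + _OFF] = i * D
    C1 = [max_val] * (m + 2)  # column -1
    FC = [max_val] * (m + 2)  # H[i-2][l-1]; sentinel while l undefined
    last_col = [0] * (m + 1)  # the l of FC[i] (0 = none); index by row i
    # Peak resident DP storage: C/C1/FC + their double buffers, the l-index
    # carry, the per-strip row arrays and the occurrence table.
    allocated = 5 * (m + 2) + (m + 1) + s + 3 * (min(q, n) + 2)

    j0 = 1
    while j0 <= n:
        j1 = min(j0 + q - 1, n)
        w = j1 - j0 + 1
        # Local slot t in [-1..w] maps to column j0-1+t (t=-1 -> j0-2).
        # Row arrays for row i (R) and i-1 (R1), sized w+2 with offset 1.
        Rl = [max_val] * (w + 2)
        R1l = [max_val] * (w + 2)  # row -1
        FRl = [max_val] * (w + 2)
        # Row 0 of this strip: boundary H[0][j] = j*I, left-edge from C/C1.
        Rl[-1 + _OFF] = C1[0 + _OFF]  # H[0][j0-2]
        Rl[0 + _OFF] = C[0 + _OFF]  # H[0][j0-1]
        for t in range(1, w + 1):
            Rl[t + _OFF] = (j0 - 1 + t) * I
        newC = [max_val] * (m + 2)
        newC1 = [max_val] * (m + 2)
        newC[0 + _OFF] = Rl[w + _OFF]  # H[0][j1]
        newC1[0 + _OFF] = Rl[w - 1 + _OFF]  # H[0][j1-1]
        last_row_id = [0] * s

        for i in range(1, m + 1):
            Rl, R1l = R1l, Rl  # R1l = row i-1, Rl = row i-2 (stale)
            # Left-edge values of rows i-1 and i from previous strips:
            R1l[-1 + _OFF] = C1[i - 1 + _OFF]  # H[i-1][j0-2]
            R1l[0 + _OFF] = C[i - 1 + _OFF]  # H[i-1][j0-1]
            Rl[0 + _OFF] = C[i + _OFF]  # H[i][j0-1]
            a = A[i - 1]
            l = last_col[i]  # rightmost column < j0 with B[col] == a
            Tval = FC[i + _OFF]  # H[i-2][l-1]
            last_i2l1 = C[i - 2 + _OFF] if i >= 1 else max_val  # H[i-2][j0-1]
            for t in range(1, w + 1):
                j = j0 - 1 + t
                b = Bc[j - 1]
                if a == b:
                    temp = R1l[t - 1 + _OFF]
                    d = Rl[t - 1 + _OFF] + I
                    if d < temp:
                        temp = d
                    d = R1l[t + _OFF] + D
                    if d < temp:
                        temp = d
                    FRl[t + _OFF] = R1l[t - 2 + _OFF]  # H[i-1][j-2]
                    Tval = last_i2l1
                    l = j
                else:
                    temp = R1l[t - 1 + _OFF] + S
                    d = Rl[t - 1 + _OFF] + I
                    if d < temp:
                        temp = d
                    d = R1l[t + _OFF] + D
                    if d < temp:
                        temp = d
                    k = last_row_id[b]
                    if j - l == 1:
                        d = FRl[t + _OFF] + (i - k - 1) * D + T
                        if d < temp:
                            temp = d
                    if i - k == 1:
                        d = Tval + (j - l - 1) * I + T
                        if d < temp:
                            temp = d
                last_i2l1 = Rl[t + _OFF]  # H[i-2][j]
                Rl[t + _OFF] = temp
            last_row_id[a] = i
            # Carry per-row state into the next strip.
            FC[i + _OFF] = Tval
            last_col[i] = l
            newC[i + _OFF] = Rl[w + _OFF]  # H[i][j1]
            newC1[i + _OFF] = Rl[w - 1 + _OFF]  # H[i][j1-1] (w=1: = C[i])
        C, C1 = newC, newC1
        j0 = j1 + 1

    return DLResult(
        distance=C[m + _OFF],
        R=EdgeArray(C),
        R1=EdgeArray(C1),
        FR=EdgeArray(FC),
        max_val=max_val,
        allocated_cells=allocated,
        column_oriented=True,
    )


def choose_strip_width(
    m: int,
    cache_bytes: int,
    element_bytes: int = 8,
    n: Optional[int] = None,
) -> int:
    """Largest strip width whose working set fits in ``cache_bytes``.

    The strip working set is modeled as the three strip-local row arrays of
    q + 2 elements each (the rows resident while sweeping a strip) plus the
    three m-length column arrays that carry state between strips:

        bytes(q) = 3 * (q + 2) * element_bytes + 3 * (m + 2) * element_bytes

    This model is the package's own (only the fitting requirement is
    prescribed); override q explicitly when it is a poor match for the target
    machine. The result is clamped to [1, n] when n is given.
    """
    if m < 0 or cache_bytes <= 0 or element_bytes <= 0:
        raise ValueError("m must be >= 0 and cache/element sizes positive")
    fixed = 3 * (m + 2) * element_bytes
    q = (cache_bytes - fixed) // (3 * element_bytes) - 2
    q = max(int(q), 1)
    if n is not None:
        q = min(q, max(n, 1))
    return q
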
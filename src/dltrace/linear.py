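"""Linear-space computation of the weighted DL distance (LS_DL2).

The refined recurrence needs, at cell (i, j), values from rows i-1 and i-2
only, plus two transposition helpers that look further back:

* ``H[k-1][j-2]`` where k is the rightmost row < i with A[k] = B[j], and
* ``H[i-2][l-1]`` where l is the rightmost column < j with B[l] = A[i].

Both can be carried forward in O(1) amortised time: the first in a row-shaped
array ``FR`` (written whenever A[i] = B[j], i.e. exactly when k changes for
column j), the second in a scalar ``T`` refreshed the same way. The whole DP
state is therefore three (n+2)-arrays (``R``, ``R1``, ``FR``), one length-s
occurrence table and a handful of scalars: Theta(m + n + s) elements in total,
never an m x n matrix.

Array index convention: the matrix is augmented with row -1 and column -1
whose entries are all ``maxVal`` (a sentinel strictly larger than any
reachable cost, so that sums involving it always lose the minimisation).
Internally the arrays have length n + 2 and conceptual index q lives in slot
q + 1; :class:`EdgeArray` exposes the conceptual [-1..n] indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .costs import CostModel, UNIT_COSTS, require_valid
from .encoding import as_pair

__all__ = ["EdgeArray", "DLResult", "ls_dl2", "default_sentinel"]

_OFF = 1  # conceptual index q -> list slot q + 1


class EdgeArray:
    """A sequence indexed from -1 to n inclusive (n = len - 2)."""

    __slots__ = ("_data",)

    def __init__(self, data: Sequence[float]):
        self._data = list(data)

    def __getitem__(self, q: int) -> float:
        if not -1 <= q <= len(self._data) - 2:
            raise IndexError(q)
        return self._data[q + _OFF]

    def __len__(self) -> int:
        return len(self._data)

    @property
    def last_index(self) -> int:
        return len(self._data) - 2

    def tolist(self) -> List[float]:
        """Entries for conceptual indices 0..n (drops the -1 sentinel slot)."""
        return list(self._data[_OFF:])

    def __repr__(self) -> str:  # pragma: no cover
        return f"EdgeArray({self._data[_OFF:]!r})"


@dataclass
class DLResult:
    """Distance plus the final boundary arrays of a linear-space run.

    For the row-oriented algorithm the arrays are the last computed row of H
    (``R``), the next-to-last row (``R1``) and the transposition helper row
    (``FR``, with ``FR[q] = H[k-1][q-2]`` for k the last row whose A character
    equals B[q], ``maxVal`` where no such row exists). The strip algorithm
    produces the column-oriented counterparts, exposed as ``C``/``C1``/``FC``.

    ``allocated_cells`` counts the DP elements allocated, for verifying the
    linear-space contract.
    """

    distance: float
    R: EdgeArray
    R1: EdgeArray
    FR: EdgeArray
    max_val: float
    allocated_cells: int = 0
    column_oriented: bool = False

    @property
    def C(self) -> EdgeArray:
        return self.R

    @property
    def C1(self) -> EdgeArray:
        return self.R1

    @property
    def FC(self) -> EdgeArray:
        return self.FR


def default_sentinel(m: int, n: int, costs: CostModel) -> float:
    """Smallest safe sentinel: strictly dominates any reachable cell value.

    Any cell value is at most (m + n) * max_cost; one extra max_cost keeps
    sums of a sentinel with per-operation terms above every finite value.
    """
    return (m + n + 1) * max(costs.max_cost, 1) + 1


def ls_dl2(
    pair,
    B=None,
    costs: CostModel = UNIT_COSTS,
    max_val: Optional[float] = None,
) -> DLResult:
    """Weighted DL distance in Theta(m + n + s) space.

    Parameters
    ----------
    pair, B
        An :class:`~dltrace.encoding.EncodedPair`, or two raw sequences.
    costs
        Must satisfy the refined validity condition 2S <= I + D <= 2T.
    max_val
        Sentinel for augmented row/column -1; must strictly exceed any
        reachable cell value (defaults to :func:`default_sentinel`).

    Returns
    -------
    DLResult
        ``distance`` equals the full-matrix H[m][n]; ``R``, ``R1``, ``FR``
        carry the final row semantics needed by the trace combiners.
    """
    pair = as_pair(pair, B)
    require_valid(costs, "refined")
    A, Bc, s = pair.A, pair.B, pair.s
    m, n = pair.m, pair.n
    S, I, D, T = costs.S, costs.I, costs.D, costs.T
    if max_val is None:
        max_val = default_sentinel(m, n, costs)
    elif max_val <= (m + n) * costs.max_cost:
        raise ValueError(
            f"max_val={max_val} does not dominate the largest reachable cost "
            f"{(m + n) * costs.max_cost}"
        )

    # Slot q+1 holds conceptual index q; slot 0 is the augmented column -1.
    R = [max_val] * (n + 2)  # becomes row 0 below, then alternates
    for q in range(n + 1):
        R[q + _OFF] = q * I
    R1 = [max_val] * (n + 2)  # row -1
    FR = [max_val] * (n + 2)
    last_row_id = [0] * s  # rightmost row < i with A[row] == symbol (0 = none)
    allocated = 3 * (n + 2) + s

    for i in range(1, m + 1):
        R, R1 = R1, R  # now R1 = row i-1, R = row i-2 (to be overwritten)
        a = A[i - 1]
        last_col_id = 0  # rightmost column < j with B[col] == a (0 = none)
        last_i2l1 = R[0 + _OFF]  # H[i-2][0]
        R[0 + _OFF] = i * D  # H[i][0]
        Tval = max_val  # H[i-2][l-1]; sentinel while l undefined
        for j in range(1, n + 1):
            b = Bc[j - 1]
            if a == b:
                temp = R1[j - 1 + _OFF]
                d = R[j - 1 + _OFF] + I
                if d < temp:
                    temp = d
                d = R1[j + _OFF] + D
                if d < temp:
                    temp = d
                # k for column j becomes i from the next row on:
                FR[j + _OFF] = R1[j - 2 + _OFF]  # H[i-1][j-2]
                # l becomes j for the following columns of this row:
                Tval = last_i2l1  # H[i-2][j-1]
                last_col_id = j
            else:
                temp = R1[j - 1 + _OFF] + S
                d = R[j - 1 + _OFF] + I
                if d < temp:
                    temp = d
                d = R1[j + _OFF] + D
                if d < temp:
                    temp = d
                k = last_row_id[b]
                if j - last_col_id == 1:
                    d = FR[j + _OFF] + (i - k - 1) * D + T
                    if d < temp:
                        temp = d
                if i - k == 1:
                    d = Tval + (j - last_col_id - 1) * I + T
                    if d < temp:
                        temp = d
            last_i2l1 = R[j + _OFF]  # H[i-2][j], needed at column j+1
            R[j + _OFF] = temp
        last_row_id[a] = i

    return DLResult(
        distance=R[n + _OFF],
        R=EdgeArray(R),
        R1=EdgeArray(R1),
        FR=EdgeArray(FR),
        max_val=max_val,
        allocated_cells=allocated,
    )
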
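"""Edit-operation cost models for the Damerau-Levenshtein distance.

The weighted DL distance assigns a cost to each of the four edit operations:
substitution (``S``, charged only when the two characters differ — substituting
a character for itself is always free), insertion (``I``), deletion (``D``) and
transposition of adjacent characters (``T``).

Two validity regimes matter:

* ``lw``:      I + D <= 2T.  Under this condition the classic full-matrix
               recurrence computes the minimum edit-sequence cost.
* ``refined``: 2S <= I + D <= 2T.  Under this stronger condition the
               transposition case of the recurrence can be restricted to the
               situation where the matching occurrences are adjacent to the
               current cell, which is what enables the linear-space algorithms.

The unit model S = I = D = T = 1 (the plain DL distance) satisfies both.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostModel", "UNIT_COSTS", "validate_cost_model"]


@dataclass(frozen=True)
class CostModel:
    """Costs of the four edit operations.

    All costs must be nonnegative. Integer costs keep all arithmetic exact in
    integers; float costs are compared exactly (every DP value is a finite sum
    of input costs, so no tolerance is required).
    """

    S: float = 1
    I: float = 1
    D: float = 1
    T: float = 1

    def __post_init__(self) -> None:
        for name in ("S", "I", "D", "T"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"cost {name} must be nonnegative, got {value!r}")

    @property
    def lw_valid(self) -> bool:
        """True iff I + D <= 2T (full-matrix recurrence applies)."""
        return self.I + self.D <= 2 * self.T

    @property
    def refined_valid(self) -> bool:
        """True iff 2S <= I + D <= 2T (refined recurrence applies)."""
        return 2 * self.S <= self.I + self.D <= 2 * self.T

    @property
    def max_cost(self) -> float:
        return max(self.S, self.I, self.D, self.T)

    def swap_indel(self) -> "CostModel":
        """Cost model for the reverse transformation (B -> A).

        Transforming A into B with insertions costing I and deletions costing D
        has the same cost as transforming B into A with the two roles swapped.
        Used by the divide-and-conquer trace passes, which run the row/column
        roles transposed.
        """
        return CostModel(S=self.S, I=self.D, D=self.I, T=self.T)

    def is_integral(self) -> bool:
        return all(
            isinstance(c, int) or float(c).is_integer()
            for c in (self.S, self.I, self.D, self.T)
        )


UNIT_COSTS = CostModel(1, 1, 1, 1)


def validate_cost_model(costs: CostModel, mode: str = "refined") -> bool:
    """Check a cost model against one of the two validity regimes.

    Parameters
    ----------
    costs
        The cost model to check. Negative costs raise ``ValueError`` (they are
        already rejected at construction; raw tuples are coerced here).
    mode
        ``"lw"`` checks I + D <= 2T; ``"refined"`` checks 2S <= I + D <= 2T.
    """
    if not isinstance(costs, CostModel):
        costs = CostModel(*costs)
    if mode == "lw":
        return costs.lw_valid
    if mode == "refined":
        return costs.refined_valid
    raise ValueError(f"unknown validity mode {mode!r}; expected 'lw' or 'refined'")


def require_valid(costs: CostModel, mode: str) -> None:
    if not validate_cost_model(costs, mode):
        bound = "I + D <= 2T" if mode == "lw" else "2S <= I + D <= 2T"
        raise ValueError(
            f"cost model {costs} violates the {mode} validity condition {bound}"
        )
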
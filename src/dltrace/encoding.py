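"""Integer encoding of sequence pairs over their reduced joint alphabet.

Characters that occur in neither string are irrelevant to the distance, so the
working alphabet is exactly the set of symbols occurring in A or B; its size
``s`` therefore never exceeds m + n. Codes are assigned deterministically in
first-occurrence order, scanning A then B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Sequence, Tuple

__all__ = ["EncodedPair", "encode_pair", "as_pair"]


@dataclass(frozen=True)
class EncodedPair:
    """Two integer-coded sequences plus their reduced alphabet.

    ``A`` and ``B`` hold codes in ``[0, s)``; ``code_map`` is the bijection
    from original symbols to codes.
    """

    A: Tuple[int, ...]
    B: Tuple[int, ...]
    s: int
    code_map: Dict[Hashable, int] = field(default_factory=dict, compare=False)

    @property
    def m(self) -> int:
        return len(self.A)

    @property
    def n(self) -> int:
        return len(self.B)

    def decode(self, codes: Sequence[int]) -> List[Hashable]:
        inverse = {v: k for k, v in self.code_map.items()}
        return [inverse[c] for c in codes]


def encode_pair(A: Sequence[Hashable], B: Sequence[Hashable]) -> EncodedPair:
    """Encode two sequences over their joint alphabet.

    Either sequence may be empty. Code assignment is deterministic: symbols are
    numbered by first occurrence, scanning A left to right, then B.
    """
    code_map: Dict[Hashable, int] = {}
    for seq in (A, B):
        for ch in seq:
            if ch not in code_map:
                code_map[ch] = len(code_map)
    encA = tuple(code_map[ch] for ch in A)
    encB = tuple(code_map[ch] for ch in B)
    return EncodedPair(A=encA, B=encB, s=len(code_map), code_map=code_map)


def as_pair(A, B=None) -> EncodedPair:
    """Coerce either an :class:`EncodedPair` or two raw sequences."""
    if isinstance(A, EncodedPair):
        if B is not None:
            raise TypeError("pass either an EncodedPair or two sequences, not both")
        return A
    if B is None:
        raise TypeError("two sequences required")
    return encode_pair(A, B)
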
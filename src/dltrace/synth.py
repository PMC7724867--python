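"""Synthetic test sequences.

The benchmark workloads in this field are uniform random sequences over the
20-letter amino-acid alphabet; that is the default here. Smaller alphabets
(2 for binary, 4 for nucleotides) exercise the transposition-heavy regimes,
since adjacent equal characters and repeated occurrences are more frequent.
"""

from __future__ import annotations

import random
from typing import Optional

__all__ = ["AMINO_ACIDS", "random_sequence", "random_pair"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _alphabet(size: int) -> str:
    if size < 1 or size > 26:
        raise ValueError(f"alphabet size must be in [1, 26], got {size}")
    if size == 20:
        return AMINO_ACIDS
    return _LETTERS[:size]


def random_sequence(length: int, alphabet_size: int = 20, seed: Optional[int] = None,
                    rng: Optional[random.Random] = None) -> str:
    """Uniform i.i.d. sequence; identical output for identical seed.

    Pass either ``seed`` (fresh generator) or an existing ``rng`` to draw
    several sequences from one stream.
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    letters = _alphabet(alphabet_size)
    if rng is None:
        rng = random.Random(seed)
    return "".join(rng.choice(letters) for _ in range(length))


def random_pair(max_len: int, alphabet_size: int, rng: random.Random):
    """Two independent sequences with lengths uniform in [0, max_len]."""
    return (
        random_sequence(rng.randint(0, max_len), alphabet_size, rng=rng),
        random_sequence(rng.randint(0, max_len), alphabet_size, rng=rng),
    )
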
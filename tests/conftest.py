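import random

import pytest

from dltrace.costs import CostModel

# Quarter-integer grid keeps float cost arithmetic exact in binary.
_GRID = [x / 4 for x in range(1, 13)]


def random_refined_costs(rng: random.Random) -> CostModel:
    """Random weighted cost model satisfying 2S <= I + D <= 2T."""
    I = rng.choice(_GRID)
    D = rng.choice(_GRID)
    T = rng.choice([g for g in _GRID if 2 * g >= I + D])
    S = rng.choice([g for g in _GRID if 2 * g <= I + D])
    return CostModel(S, I, D, T)


def random_positive_refined_costs(rng: random.Random) -> CostModel:
    c = random_refined_costs(rng)
    assert min(c.S, c.I, c.D, c.T) > 0
    return c


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260919)
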